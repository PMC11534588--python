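"""Simulate multi-slice acquisitions and extract aligned LR-HR patch pairs.

Three orthogonal 5 mm-thickness / 6 mm-spacing acquisitions are simulated
from one HR phantom; 3-channel patch pairs are then drawn for training.
The final check degrades each HR patch and compares it bit-exactly with
its LR counterpart — the alignment guarantee the training data relies on.
"""

import numpy as np

import slicesr as S

ph = S.generate_phantom(S.PhantomSpec(seed=7))
vol, scale = S.normalize_intensity(ph.volume, ph.brain_mask)
print(f"normalization scale: {scale:.3f} (99.5th percentile inside brain)")

profile = S.SliceProfile()      # 5 mm boxcar slabs every 6 mm (1 mm gap)
for lr, acq in S.simulate_lr_set(vol, profile):
    print(f"slice axis {acq.slice_axis}: LR shape {lr.shape}, "
          f"spacing {lr.spacing} mm")

lr, acq = S.apply_acquisition(vol, S.AcquisitionModel(2, profile)), \
    S.AcquisitionModel(2, profile)
pairs = S.extract_pairs(vol, lr, acq, ph.brain_mask,
                        S.ExtractionSpec(n_patches=6, seed=1))
worst = 0.0
for p in pairs:
    redeg = S.apply_acquisition(
        S.Volume(p.hr, (1, 1, 1)),
        S.AcquisitionModel(p.provenance["slice_dim"], profile))
    worst = max(worst, float(np.abs(redeg.data - p.lr).max()))
print(f"{len(pairs)} pairs, HR {pairs[0].hr.shape} / LR {pairs[0].lr.shape}")
print(f"max |degrade(HR patch) - LR patch| = {worst:.1e}")
print("-> zero: every LR patch is exactly the acquisition model applied "
      "to its HR patch.")
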