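"""Generate a synthetic FLAIR-like brain phantom and inspect its tissue
composition.

The phantom is the package's stand-in for real structural MRI: nested
smooth tissue regions (CSF/GM/WM), hyperintense white-matter lesions, a
smooth bias field and additive noise, on a 1 mm isotropic grid.
"""

import numpy as np

import slicesr as S

spec = S.PhantomSpec(seed=42)
ph = S.generate_phantom(spec)

print(f"volume shape {ph.volume.shape}, spacing {ph.volume.spacing} mm")
print(f"brain voxels: {int(ph.brain_mask.data.sum())} "
      f"({ph.brain_mask.data.mean():.1%} of the grid)")
print(f"lesions placed: {len(ph.lesions)}, "
      f"lesion voxels: {int(ph.lesion_mask.data.sum())}")

wm = (ph.labels == 3) & ~ph.lesion_mask.data
print(f"mean intensity  WM {ph.volume.data[wm].mean():.3f}  "
      f"lesion {ph.volume.data[ph.lesion_mask.data].mean():.3f}")
print("-> lesions are hyperintense relative to surrounding white matter,")
print("   as in T2-W FLAIR; the difference is what the SR must preserve.")
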