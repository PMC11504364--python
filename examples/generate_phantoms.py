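"""Generate a small synthetic phantom dataset and describe it.

Each phantom is a low-contrast elliptical lesion on a smooth mucosa-like
background; the printed numbers are the lesion area (in pixels) and the
intensity gap between lesion and background, which is what makes the
segmentation task easy or hard.
"""

import numpy as np

from eenet import PhantomSpec, generate_dataset

spec = PhantomSpec(
    image_size=(64, 64),
    n_lesions=1,
    contrast=0.4,  # lesion/background intensity gap; lower is harder
    texture_strength=1.0,
    boundary_softness=1.5,  # Gaussian blur radius of the lesion rim (px)
    seed=0,
)
train, val, test = generate_dataset(spec, n_train=6, n_val=2, n_test=2, seed=0)

print(f"{len(train)}/{len(val)}/{len(test)} train/val/test phantoms, 64x64 px")
for s in train:
    area = int(s.mask.sum())
    fg = s.image[0][s.mask == 1].mean() if area else float("nan")
    bg = s.image[0][s.mask == 0].mean()
    print(
        f"{s.sample_id}: lesion area {area:4d} px, "
        f"red-channel gap {abs(fg - bg):.3f} (lesion {fg:.3f} vs mucosa {bg:.3f})"
    )
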