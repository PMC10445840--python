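"""Recover a known deformation with landmark-regularized FFD registration.

Warps a phantom brain with a known smooth deformation (max 2.5 mm) plus
a small affine, registers it back to the original with the hybrid
LNCC + landmark objective, and prints the mean landmark error before and
after the non-linear stage.
"""

import numpy as np

from fetatlas import GestationalAge, PhantomSpec, make_phantom, perturb_phantom
from fetatlas.registration import fit_affine_init, register_ffd

spec = PhantomSpec(
    ga=GestationalAge.from_weeks_days(26), noise_sd=8.0, seed=1,
    grid_shape=(48, 48, 48), spacing=1.0,
)
atlas = make_phantom(spec)
subject, truth = perturb_phantom(
    atlas, scale=(1.04, 0.96, 1.0), translation=(1.5, -1.0, 0.5),
    smooth_warp_amplitude=2.5, seed=5,
)

ids = subject.landmarks.present_ids
xs = np.array([subject.landmarks[k] for k in ids])
xa = np.array([atlas.landmarks[k] for k in ids])

A = fit_affine_init(subject, atlas, use_landmarks=True)
affine_err = np.linalg.norm(xs @ A[:3, :3].T + A[:3, 3] - xa, axis=1).mean()
print(f"mean landmark error after affine initialization: {affine_err:.3f} mm")

transform = register_ffd(subject, atlas, use_landmarks=True)
ffd_err = np.linalg.norm(transform.apply_points(xs) - xa, axis=1).mean()
print(f"mean landmark error after FFD registration:      {ffd_err:.3f} mm")
print(
    "\nThe affine stage removes the global scale/shift; the B-spline stage\n"
    "(3 mm control grid, 3 pyramid levels) absorbs the smooth warp, so the\n"
    "residual error is far below the 1 mm voxel size."
)
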