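"""Register two surface clouds with robust multiscale point-to-plane ICP.

Renders the head phantom twice — once at rest and once displaced by a known
5 mm / 3 deg rigid motion — through the two virtual depth cameras, then
recovers the motion with the default 5-level rough-to-fine registration.
"""

import numpy as np

from surftrack import (
    NoiseModel,
    SixDoF,
    SurfaceCloud,
    default_cameras,
    from_sixdof,
    make_phantom,
    multiscale_register,
    render_depth,
    to_sixdof,
)


def render_fused(phantom, pose, cameras, noise, seed):
    clouds = [
        render_depth(pose.apply(phantom.vertices), phantom.faces, cam,
                     noise, np.random.default_rng([seed, j]))
        for j, cam in enumerate(cameras)
    ]
    return SurfaceCloud.concatenate(clouds)


phantom = make_phantom(seed=0)
cameras = default_cameras(resolution_scale=0.5)
noise = NoiseModel.from_sigma_at(1.0)  # 1 mm axial sigma at 450 mm range

true_motion = SixDoF(tx=5.0, ty=-2.0, tz=1.0, rx=2.0, ry=-1.0, rz=3.0)
reference = render_fused(phantom, from_sixdof(SixDoF()), cameras, noise, 0)
target = render_fused(phantom, from_sixdof(true_motion), cameras, noise, 1)

result = multiscale_register(target, reference)
estimate = to_sixdof(result.transform)

print(f"true motion:      {np.round(true_motion.as_array(), 3)}")
print(f"estimated motion: {np.round(estimate.as_array(), 3)}")
print(f"per-axis error:   "
      f"{np.round(estimate.as_array() - true_motion.as_array(), 3)}")
print(f"converged={result.converged} after {result.iterations_used} "
      f"iterations per level, final cost {result.final_cost:.2f} mm^2")
# The six numbers are tx,ty,tz (mm along LR/SI/AP) and rx,ry,rz (deg);
# errors well under 0.1 mm / 0.1 deg despite 1 mm per-pixel depth noise,
# because tens of thousands of correspondences average it away.
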