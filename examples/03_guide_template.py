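"""Build the drill-guide template and audit its tube axes.

The guide is an offset shell on the dorsal bone surface with one hollow
tube per planned trajectory; a cylinder fit of each printed bore checks
that the template cannot introduce plan error by construction.
"""

import numpy as np

from sacroplan import (ScrewSpec, TrajectoryPlan, angle_between, build_guide,
                       extract_contact_patch, extract_surface, fit_cylinder_axis,
                       segment, smooth_surface)
from sacroplan.guide import GuideSpec
from sacroplan.phantom import PhantomSpec, generate_phantom

spec = PhantomSpec.small(scale=0.55, voxel_spacing=1.0, noise_sd=15.0, seed=1)
volume, truth = generate_phantom(spec)
bone = smooth_surface(extract_surface(segment(volume, 200.0, 1400.0)), 6, 0.7)

patch = extract_contact_patch(bone)
print(f"contact patch: {patch.area:.0f} mm^2, {len(patch.faces)} faces")

plans = [TrajectoryPlan(k, ax.point, ax.direction, ScrewSpec().scaled(0.55))
         for k, ax in truth.true_axes.items()]
gspec = GuideSpec()
guide = build_guide(patch, plans, gspec)
print(f"guide: watertight={guide.is_watertight}, {len(guide.faces)} faces, "
      f"genus {(2 - guide.euler_number) // 2}")
guide.export("guide.stl")

r_in = gspec.tube_inner_diameter / 2
for plan in plans:
    d = plan.axis.distance_to_point(guide.vertices)
    t = (guide.vertices - plan.entry) @ -plan.direction
    sel = (np.abs(d - r_in) < 0.2) & (t > 1.0) & (t < gspec.tube_length - 1.0)
    fitted = fit_cylinder_axis(guide.vertices[sel], cloud="surface")
    print(f"{plan.label}: bore axis deviates {angle_between(fitted, plan.axis):.3f} deg "
          f"from the plan")
# Sub-0.15-degree deviations mean trajectory error can only come from
# guide seating or drilling, not from the template geometry itself.
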