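"""Analytic perspective projection: magnification and landmark distances.

Shows the similar-triangles magnification of the divergent beam (an object
in the isocentre plane is enlarged by SID / source-isocentre = 4/3 at
SID 1000 / OID 250) and lists the six study distances as projected onto
the detector for their respective projections.
"""
import numpy as np

from isodrr import (DetectorSpec, IsocentricSetup, default_catalogue,
                    default_projections, load_measurement_definitions,
                    pose_from_isocentric, project_point, projected_distance)

det = DetectorSpec()
pose = pose_from_isocentric(IsocentricSetup(0, 0))

p = project_point(np.array([30.0, 0.0, 0.0]), pose, det)
print(f"point 30 mm off-axis in the isocentre plane -> "
      f"{np.hypot(p.u_mm, p.v_mm):.3f} mm on the detector (expect 40: mag 4/3)")

p = project_point(np.array([30.0, -150.0, 0.0]), pose, det)
print(f"same offset but 150 mm source-ward            -> "
      f"{np.hypot(p.u_mm, p.v_mm):.3f} mm (expect 50: mag 1000/600)\n")

catalogue = default_catalogue()
setups = {s.name: s for s in default_projections()}
print("projected landmark distances (the geometric oracle):")
for d in load_measurement_definitions():
    pose = pose_from_isocentric(setups[d.projection])
    dist = projected_distance(d.landmark_a, d.landmark_b, catalogue, pose, det)
    print(f"  {d.name:24s} on {d.projection:4s} ({d.plane:8s}) = {dist:7.2f} mm")
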