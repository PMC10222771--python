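"""Extract the 12-point skeleton from a rendered silhouette and score it.

The extractor is purely geometric (distance transform + medial axis); we
check it against the renderer's ground-truth joints with the Euclidean
distance rule: a point is recognised when its distance stays within 15 px
at 640x480 (7.5 px at this 320x240 render).
"""

import numpy as np

from momofuse import extract_skeleton, point_distance, render_stick_figure
from momofuse.skeleton import POINT_NAMES
from momofuse.synthetic import _class_params, make_background, stick_figure_joints

params = _class_params(3, 6)
background = make_background((320, 240), seed=5)
joints = stick_figure_joints(1.7, params, 160.0, (320, 240))
mask, frame = render_stick_figure(joints, (320, 240), background)

sk = extract_skeleton(mask)
print(f"{'point':15s} {'detected':>16s} {'truth':>16s} {'dist':>6s} {'conf':>5s}")
for i, name in enumerate(POINT_NAMES):
    d = point_distance(sk.points[i], joints[i])
    print(f"{name:15s} ({sk.points[i][0]:6.1f},{sk.points[i][1]:6.1f}) "
          f"({joints[i][0]:6.1f},{joints[i][1]:6.1f}) {d:6.2f} {sk.confidence[i]:5.2f}")
mean_d = np.mean([point_distance(sk.points[i], joints[i]) for i in range(12)])
print(f"\nmean joint distance: {mean_d:.2f} px (threshold 7.5 px at 320x240)")
print("Distances below the threshold count the point as recognised; the")
print("confidence is the silhouette thickness at the point relative to the torso.")
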