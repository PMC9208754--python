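"""Activity mapping of a movie with a known active region and an activity switch.

Generates a movie whose left half holds confined swimmers over a static
textured surround; halfway through, the swimmers freeze (emulating the loss
of motility inside channels without structural change). Computes normalized
degree-of-correlation maps before and after the switch, classifies ROIs and
scores them against the generator mask. Writes results/activity_map_pre.csv
and results/activity_map_post.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wrinklekit.activity import activity_map, classify_rois
from wrinklekit.synthetic import generate_activity_movie

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

movie, mask, switch = generate_activity_movie(frames=480, switch_frame=240, seed=0)
pre = activity_map(movie, tau_s=1.0, n_pairs=200, frame_range=(0, switch))
post = activity_map(movie, tau_s=1.0, n_pairs=200, frame_range=(switch, 480))

pd.DataFrame(pre.normalized).to_csv(OUT / "activity_map_pre.csv", index=False)
pd.DataFrame(post.normalized).to_csv(OUT / "activity_map_post.csv", index=False)

roi = pre.roi_px
h = mask.shape[0] // roi * roi
w = mask.shape[1] // roi * roi
troi = mask[:h, :w].reshape(h // roi, roi, w // roi, roi).mean(axis=(1, 3)) > 0.5
acc = (classify_rois(pre) == troi).mean()

print(f"ROI grid: {pre.normalized.shape} at {roi} px per ROI (~2.5 um)")
print(f"pre-switch: active-region correlation {np.nanmean(pre.normalized[troi]):.3f}, "
      f"static surround {np.nanmean(pre.normalized[~troi]):.3f}")
print(f"ROI classification accuracy vs generator mask: {acc:.1%}")
print(f"post-switch: formerly active region reverts to {np.nanmean(post.normalized[troi]):.3f}")
print("Low correlation marks motile-bacteria activity; freezing the swimmers restores")
print("high correlation without any structural change, as in maturing channel networks.")
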