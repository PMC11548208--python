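"""Turn a segmentation into timed movement annotations on an fNIRS timebase.

Uses a threshold rule as a stand-in predictor (any trained model plugs in
the same way) to show the annotation path: binary mask -> merged/filtered
event intervals -> mask resampled from the 30 Hz video grid to the
10.17 Hz fNIRS grid, where it can flag potentially artifact-bearing
samples.
"""

import numpy as np

from headseg import generate_session, mask_to_events, resample_mask

session = generate_session(participant_id="demo", seed=7)

# stand-in predictor: movement = sustained change of the smoothed orientation
# (any trained model plugs in identically via predict_session)
from scipy.ndimage import uniform_filter1d

smooth = uniform_filter1d(session.signal.values, size=15, axis=0)
speed = np.abs(np.diff(smooth, axis=0, prepend=smooth[:1]))
pred_mask = (speed.max(axis=1) > 0.15).astype(np.uint8)

events = mask_to_events(pred_mask, session.signal.fs,
                        min_duration_s=0.2, merge_gap_s=0.2)
print(f"detected {len(events)} movement events (truth: {len(session.events)})")
for ev in events[:3]:
    print(f"  {ev.onset:7.2f} - {ev.offset:7.2f} s ({ev.duration:.2f} s)")

fnirs = resample_mask(pred_mask, session.signal.fs, 10.17)
print(f"fNIRS-grid mask: {len(fnirs)} samples at 10.17 Hz, "
      f"{fnirs.mean():.1%} flagged as movement")
print(f"flagged duration {fnirs.sum() / 10.17:.1f} s "
      f"vs video-grid {pred_mask.sum() / session.signal.fs:.1f} s")
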