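"""Simulate one instructed-movement session and inspect its ground truth.

Generates a 60-movement session (3 axes x 2 speeds x 3 movement types over
3 blocks, 3 s countdown + 7 s response window per trial) and prints its
anatomy.  The event table and rasterised mask are what the segmentation
model later learns to reproduce from the orientation signal alone.
"""

import collections

from headseg import generate_session
from headseg.io import write_session

session = generate_session(participant_id="demo", seed=42)

print(f"session duration : {session.signal.duration:.0f} s "
      f"({len(session.signal)} samples at {session.signal.fs:g} Hz)")
print(f"movement events  : {len(session.events)}")
print(f"moving fraction  : {session.mask.mean():.2%} of samples")

by_type = collections.Counter(e.mtype for e in session.events)
print("events per type  :", dict(by_type))

ev = session.events[0]
print(f"first event      : {ev.axis}/{ev.speed}/{ev.mtype} "
      f"at {ev.onset:.2f}-{ev.offset:.2f} s")

paths = write_session(session, "scratch/demo_session")
print("written          :", *paths)
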