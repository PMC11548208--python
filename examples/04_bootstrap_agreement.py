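"""Score annotation agreement with Jaccard + percentile-bootstrap CIs.

Compares a corrupted copy of a session's ground truth against the original,
trial by trial, stratified by movement type — the same report structure the
full pipeline produces for a trained model.
"""

import numpy as np

from headseg import bootstrap_ci, generate_session, stratified_scores

session = generate_session(participant_id="demo", seed=11)

# corrupt the reference: shift every predicted event 300 ms late
shift = int(0.3 * session.signal.fs)
pred = np.roll(session.mask, shift)

print("per-movement-type Jaccard (mean [2.5%, 97.5%] over trials):")
for mtype, scores in sorted(stratified_scores(pred, session, "mtype").items()):
    lo, hi = bootstrap_ci(scores, n_boot=5000, seed=0)
    print(f"  {mtype:9s} {np.mean(scores):.3f} [{lo:.3f}, {hi:.3f}]  n={len(scores)}")

print("\nshort 'half' movements lose the largest overlap fraction to a fixed")
print("time shift, mirroring how brief movements are hardest to annotate.")
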