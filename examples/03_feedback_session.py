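"""A full online feedback run: gating, accumulation, diffusion embedding.

Generates a one-run synthetic session with occasional artifacts, replays
it through the streaming engine, and prints the per-run bookkeeping plus
the final 2-D positions of the two class-mean pseudo-points (the
rectangles a subject would watch drift apart as their imagery improves).
"""

import numpy as np

from riemannbci import GeneratorConfig, SessionConfig, generate_session, run_session

gen = GeneratorConfig(seed=7, trials_per_run=20, runs_per_session=1,
                      erd_effect=0.5, artifact_rate=0.05)
session = generate_session(gen)
cfg = SessionConfig(trials_per_run=20, runs_per_session=1)

result = run_session(session, cfg)
run = result.runs[0]
print(f"presented segments: {run.n_retained + run.n_rejected}")
print(f"retained (clean):   {run.n_retained}")
print(f"rejected (gate):    {run.n_rejected}")

final = run.frames[-1]
ids = final.point_ids
for pid in ("mean:left", "mean:right"):
    x, y = final.coordinates[ids.index(pid)]
    print(f"{pid:11s} at ({x:+.4f}, {y:+.4f})")
gap = np.linalg.norm(
    final.coordinates[ids.index("mean:left")]
    - final.coordinates[ids.index("mean:right")]
)
print(f"class-mean separation on screen: {gap:.4f}")
# With a solid ERD effect (g = 0.5) the two class means occupy opposite
# sides of the display; their separation is the visual feedback target.
warmups = sum(f.warm_up for f in run.frames)
print(f"warm-up frames before a stable projection: {warmups}")
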