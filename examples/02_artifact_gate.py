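"""The Riemannian Potato artifact gate in action.

Initialises the gate from a resting baseline, then streams clean
motor-imagery segments and one injected high-amplitude artifact through
it, printing each geodesic distance against the adaptive threshold.
"""

import numpy as np

from riemannbci import (
    GeneratorConfig,
    classify_segment,
    estimate_covariance,
    generate_segment,
    initialize_potato,
    inject_artifact,
    update_potato,
)

cfg = GeneratorConfig(seed=0)
rng = np.random.default_rng(1)

baseline_covs = [
    estimate_covariance(generate_segment("rest", cfg, rng).samples,
                        shrinkage=0.01)
    for _ in range(10)
]
state = initialize_potato(baseline_covs)  # z = 2.5, w = 0.01, alpha = 100
print(f"gate initialised: mu={state.mu:.3f} sigma={state.sigma:.3f} "
      f"threshold={state.threshold:.3f}")

for i in range(5):
    seg = generate_segment("left", cfg, rng)
    if i == 3:
        seg = inject_artifact(seg, gain=10.0, rng=rng)
    P = estimate_covariance(seg.samples, shrinkage=0.01)
    is_artifact, d = classify_segment(state, P)
    verdict = "ARTIFACT (discarded)" if is_artifact else "clean"
    print(f"segment {i}: distance {d:6.3f} vs threshold "
          f"{state.threshold:.3f} -> {verdict}")
    if not is_artifact:
        state = update_potato(state, P, distance=d)
# Clean segments sit well below the threshold and nudge the reference and
# the mu/sigma statistics; the gain-10 transient lands an order of
# magnitude above it and is rejected without touching the state.
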