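"""One adaptive assessment, step by step.

Builds the synthetic 11-item, 7-category hand-function bank, administers an
adaptive assessment to a simulated respondent with true severity theta = 0.2,
and prints how the score estimate sharpens after each item until the SE of
measurement drops below 0.3.
"""

import numpy as np

from promcat import (
    CATConfig,
    NormalPrior,
    make_synthetic_bank,
    run_assessment,
    simulate_response,
)

bank = make_synthetic_bank()
rng = np.random.default_rng(1)
result = run_assessment(
    response_provider=lambda item: simulate_response(0.2, item, rng),
    bank=bank,
    prior=NormalPrior(0.0, 1.0),  # population prior for a first assessment
    config=CATConfig(),  # EAP + MEPV + stop at SE < 0.3
)

print("step  item    cat   eap     se")
for i, ((item_id, cat), s) in enumerate(zip(result.administered, result.step_summaries), 1):
    print(f"{i:>4}  {item_id}  {cat:>3}  {s.eap:+.3f}  {s.se:.3f}")
f = result.final
print(f"\nfinal: eap={f.eap:+.3f} (z score; higher = more severe), "
      f"se={f.se:.3f}, 95% CI=({f.ci_low:+.3f}, {f.ci_high:+.3f})")
print(f"terminated after {result.n_items}/{len(bank)} items ({result.termination_reason})")
# The EAP is the posterior-mean severity; each administered item shrinks the
# posterior SD (the SE of measurement) until the precision rule is met.
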