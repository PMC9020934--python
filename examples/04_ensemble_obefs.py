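"""Full ensemble selection: three selectors, majority vote, redundancy filter.

The three metaheuristics run with independently derived seeds (including
independent internal CV splits), their best masks are fused by a 2-of-3 vote,
and highly correlated survivors (|r| > 0.9) are deduplicated, keeping the
member more correlated with the class label.
"""

import numpy as np

from obefs import ObefsConfig, SyntheticSpec, generate_synthetic, run_obefs

table, truth = generate_synthetic(
    SyntheticSpec(n_subjects_per_class=12, n_informative=4, n_redundant=4,
                  n_noise=22, effect_size=2.0, seed=1)
)

res = run_obefs(table, ObefsConfig(seed=1, pop_size=12, max_iters=40, lfcsa_max_iters=800))

for name, mask in res.input_masks.items():
    print(f"{name:6s}: {int(mask.sum())} features selected")
print(f"consensus (>=2 votes): {int(res.consensus_mask.sum())} features")
for kept, dropped, r in res.dropped_redundant:
    print(f"  dropped column {dropped} (|r|={abs(r):.3f} with kept column {kept})")

sel = set(np.flatnonzero(res.final_mask).tolist())
inf = set(truth.informative)
print(f"final mask: {len(sel)} features; informative recovered {len(sel & inf)}/{len(inf)}")
# Voting removes selector-specific noise picks; the correlation filter removes
# redundant copies of informative features that survived the vote.
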