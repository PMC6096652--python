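"""A miniature selective-influence check.

Plants a drift-only race effect in a few replicate datasets, refits each,
and reports how often each parameter's group-level race contrast excludes
zero.  The drift rate should dominate; parameters with no planted effect
are excluded only at roughly the HDI's error rate.  (The full
20-replicate battery per setting runs via ``python scripts/acceptance.py``.)
"""

import json

import shootddm as S

res = S.recovery_suite("drift_only", n_datasets=8, seed=1)
print(json.dumps({k: res[k] for k in
                  ("setting", "n_datasets", "effect_sizes", "rates",
                   "true_rate", "false_rate")}, indent=1))
# rates: fraction of replicates in which each parameter's 95% HDI excluded
# zero.  true_rate aggregates the planted parameter(s), false_rate the rest.
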