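"""The hierarchical signal-detection baseline on the same trial table.

Choice data are collapsed to hit/false-alarm counts per subject and race,
then fit with the equal-variance probit SDT model.  Because SDT ignores
response times, a drift-rate race effect shows up (if at all) smeared over
sensitivity d' and criterion c.
"""

import shootddm as S

trials, _ = S.generate_dataset(
    S.TruthConfig(effects={("delta", "race", "black"): 0.5}),
    n_subjects=25, trials_per_cell=20, window_ms=None, censor_mode="none",
    seed=7)

counts = S.aggregate_counts(trials)
print(counts.groupby("race")[["hits", "misses", "false_alarms",
                              "correct_rejections"]].sum())

draws = S.fit_sdt(counts, chains=2, iterations=800, warmup=800, seed=9)
print(draws.summary().to_string(index=False, float_format=lambda x: f"{x:.3f}"))

for fam in ("dprime", "criterion"):
    c = S.contrast(draws, fam, {"race": "black"}, {"race": "white"})
    flag = "*" if c.excludes_zero else " "
    print(f"{fam:9s} race contrast M = {c.mean:+.3f} "
          f"[{c.hdi_lo:+.3f}, {c.hdi_hi:+.3f}] {flag}")
# d' is sensitivity in z-units; c is the criterion measured from the
# midpoint (negative = liberal, i.e. a lower bar for responding "shoot").
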