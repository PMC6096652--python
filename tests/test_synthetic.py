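"""Synthetic-data generator: presets, censoring, ground truth, recovery suites."""

import math

import numpy as np
import pytest

import shootddm as S
from shootddm.hierarchy import FAMILIES
from shootddm.inference import PosteriorDraws
from shootddm.synthetic import (DEFAULT_EFFECTS, PAYOFFS, STUDY_PRESETS,
                                TruthConfig, generate_dataset, generate_preset,
                                parameter_recovery, recovery_suite,
                                truth_group_level)


class TestPresets:
    def test_study_design_constants(self):
        s1 = STUDY_PRESETS["study1"]
        assert (s1.n_subjects, s1.trials_per_subject, s1.window_ms,
                s1.censor_mode) == (56, 100, 850.0, "drop")
        assert STUDY_PRESETS["study2"].context == "between"
        assert STUDY_PRESETS["study2"].window_ms == 630.0
        assert STUDY_PRESETS["study3"].blur == "within"
        assert STUDY_PRESETS["study3"].window_ms == 750.0
        assert STUDY_PRESETS["study4"].window_ms == 630.0
        assert STUDY_PRESETS["study4"].trials_per_cell == 40
        for p in STUDY_PRESETS.values():
            assert dict(p.payoffs) == PAYOFFS

    def test_study1_generated_shape(self):
        trials, truth = generate_preset("study1", seed=1, n_subjects=6,
                                        trials_per_cell=5)
        assert trials["subject"].nunique() == 6
        assert len(trials) == 6 * 4 * 5
        assert trials.loc[trials["censored"], "choice"].eq("").all()
        assert trials.loc[trials["censored"], "rt_ms"].isna().all()
        assert (trials.loc[~trials["censored"], "rt_ms"] <= 850.0).all()
        assert truth["window_ms"] == 850.0

    def test_between_vs_within_context_assignment(self):
        t2, _ = generate_preset("study2", seed=2, n_subjects=8, trials_per_cell=3)
        per_subj = t2.groupby("subject")["context"].nunique()
        assert (per_subj == 1).all()
        assert set(t2["context"]) == {"neutral", "dangerous"}
        t4, _ = generate_preset("study4", seed=2, n_subjects=4, trials_per_cell=3)
        assert (t4.groupby("subject")["context"].nunique() == 2).all()


class TestGenerator:
    def test_unbiased_zero_drift_shoot_rate(self):
        cfg = TruthConfig(beta=0.5, delta_gun=0.0, delta_nongun=0.0,
                          sd={"beta": 0.02, "alpha": 0.1, "delta": 0.05,
                              "ndt": 0.03})
        trials, _ = generate_dataset(cfg, n_subjects=12, trials_per_cell=25,
                                     window_ms=None, censor_mode="none", seed=9)
        p = (trials["choice"] == "shoot").mean()
        n = len(trials)
        se = math.sqrt(0.25 / n + 0.02**2 / 12)
        assert abs(p - 0.5) < 3 * se

    def test_censoring_fraction_matches_survivor_mass(self):
        """Per-condition censoring fraction against the analytic survivor
        mass at the window, averaged over the sampled subjects."""
        trials, truth = generate_dataset(
            TruthConfig(alpha=1.04), n_subjects=20, trials_per_cell=25,
            window_ms=630.0, censor_mode="drop", seed=31)
        th = {f: np.asarray(truth["subject_theta"][f]) for f in FAMILIES}
        d_cells = [tuple(c) for c in truth["cells"]["delta"]]
        for k, cell in enumerate(d_cells):
            levels = dict(zip(("race", "object"), cell))
            kb = [tuple(c) for c in truth["cells"]["beta"]].index((levels["race"],))
            expect = np.mean([
                S.survivor_probability(
                    0.63 - th["ndt"][j, k],
                    S.DDMParams(th["beta"][j, kb], th["alpha"][j, kb],
                                th["delta"][j, k], th["ndt"][j, k]))
                for j in range(20)])
            sel = (trials["race"] == levels["race"]) & \
                  (trials["object"] == levels["object"])
            frac = trials.loc[sel, "censored"].mean()
            n = int(sel.sum())
            se = math.sqrt(max(expect * (1 - expect), 0.002) / n)
            assert abs(frac - expect) < 3.5 * se

    def test_flag_mode_keeps_outcomes(self):
        trials, _ = generate_dataset(TruthConfig(), n_subjects=5, trials_per_cell=10,
                                     window_ms=630.0, censor_mode="flag", seed=4)
        late = trials["censored"]
        assert late.any()
        assert (trials.loc[late, "rt_ms"] > 630.0).all()
        assert trials.loc[late, "choice"].isin(["shoot", "dontshoot"]).all()

    def test_truth_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            generate_dataset(TruthConfig(beta=0.95), 4, 4, None, "none", seed=0)
        with pytest.raises(ValueError):
            generate_dataset(TruthConfig(), 4, 4, None, censor_mode="drop", seed=0)

    def test_reproducible(self):
        a, ta = generate_dataset(TruthConfig(), 4, 4, None, "none", seed=5)
        b, tb = generate_dataset(TruthConfig(), 4, 4, None, "none", seed=5)
        assert a.equals(b) and ta == tb

    def test_roundtrip_io(self, tmp_path):
        trials, truth = generate_dataset(TruthConfig(), 4, 4, 630.0, "drop", seed=6)
        S.write_dataset(trials, truth, tmp_path / "d.csv")
        trials2, truth2 = S.read_dataset(tmp_path / "d.csv")
        assert truth2 == truth
        assert len(trials2) == len(trials)
        assert (trials2["censored"] == trials["censored"]).all()
        assert trials2.loc[~trials2["censored"], "choice"].isin(
            ["shoot", "dontshoot"]).all()


class TestParameterRecovery:
    def _centered_draws(self, truth, spread, rng, shuffle=False):
        group, subject, taus = {}, {}, {}
        for f in FAMILIES:
            mu = np.asarray(truth["group_mu"][f])
            th = np.asarray(truth["subject_theta"][f])
            if shuffle:
                th = th.copy()
                rng.shuffle(th.ravel())
            group[f] = mu[None, None, :] + rng.normal(0, spread, (2, 200, len(mu)))
            subject[f] = th[None, None] + rng.normal(0, spread, (2, 200) + th.shape)
            taus[f] = np.full((2, 200), truth["tau"][f])
        return PosteriorDraws(
            group=group, tau=taus, subject=subject,
            cells={f: [tuple(c) for c in truth["cells"][f]] for f in FAMILIES},
            factors={"beta": ("race",), "alpha": ("race",),
                     "delta": ("race", "object"), "ndt": ("race", "object")})

    def test_truth_centered_draws_full_coverage(self, rng):
        _, truth = generate_dataset(TruthConfig(), 10, 5, None, "none", seed=7)
        rec = parameter_recovery(truth, self._centered_draws(truth, 0.02, rng))
        assert rec["overall_group_coverage"] == 1.0
        for f in FAMILIES:
            assert abs(np.mean(rec[f]["group_bias"])) < 0.01
            assert rec[f]["subject_corr"] > 0.95

    def test_shuffled_truth_collapses_correlation(self, rng):
        _, truth = generate_dataset(TruthConfig(), 10, 5, None, "none", seed=7)
        rec = parameter_recovery(truth, self._centered_draws(truth, 0.02, rng,
                                                             shuffle=True))
        assert rec["delta"]["subject_corr"] < 0.5

    def test_map_mismatch_rejected(self, rng):
        _, truth = generate_dataset(TruthConfig(), 10, 5, None, "none", seed=7)
        draws = self._centered_draws(truth, 0.02, rng)
        draws.cells["delta"] = draws.cells["delta"][::-1]
        with pytest.raises(ValueError, match="map mismatch"):
            parameter_recovery(truth, draws)


class TestRecoverySuite:
    def test_saturated_effect_always_identified(self):
        """An implausibly large drift effect must be identified in every
        replicate, and the start point left alone."""
        res = recovery_suite("drift_only", n_datasets=2,
                             effect_sizes={"delta": 3.0},
                             fit_config=S.FitConfig(chains=2, iterations=250,
                                                    warmup=250),
                             seed=77, n_subjects=12, trials_per_cell=12)
        assert res["true_rate"] == 1.0
        assert res["identified"]["beta"] == 0
        assert res["effect_sizes"] == {"delta": 3.0}

    def test_default_effect_sizes(self):
        assert DEFAULT_EFFECTS == {"beta": 0.05, "delta": 0.5, "alpha": 0.1}
        with pytest.raises(ValueError):
            recovery_suite("not_a_setting", n_datasets=1)


class TestTruthGroupLevel:
    def test_effects_applied_to_matching_cells(self):
        trials, _ = generate_dataset(TruthConfig(), 3, 2, None, "none", seed=1)
        pmap = S.build_design(trials)
        cfg = TruthConfig(effects={("delta", "race", "black"): 0.5})
        g = truth_group_level(cfg, pmap)
        for k, cell in enumerate(pmap.cells["delta"]):
            levels = dict(zip(pmap.factors["delta"], cell))
            base = 2.0 if levels["object"] == "gun" else -2.0
            expect = base + (0.5 if levels["race"] == "black" else 0.0)
            assert g.mu["delta"][k] == pytest.approx(expect)
        assert g.tau["delta"] == pytest.approx(1 / 0.58**2)
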