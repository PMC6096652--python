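"""Design maps, priors and the assembled log posterior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shootddm as S
from shootddm import _sampler
from shootddm.hierarchy import (FAMILIES, GroupLevel, HierarchicalDDM,
                                IdentifiabilityError, PriorConfig, SchemaError,
                                SubjectParams, VariationSpec, build_design,
                                log_prior)


def _toy_trials(n_subjects=2, contexts=None):
    rows = []
    rng = np.random.default_rng(7)
    for j in range(n_subjects):
        ctx = "none" if contexts is None else contexts[j]
        for race in ("black", "white"):
            for obj in ("gun", "nongun"):
                for _ in range(3):
                    rows.append({
                        "subject": f"s{j}", "study": "toy", "race": race,
                        "object": obj, "context": ctx, "blur": "none",
                        "choice": "shoot" if rng.random() < 0.6 else "dontshoot",
                        "rt_ms": float(rng.uniform(420, 800)), "censored": False,
                    })
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_race_only_cell_combinatorics(self):
        pmap = build_design(_toy_trials())
        assert pmap.n_cells("delta") == 4   # race x object
        assert pmap.n_cells("beta") == 2    # race only
        assert pmap.n_cells("alpha") == 2
        assert sorted(pmap.cells["beta"]) == [("black",), ("white",)]

    def test_object_varying_start_point_rejected(self):
        with pytest.raises(IdentifiabilityError):
            VariationSpec(beta=("race", "object")).validate()
        with pytest.raises(IdentifiabilityError):
            build_design(_toy_trials(), VariationSpec(alpha=("object",)))

    def test_unknown_factor_rejected(self):
        with pytest.raises(SchemaError):
            build_design(_toy_trials(), VariationSpec(beta=("colour",)))

    def test_unknown_level_rejected(self):
        t = _toy_trials()
        t.loc[0, "race"] = "green"
        with pytest.raises(SchemaError):
            build_design(t)

    def test_empty_table_rejected(self):
        with pytest.raises(SchemaError):
            build_design(_toy_trials().iloc[:0])

    def test_between_subject_cells_are_disjoint(self):
        """Study-2-like design: with context varied between subjects, each
        subject's observed cells span exactly one context level."""
        t = _toy_trials(n_subjects=4,
                        contexts=["neutral", "dangerous", "neutral", "dangerous"])
        spec = VariationSpec(beta=("race", "context"), alpha=("race", "context"),
                             delta=("race", "context", "object"),
                             ndt=("race", "context", "object"))
        pmap = build_design(t, spec)
        model = HierarchicalDDM(t, spec=spec)
        ctx_pos = pmap.factors["beta"].index("context")
        for j in range(pmap.n_subjects):
            present = np.flatnonzero(model.presence["beta"][j])
            levels = {pmap.cells["beta"][k][ctx_pos] for k in present}
            assert len(levels) == 1


def _toy_group_subjects(pmap, rng):
    group = GroupLevel(
        mu={"beta": np.full(pmap.n_cells("beta"), 0.55),
            "alpha": np.full(pmap.n_cells("alpha"), 1.1),
            "delta": rng.uniform(-1, 1, pmap.n_cells("delta")),
            "ndt": np.full(pmap.n_cells("ndt"), 0.3)},
        tau={"beta": 200.0, "alpha": 30.0, "delta": 3.0, "ndt": 400.0})
    subj = SubjectParams(theta={
        f: np.clip(group.mu[f][None, :] + rng.normal(0, 0.3 / np.sqrt(group.tau[f]),
                                                     (pmap.n_subjects, pmap.n_cells(f))),
                   PriorConfig().lo(f) + 0.01, 0.38 if f == "ndt" else
                   PriorConfig().hi(f) - 0.01)
        for f in FAMILIES})
    return group, subj


class TestLogPrior:
    def test_outside_truncation_is_impossible(self, rng):
        pmap = build_design(_toy_trials())
        group, subj = _toy_group_subjects(pmap, rng)
        base = log_prior(group, subj, pmap, PriorConfig())
        assert np.isfinite(base)
        subj.theta["beta"][0, 0] = 0.95   # outside [.1, .9]
        assert log_prior(group, subj, pmap, PriorConfig()) == -np.inf

    def test_group_mean_outside_uniform_bounds(self, rng):
        pmap = build_design(_toy_trials())
        group, subj = _toy_group_subjects(pmap, rng)
        group.mu["alpha"] = np.array([6.0, 1.0])  # above uniform hi = 5
        assert log_prior(group, subj, pmap, PriorConfig()) == -np.inf
        group.mu["alpha"] = np.array([1.0, 1.0])
        group.tau["delta"] = -1.0
        assert log_prior(group, subj, pmap, PriorConfig()) == -np.inf

    def test_matches_hand_computed_sum(self):
        """2-subject, 1-cell toy against an independently assembled sum of
        truncated-normal, gamma and uniform log densities."""
        t = _toy_trials(n_subjects=2)
        spec = VariationSpec(beta=(), alpha=(), delta=(), ndt=())
        pmap = build_design(t, spec)
        pr = PriorConfig()
        group = GroupLevel(mu={"beta": np.array([0.6]), "alpha": np.array([1.2]),
                               "delta": np.array([0.4]), "ndt": np.array([0.31])},
                           tau={"beta": 150.0, "alpha": 25.0, "delta": 2.0, "ndt": 300.0})
        subj = SubjectParams(theta={
            "beta": np.array([[0.58], [0.66]]), "alpha": np.array([[1.0], [1.4]]),
            "delta": np.array([[0.2], [0.9]]), "ndt": np.array([[0.28], [0.35]])})
        expect = 0.0
        for f in FAMILIES:
            lo, hi = pr.bounds[f]
            sd = 1.0 / np.sqrt(group.tau[f])
            a, b = (lo - group.mu[f][0]) / sd, (hi - group.mu[f][0]) / sd
            for j in range(2):
                expect += stats.truncnorm.logpdf(
                    subj.theta[f][j, 0], a, b, loc=group.mu[f][0], scale=sd)
            expect += stats.gamma.logpdf(group.tau[f], pr.tau_shape,
                                         scale=1.0 / pr.tau_rate)
            expect += -np.log(hi - lo)
        got = log_prior(group, subj, pmap, pr)
        assert got == pytest.approx(expect, rel=1e-12)


class TestLogPosterior:
    def test_additivity_over_trials(self, rng):
        t = _toy_trials(n_subjects=1).iloc[:4].reset_index(drop=True)
        model = HierarchicalDDM(t)
        group, subj = _toy_group_subjects(model.pmap, rng)
        lp = model.log_posterior(group, subj)
        expect = model.log_prior(group, subj)
        for i in range(4):
            p = model.trial_params(subj, i)
            out = S.TrialOutcome(
                boundary="upper" if model.choice[i] == 1 else "lower",
                rt_ms=model.rt_s[i] * 1000.0)
            expect += S.trial_loglik(out, p)
        assert lp == pytest.approx(expect, rel=1e-10)

    def test_minus_inf_prior_propagates(self, rng):
        model = HierarchicalDDM(_toy_trials())
        group, subj = _toy_group_subjects(model.pmap, rng)
        subj.theta["beta"][0, 0] = 0.95
        assert model.log_posterior(group, subj) == -np.inf

    def test_doubling_data_doubles_likelihood(self, rng):
        t = _toy_trials()
        doubled = pd.concat([t, t], ignore_index=True)
        m1, m2 = HierarchicalDDM(t), HierarchicalDDM(doubled)
        group, subj = _toy_group_subjects(m1.pmap, rng)
        assert m2.log_likelihood(subj) == pytest.approx(
            2.0 * m1.log_likelihood(subj), rel=1e-10)

    def test_invariant_to_trial_order_and_relabeling(self, rng):
        t = _toy_trials(n_subjects=3)
        group, subj0 = _toy_group_subjects(build_design(t), rng)
        m1 = HierarchicalDDM(t)
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = HierarchicalDDM(shuffled)
        assert m1.log_posterior(group, subj0) == pytest.approx(
            m2.log_posterior(group, subj0), rel=1e-10)
        relabeled = t.copy()
        relabeled["subject"] = relabeled["subject"].map(
            {"s0": "zz", "s1": "aa", "s2": "mm"})
        m3 = HierarchicalDDM(relabeled)
        perm = [m3.pmap.subjects.index(x) for x in ("aa", "mm", "zz")]
        inv = np.argsort(perm)  # s1, s2, s0 sorted -> aa, mm, zz
        subj_perm = SubjectParams(theta={
            f: subj0.theta[f][np.array([1, 2, 0])] for f in FAMILIES})
        assert m3.log_posterior(group, subj_perm) == pytest.approx(
            m1.log_posterior(group, subj0), rel=1e-10)

    def test_kernel_matches_reference_likelihood(self, rng):
        """The numba likelihood kernel agrees with the pure-Python path,
        including censored trials."""
        trials, _ = S.generate_dataset(
            S.TruthConfig(), n_subjects=4, trials_per_cell=6,
            window_ms=630.0, censor_mode="drop", seed=5)
        model = HierarchicalDDM(trials, windows_ms={"sim": 630.0})
        group, subj = _toy_group_subjects(model.pmap, rng)
        ref = model.log_likelihood(subj)
        got = _sampler.total_loglik(
            model.starts, model.rt_s, model.choice, model.win_s,
            model.cell_index["beta"], model.cell_index["alpha"],
            model.cell_index["delta"], model.cell_index["ndt"],
            subj.theta["beta"], subj.theta["alpha"],
            subj.theta["delta"], subj.theta["ndt"], model.tol)
        assert got == pytest.approx(ref, rel=1e-9)

    def test_censoring_blind_drops_censored_rows(self):
        trials, _ = S.generate_dataset(
            S.TruthConfig(), n_subjects=4, trials_per_cell=6,
            window_ms=630.0, censor_mode="drop", seed=5)
        blind = HierarchicalDDM(trials, windows_ms={"sim": 630.0}, censoring="blind")
        assert (blind.choice >= 0).all()
        assert len(blind.choice) == int((~trials["censored"]).sum())
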