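"""Synthetic shoot/don't-shoot datasets with known ground truth.

The generator reproduces the statistical structure of the four study
designs this package targets: hierarchical truncated-normal subject
effects around condition-specific group means, drift signed by object
type, and a response deadline that either censors trials (the two
short-window studies with unrecorded late responses) or merely flags them.

Ground-truth defaults put the group means and spreads at the magnitudes
typical for this task: a start point biased toward "Shoot" (the task's
payoff structure rewards shooting), drift of about +/-2 evidence units per
second toward the correct boundary, threshold separation near 1 that
shrinks as the deadline tightens, and roughly 300 ms of non-decision time
(slightly longer for non-gun objects).  Group SDs follow the study-level
standardized-effect magnitudes for this task (e.g. a drift contrast of
0.62 at d = 1.07 implies a group SD near 0.58).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _wfpt, inference, wiener
from .hierarchy import (FAMILIES, GroupLevel, HierarchicalDDM, ParameterMap,
                        PriorConfig, VariationSpec, build_design)

__all__ = [
    "StudyPreset", "STUDY_PRESETS", "TruthConfig", "FitConfig",
    "truth_group_level", "generate_dataset", "generate_preset",
    "recovery_suite", "parameter_recovery", "write_dataset", "read_dataset",
]

#: task payoff metadata (points): not used by any simulation, recorded for
#: completeness of the presets
PAYOFFS = {"hit": 10, "correct_rejection": 5, "false_alarm": -20, "miss": -40}


@dataclass(frozen=True)
class StudyPreset:
    """Design skeleton of one study: sizes, deadline and factor layout."""

    name: str
    n_subjects: int
    trials_per_subject: int
    window_ms: float
    censor_mode: str                  # "drop", "flag" or "none"
    context: str = "none"             # "none", "between" or "within"
    blur: str = "none"                # "none" or "within"
    alpha: float = 1.1                # preset group-mean threshold separation
    payoffs: Mapping[str, int] = field(default_factory=lambda: dict(PAYOFFS))

    @property
    def n_cells(self) -> int:
        n = 4  # race x object
        if self.context == "within":
            n *= 2
        if self.blur == "within":
            n *= 2
        return n

    @property
    def trials_per_cell(self) -> int:
        return self.trials_per_subject // self.n_cells


STUDY_PRESETS: Dict[str, StudyPreset] = {
    "study1": StudyPreset("study1", 56, 100, 850.0, "drop", alpha=1.36),
    "study2": StudyPreset("study2", 116, 80, 630.0, "drop", context="between", alpha=1.04),
    "study3": StudyPreset("study3", 38, 320, 750.0, "none", context="within",
                          blur="within", alpha=1.10),
    "study4": StudyPreset("study4", 108, 320, 630.0, "none", context="within", alpha=0.99),
}


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth group-level parameters for the generator.

    ``effects`` maps (family, factor, level) to an additive shift applied to
    every group-mean cell at that factor level; this is how condition
    effects (e.g. a race effect on drift) are planted.
    """

    beta: float = 0.55
    alpha: float = 1.1
    delta_gun: float = 2.0
    delta_nongun: float = -2.0
    ndt_gun: float = 0.30
    ndt_nongun: float = 0.33
    sd: Mapping[str, float] = field(default_factory=lambda: {
        "beta": 0.059, "alpha": 0.15, "delta": 0.58, "ndt": 0.045,
    })
    effects: Mapping[Tuple[str, str, str], float] = field(default_factory=dict)

    def tau(self, family: str) -> float:
        return 1.0 / self.sd[family] ** 2


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings used by the validation suites."""

    chains: int = 2
    iterations: int = 600
    warmup: int = 600


def truth_group_level(cfg: TruthConfig, pmap: ParameterMap,
                      prior: Optional[PriorConfig] = None) -> GroupLevel:
    """Materialize a TruthConfig into per-cell group means for a design."""
    prior = prior or PriorConfig()
    base = {"beta": cfg.beta, "alpha": cfg.alpha}
    mu = {}
    for fam in FAMILIES:
        fs = pmap.factors[fam]
        vals = np.empty(pmap.n_cells(fam))
        for k, cell in enumerate(pmap.cells[fam]):
            levels = dict(zip(fs, cell))
            if fam == "delta":
                v = cfg.delta_gun if levels.get("object") == "gun" else cfg.delta_nongun
            elif fam == "ndt":
                if "object" in levels:
                    v = cfg.ndt_gun if levels["object"] == "gun" else cfg.ndt_nongun
                else:
                    v = 0.5 * (cfg.ndt_gun + cfg.ndt_nongun)
            else:
                v = base[fam]
            for (efam, factor, level), shift in cfg.effects.items():
                if efam == fam and levels.get(factor) == level:
                    v += shift
            lo, hi = prior.lo(fam), prior.hi(fam)
            if not (lo < v < hi):
                raise ValueError(
                    f"truth {fam} mean {v} for cell {cell} outside bounds ({lo}, {hi})")
            vals[k] = v
        mu[fam] = vals
    return GroupLevel(mu=mu, tau={f: cfg.tau(f) for f in FAMILIES})


def _design_scaffold(n_subjects: int, trials_per_cell: int, context: str,
                     blur: str, study: str) -> pd.DataFrame:
    """Balanced factor scaffold: one row per to-be-simulated trial."""
    subjects = [f"s{i + 1:03d}" for i in range(n_subjects)]
    within = {"race": ["black", "white"], "object": ["gun", "nongun"]}
    if context == "within":
        within["context"] = ["neutral", "dangerous"]
    if blur == "within":
        within["blur"] = ["clear", "blurred"]
    rows = []
    for si, subj in enumerate(subjects):
        ctx_between = ["neutral", "dangerous"][si % 2] if context == "between" else None
        combos = [()]
        for f, levels in within.items():
            combos = [c + ((f, l),) for c in combos for l in levels]
        for combo in combos:
            levels = dict(combo)
            for _ in range(trials_per_cell):
                rows.append({
                    "subject": subj, "study": study,
                    "race": levels["race"], "object": levels["object"],
                    "context": levels.get("context", ctx_between or "none"),
                    "blur": levels.get("blur", "none"),
                })
    return pd.DataFrame(rows)


def generate_dataset(
    truth: TruthConfig,
    n_subjects: int,
    trials_per_cell: int,
    window_ms: Optional[float],
    censor_mode: str = "none",
    seed: int = 0,
    spec: Optional[VariationSpec] = None,
    context: str = "none",
    blur: str = "none",
    study: str = "sim",
    prior: Optional[PriorConfig] = None,
    step: float = wiener.DEFAULT_STEP,
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate one full trial table plus its ground-truth sidecar.

    Subject-level parameters are drawn from truncated normals around the
    truth group means; each trial is then simulated with the subject's
    cell-specific parameters.  ``censor_mode``: "drop" removes choice and rt
    of trials slower than the window (flagging them censored), "flag" keeps
    everything but marks late trials, "none" records everything unflagged.
    """
    if censor_mode not in ("drop", "flag", "none"):
        raise ValueError("censor_mode must be 'drop', 'flag' or 'none'")
    if censor_mode != "none" and window_ms is None:
        raise ValueError(f"censor_mode {censor_mode!r} needs a finite window")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    trials = _design_scaffold(n_subjects, trials_per_cell, context, blur, study)
    pmap = build_design(_with_placeholder_outcomes(trials), spec)
    group = truth_group_level(truth, pmap, prior)

    theta = {}
    for fam in FAMILIES:
        lo, hi = prior.lo(fam), prior.hi(fam)
        if fam == "ndt":
            lo = max(lo, 0.05)  # physiologically implausible below ~50 ms
            hi = min(hi, 0.8)
        sd = truth.sd[fam]
        a = (lo - group.mu[fam]) / sd
        b = (hi - group.mu[fam]) / sd
        theta[fam] = stats.truncnorm.rvs(
            a[None, :], b[None, :], loc=group.mu[fam][None, :], scale=sd,
            size=(n_subjects, pmap.n_cells(fam)), random_state=rng)

    si = pmap.subject_index
    a_t = theta["alpha"][si, pmap.cell_index["alpha"]]
    v_t = theta["delta"][si, pmap.cell_index["delta"]]
    w_t = theta["beta"][si, pmap.cell_index["beta"]]
    n_t = theta["ndt"][si, pmap.cell_index["ndt"]]
    sim_window = np.inf if (window_ms is None or censor_mode != "drop") else window_ms / 1000.0
    choice, rt_s = _wfpt.simulate_table(
        a_t, v_t, w_t, n_t, step, sim_window, int(rng.integers(2**31 - 1)))

    rt_ms = rt_s * 1000.0
    censored = choice < 0
    if censor_mode == "flag":
        censored = rt_ms > window_ms
    elif censor_mode == "none":
        censored = np.zeros(len(trials), bool)
    out = trials.copy()
    out["choice"] = np.where(choice == 1, "shoot", np.where(choice == 0, "dontshoot", ""))
    out["rt_ms"] = rt_ms
    out["censored"] = censored
    if censor_mode == "drop":
        out.loc[censored, "choice"] = ""
        out.loc[censored, "rt_ms"] = np.nan

    truth_sidecar = {
        "seed": int(seed),
        "study": study,
        "window_ms": window_ms,
        "censor_mode": censor_mode,
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(truth).items()
                   if k != "effects"},
        "effects": {"|".join(k): v for k, v in truth.effects.items()},
        "cells": {f: [list(c) for c in pmap.cells[f]] for f in FAMILIES},
        "group_mu": {f: group.mu[f].tolist() for f in FAMILIES},
        "tau": {f: group.tau[f] for f in FAMILIES},
        "subjects": pmap.subjects,
        "subject_theta": {f: theta[f].tolist() for f in FAMILIES},
    }
    return out, truth_sidecar


def _with_placeholder_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials.copy()
    t["choice"] = "shoot"
    t["rt_ms"] = 500.0
    t["censored"] = False
    return t


def generate_preset(
    name: str,
    seed: int = 0,
    truth: Optional[TruthConfig] = None,
    n_subjects: Optional[int] = None,
    trials_per_cell: Optional[int] = None,
    **kwargs,
) -> Tuple[pd.DataFrame, Dict]:
    """Generate a dataset following one of the four study presets."""
    preset = STUDY_PRESETS[name]
    cfg = truth if truth is not None else TruthConfig(alpha=preset.alpha)
    return generate_dataset(
        cfg,
        n_subjects=n_subjects or preset.n_subjects,
        trials_per_cell=trials_per_cell or preset.trials_per_cell,
        window_ms=preset.window_ms,
        censor_mode=preset.censor_mode,
        seed=seed,
        context=preset.context,
        blur=preset.blur,
        study=name,
        **kwargs,
    )


def write_dataset(trials: pd.DataFrame, truth: Dict, path) -> None:
    """Write the trial table as CSV with the ground truth in a JSON sidecar."""
    path = Path(path)
    trials.to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)


def read_dataset(path) -> Tuple[pd.DataFrame, Optional[Dict]]:
    path = Path(path)
    trials = pd.read_csv(path, keep_default_na=False,
                         na_values=[""], dtype={"choice": str})
    trials["choice"] = trials["choice"].fillna("")
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    truth = None
    if sidecar.exists():
        with open(sidecar) as fh:
            truth = json.load(fh)
    return trials, truth


# ---------------------------------------------------------------------------
# validation suites
# ---------------------------------------------------------------------------

#: planted effect sizes at the scale of the study-level reported contrasts
DEFAULT_EFFECTS = {"beta": 0.05, "delta": 0.5, "alpha": 0.1}

SETTINGS = {
    "start_point_only": ("beta",),
    "drift_only": ("delta",),
    "drift_plus_threshold": ("delta", "alpha"),
}


def recovery_suite(
    setting: str,
    n_datasets: int = 20,
    effect_sizes: Optional[Mapping[str, float]] = None,
    fit_config: Optional[FitConfig] = None,
    seed: int = 0,
    n_subjects: int = 25,
    trials_per_cell: int = 20,
) -> Dict:
    """Selective-influence check: does the fit localize a planted effect?

    For each replicate dataset an effect of the configured size is planted
    on the race factor in the setting's parameter(s) only; the full
    hierarchical model is then fit and a family counts as "identified" when
    the 95% HDI of its group-level race contrast (marginalized over the
    other factors) excludes zero.  Reports per-family identification
    counts, the true-effect identification rate and the false-identification
    rate across parameters with no planted effect.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {sorted(SETTINGS)}")
    planted = SETTINGS[setting]
    sizes = dict(DEFAULT_EFFECTS)
    if effect_sizes:
        sizes.update(effect_sizes)
    fc = fit_config or FitConfig()
    effects = {(fam, "race", "black"): sizes[fam] for fam in planted}
    truth = TruthConfig(effects=effects)
    counts = {f: 0 for f in FAMILIES}
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(sorted(SETTINGS).index(setting),))
    sub_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(2 * n_datasets, np.uint64)]
    for r in range(n_datasets):
        trials, _ = generate_dataset(
            truth, n_subjects=n_subjects, trials_per_cell=trials_per_cell,
            window_ms=None, censor_mode="none", seed=sub_seeds[2 * r])
        model = HierarchicalDDM(trials)
        draws = inference.sample_posterior(
            model, chains=fc.chains, iterations=fc.iterations,
            warmup=fc.warmup, seed=sub_seeds[2 * r + 1])
        for fam in FAMILIES:
            c = inference.marginal_contrast(draws, fam, "race", "black", "white")
            if c.excludes_zero:
                counts[fam] += 1
    rates = {f: counts[f] / n_datasets for f in FAMILIES}
    return {
        "setting": setting,
        "n_datasets": n_datasets,
        "n_subjects": n_subjects,
        "trials_per_cell": trials_per_cell,
        "effect_sizes": {f: sizes[f] for f in planted},
        "identified": counts,
        "rates": rates,
        "true_rate": float(np.mean([rates[f] for f in planted])),
        "false_rate": float(np.mean([rates[f] for f in FAMILIES if f not in planted])),
    }


def parameter_recovery(truth: Dict, draws: inference.PosteriorDraws) -> Dict:
    """Bias, HDI coverage and posterior-mean correlation against ground truth.

    ``truth`` is the sidecar written by :func:`generate_dataset`; the draws
    must come from a fit of that dataset with the same parameter map.
    """
    out = {}
    n_cover = n_total = 0
    for fam in FAMILIES:
        cells = [tuple(c) for c in truth["cells"][fam]]
        if cells != [tuple(c) for c in draws.cells[fam]]:
            raise ValueError(f"parameter map mismatch for {fam}")
        mu_true = np.asarray(truth["group_mu"][fam])
        arr = draws.group[fam]
        biases, covered = [], []
        for k in range(len(cells)):
            x = arr[:, :, k].reshape(-1)
            lo, hi = inference.hdi(x)
            biases.append(float(x.mean() - mu_true[k]))
            covered.append(bool(lo <= mu_true[k] <= hi))
        th_true = np.asarray(truth["subject_theta"][fam])
        th_mean = draws.subject[fam].mean(axis=(0, 1))
        corr = float(np.corrcoef(th_true.ravel(), th_mean.ravel())[0, 1])
        out[fam] = {
            "group_bias": biases,
            "group_coverage": float(np.mean(covered)),
            "n_cells": len(cells),
            "subject_corr": corr,
        }
        n_cover += int(np.sum(covered))
        n_total += len(covered)
    out["overall_group_coverage"] = n_cover / n_total
    out["n_group_params"] = n_total
    return out
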