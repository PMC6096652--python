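"""Hierarchical model structure for trial-level shoot/don't-shoot data.

The model follows the standard hierarchical parameterization for this task:
each subject holds one value of each process parameter per design cell,
drawn from a truncated normal around a condition-specific group mean with a
parameter-level group precision,

    theta_{i,j} ~ N(mu_i, 1/tau)   truncated to the parameter's bounds.

Group means get uniform hyperpriors over the truncation bounds and the
precisions get gamma hyperpriors.  Start point and threshold separation are
never allowed to vary by object type (with only one stimulus class on each
side of the start point the start point would not be identified); drift and
non-decision time may.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import wiener
from .wiener import DDMParams, TrialOutcome

FAMILIES = ("beta", "alpha", "delta", "ndt")

#: factor columns of the trial table that parameters may vary over
FACTORS = ("race", "object", "context", "blur", "study")

RACE_LEVELS = ("black", "white")
OBJECT_LEVELS = ("gun", "nongun")
CHOICE_LEVELS = ("shoot", "dontshoot")


class SchemaError(ValueError):
    """Raised when a trial table or variation spec is malformed."""


class IdentifiabilityError(ValueError):
    """Raised for parameter maps the design cannot identify."""


@dataclass(frozen=True)
class VariationSpec:
    """Which design factors each process parameter's group mean varies over."""

    beta: Tuple[str, ...] = ("race",)
    alpha: Tuple[str, ...] = ("race",)
    delta: Tuple[str, ...] = ("race", "object")
    ndt: Tuple[str, ...] = ("race", "object")

    def factors(self, family: str) -> Tuple[str, ...]:
        return getattr(self, family)

    def validate(self) -> None:
        for family in FAMILIES:
            for f in self.factors(family):
                if f not in FACTORS:
                    raise SchemaError(f"unknown design factor {f!r} for {family}")
        for family in ("beta", "alpha"):
            if "object" in self.factors(family):
                raise IdentifiabilityError(
                    f"{family} cannot vary by object: estimating the relative "
                    "start point requires both stimulus classes within a cell"
                )

    @classmethod
    def for_trials(cls, trials: pd.DataFrame, include_study: bool = False) -> "VariationSpec":
        """Default map: every factor with >1 observed level, object only on delta/ndt."""
        shared = ["race"]
        for f in ("context", "blur"):
            levels = set(trials[f].unique()) - {"none"}
            if len(levels) > 1:
                shared.append(f)
        if include_study and trials["study"].nunique() > 1:
            shared.append("study")
        return cls(
            beta=tuple(shared),
            alpha=tuple(shared),
            delta=tuple(shared) + ("object",),
            ndt=tuple(shared) + ("object",),
        )


@dataclass
class ParameterMap:
    """Trial-to-cell index structure for each parameter family."""

    spec: VariationSpec
    subjects: List
    subject_index: np.ndarray            # per trial
    factors: Dict[str, Tuple[str, ...]]
    cells: Dict[str, List[Tuple[str, ...]]]
    cell_index: Dict[str, np.ndarray]    # per trial, per family

    def n_cells(self, family: str) -> int:
        return max(len(self.cells[family]), 1)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def cell_label(self, family: str, k: int) -> str:
        fs = self.factors[family]
        if not fs:
            return "all"
        return ",".join(f"{f}={l}" for f, l in zip(fs, self.cells[family][k]))

    def cell_labels(self, family: str) -> List[str]:
        return [self.cell_label(family, k) for k in range(self.n_cells(family))]

    def find_cell(self, family: str, **levels: str) -> int:
        fs = self.factors[family]
        unknown = set(levels) - set(fs)
        if unknown:
            raise KeyError(f"{family} does not vary over {sorted(unknown)}")
        if set(levels) != set(fs):
            raise KeyError(f"cell lookup for {family} must fix all of {fs}")
        key = tuple(levels[f] for f in fs)
        try:
            return self.cells[family].index(key)
        except ValueError:
            raise KeyError(f"no {family} cell {key}") from None

    def matching_cells(self, family: str, **levels: str) -> List[int]:
        """Cells whose levels agree with the given partial assignment."""
        fs = self.factors[family]
        out = []
        for k, cell in enumerate(self.cells[family]):
            if all(cell[fs.index(f)] == l for f, l in levels.items() if f in fs):
                out.append(k)
        return out


def build_design(trials: pd.DataFrame, spec: Optional[VariationSpec] = None) -> ParameterMap:
    """Index each trial into its beta/alpha/delta/ndt design cells."""
    if len(trials) == 0:
        raise SchemaError("trial table is empty")
    spec = VariationSpec.for_trials(trials) if spec is None else spec
    spec.validate()
    for col in ("subject",) + FACTORS:
        if col not in trials.columns:
            raise SchemaError(f"trial table lacks required column {col!r}")
    if not set(trials["race"]).issubset(RACE_LEVELS):
        raise SchemaError(f"unknown race levels {set(trials['race']) - set(RACE_LEVELS)}")
    if not set(trials["object"]).issubset(OBJECT_LEVELS):
        raise SchemaError(f"unknown object levels {set(trials['object']) - set(OBJECT_LEVELS)}")

    subjects = sorted(trials["subject"].unique().tolist())
    subj_pos = {s: i for i, s in enumerate(subjects)}
    subject_index = trials["subject"].map(subj_pos).to_numpy(np.int32)

    factors, cells, cell_index = {}, {}, {}
    for family in FAMILIES:
        fs = spec.factors(family)
        factors[family] = fs
        if not fs:
            cells[family] = [()]
            cell_index[family] = np.zeros(len(trials), np.int32)
            continue
        combos = sorted(set(map(tuple, trials[list(fs)].astype(str).itertuples(index=False))))
        cells[family] = combos
        lookup = {c: i for i, c in enumerate(combos)}
        idx = [lookup[t] for t in map(tuple, trials[list(fs)].astype(str).itertuples(index=False))]
        cell_index[family] = np.asarray(idx, np.int32)
    return ParameterMap(
        spec=spec, subjects=subjects, subject_index=subject_index,
        factors=factors, cells=cells, cell_index=cell_index,
    )


@dataclass(frozen=True)
class PriorConfig:
    """Truncation bounds and hyperprior constants.

    Subject-level bounds: the start point is truncated to [.1, .9]; threshold
    separation, drift and NDT bounds are set wide around the plausible region
    for this task.  Each subject's NDT is additionally capped just below the
    subject's fastest observed response.  Group means are uniform over the
    same bounds; group precisions get a vague Gamma(0.001, 0.001) prior.
    """

    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "beta": (0.1, 0.9),
        "alpha": (0.05, 5.0),
        "delta": (-9.0, 9.0),
        "ndt": (0.0, 1.0),
    })
    tau_shape: float = 0.001
    tau_rate: float = 0.001

    def lo(self, family: str) -> float:
        return self.bounds[family][0]

    def hi(self, family: str) -> float:
        return self.bounds[family][1]


@dataclass
class GroupLevel:
    """Group means per condition cell and one precision per parameter family."""

    mu: Dict[str, np.ndarray]
    tau: Dict[str, float]

    def sd(self, family: str) -> float:
        return 1.0 / np.sqrt(self.tau[family])


@dataclass
class SubjectParams:
    """Subject-level parameter values, shaped (n_subjects, n_cells) per family."""

    theta: Dict[str, np.ndarray]


def _truncnorm_logpdf(x, mu, tau, lo, hi):
    sd = 1.0 / np.sqrt(tau)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.logpdf(x, a, b, loc=mu, scale=sd)


class HierarchicalDDM:
    """Assembled joint model: data, design, priors and the log posterior.

    Parameters
    ----------
    trials : DataFrame
        Trial table with columns subject, study, race, object, context,
        blur, choice ("shoot"/"dontshoot", empty for censored), rt_ms,
        censored.
    windows_ms : mapping study -> window in ms (or None for unbounded).
    spec : VariationSpec, optional
    prior : PriorConfig, optional
    censoring : {"aware", "blind"}
        "aware" keeps censored trials in the likelihood through their
        survivor mass; "blind" discards them (deliberately mis-specified
        fit used to demonstrate the censoring artefact).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        windows_ms: Optional[Mapping[str, Optional[float]]] = None,
        spec: Optional[VariationSpec] = None,
        prior: Optional[PriorConfig] = None,
        censoring: str = "aware",
        tol: float = wiener.DEFAULT_TOL,
    ) -> None:
        if censoring not in ("aware", "blind"):
            raise ValueError("censoring must be 'aware' or 'blind'")
        trials = trials.reset_index(drop=True)
        if censoring == "blind":
            trials = trials.loc[~trials["censored"].astype(bool)].reset_index(drop=True)
        self.censoring = censoring
        self.trials = trials
        self.pmap = build_design(trials, spec)
        self.prior = prior if prior is not None else PriorConfig()
        self.tol = tol
        self.windows_ms = dict(windows_ms or {})
        self._pack()

    def _pack(self) -> None:
        t = self.trials
        pm = self.pmap
        order = np.argsort(pm.subject_index, kind="stable")
        self._order = order
        self.subject_index = pm.subject_index[order]
        J = pm.n_subjects
        counts = np.bincount(self.subject_index, minlength=J)
        self.starts = np.zeros(J + 1, np.int64)
        self.starts[1:] = np.cumsum(counts)

        cens = t["censored"].astype(bool).to_numpy()[order]
        rt_ms = pd.to_numeric(t["rt_ms"], errors="coerce").to_numpy(float)[order]
        choice_raw = t["choice"].astype(str).to_numpy()[order]
        choice = np.full(len(t), -1, np.int8)
        choice[(~cens) & (choice_raw == "shoot")] = 1
        choice[(~cens) & (choice_raw == "dontshoot")] = 0
        if np.any((~cens) & (choice < 0)):
            raise SchemaError("non-censored trials must have choice 'shoot' or 'dontshoot'")
        self.choice = choice
        self.rt_s = np.where(cens, np.nan, rt_ms / 1000.0)
        if np.any((~cens) & ~(rt_ms > 0)):
            raise SchemaError("observed trials must have rt_ms > 0")

        win = np.full(len(t), np.inf)
        study = t["study"].astype(str).to_numpy()[order]
        for s, w in self.windows_ms.items():
            if w is not None:
                win[study == str(s)] = w / 1000.0
        if np.any(cens & ~np.isfinite(win)):
            raise SchemaError("censored trials require a finite response window")
        self.win_s = win
        # studies whose recording censors at the deadline (late responses
        # unrecorded) are recognized by the presence of censored rows; for
        # the others the window is metadata only
        censoring_studies = set(study[cens])
        self.censor_applies = np.isin(study, sorted(censoring_studies))

        self.cell_index = {f: pm.cell_index[f][order] for f in FAMILIES}
        self.presence = {}
        for f in FAMILIES:
            pres = np.zeros((J, pm.n_cells(f)), bool)
            pres[self.subject_index, self.cell_index[f]] = True
            self.presence[f] = pres

        # subject NDT upper bound: just below the fastest observed response
        hi = np.full(J, self.prior.hi("ndt"))
        obs = ~cens
        for j in range(J):
            sl = slice(self.starts[j], self.starts[j + 1])
            r = self.rt_s[sl][obs[sl]]
            if r.size:
                hi[j] = min(hi[j], float(r.min()))
        self.ndt_hi = hi

    # ------------------------------------------------------------------
    # reference (non-vectorized) posterior pieces, used by tests and DIC
    # ------------------------------------------------------------------

    def log_prior(self, group: GroupLevel, subjects: SubjectParams) -> float:
        # the subject NDT <= min rt constraint lives in the likelihood, not
        # in the prior truncation, so the truncation normalizer is shared
        return log_prior(group, subjects, self.pmap, self.prior,
                         presence=self.presence)

    def trial_params(self, subjects: SubjectParams, i: int) -> DDMParams:
        """Assemble the DDMParams acting on packed trial i."""
        j = self.subject_index[i]
        return DDMParams(
            beta=float(subjects.theta["beta"][j, self.cell_index["beta"][i]]),
            alpha=float(subjects.theta["alpha"][j, self.cell_index["alpha"][i]]),
            delta=float(subjects.theta["delta"][j, self.cell_index["delta"][i]]),
            ndt=float(subjects.theta["ndt"][j, self.cell_index["ndt"][i]]),
        )

    def log_likelihood(self, subjects: SubjectParams) -> float:
        total = 0.0
        for i in range(len(self.choice)):
            p = self.trial_params(subjects, i)
            w = None if not np.isfinite(self.win_s[i]) else self.win_s[i] * 1000.0
            if self.choice[i] < 0:
                out = TrialOutcome(boundary=None, rt_ms=None)
            else:
                b = wiener.UPPER if self.choice[i] == 1 else wiener.LOWER
                out = TrialOutcome(boundary=b, rt_ms=self.rt_s[i] * 1000.0)
            total += wiener.trial_loglik(out, p, window_ms=w, tol=self.tol)
            if total == -np.inf:
                return -np.inf
        return total

    def log_posterior(self, group: GroupLevel, subjects: SubjectParams) -> float:
        lp = self.log_prior(group, subjects)
        if lp == -np.inf:
            return -np.inf
        return lp + self.log_likelihood(subjects)


def log_prior(
    group: GroupLevel,
    subjects: SubjectParams,
    pmap: ParameterMap,
    prior: PriorConfig,
    ndt_hi: Optional[np.ndarray] = None,
    presence: Optional[Mapping[str, np.ndarray]] = None,
) -> float:
    """Joint log prior: truncated-normal subject terms + uniform/gamma hyperpriors.

    Returns -inf for any configuration outside the support.
    """
    total = 0.0
    J = pmap.n_subjects
    for f in FAMILIES:
        lo, hi = prior.lo(f), prior.hi(f)
        mu = np.asarray(group.mu[f], float)
        tau = float(group.tau[f])
        th = np.asarray(subjects.theta[f], float)
        if mu.shape != (pmap.n_cells(f),) or th.shape != (J, pmap.n_cells(f)):
            raise ValueError(f"shape mismatch for {f}")
        if tau <= 0 or np.any(mu < lo) or np.any(mu > hi):
            return -np.inf
        total += stats.gamma.logpdf(tau, prior.tau_shape, scale=1.0 / prior.tau_rate)
        total += -len(mu) * np.log(hi - lo)  # uniform hyperprior on each mean
        pres = None if presence is None else presence[f]
        for j in range(J):
            hij = hi
            if f == "ndt" and ndt_hi is not None:
                hij = min(hi, float(ndt_hi[j]))
            for k in range(pmap.n_cells(f)):
                if pres is not None and not pres[j, k]:
                    continue
                x = th[j, k]
                if not (lo <= x <= hij):
                    return -np.inf
                total += _truncnorm_logpdf(x, mu[k], tau, lo, hij)
    if not np.isfinite(total):
        return -np.inf
    return float(total)
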