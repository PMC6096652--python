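"""Posterior sampling and the summaries drawn from it.

Provides the adaptive Metropolis-within-Gibbs driver for the hierarchical
drift-diffusion model (and a generic coordinate sampler for small custom
targets), the shortest-interval HDI, condition contrasts with standardized
effects d = (mu_A - mu_B) * sqrt(tau), DIC model comparison, and posterior
predictive checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import _sampler, _wfpt
from .hierarchy import FAMILIES, GroupLevel, HierarchicalDDM, SubjectParams

__all__ = [
    "PosteriorDraws", "ContrastSummary", "InitializationError",
    "sample_posterior", "adaptive_mwg", "hdi", "contrast", "marginal_contrast",
    "dic", "posterior_predictive", "rhat", "ess",
]


class InitializationError(RuntimeError):
    """No finite-posterior starting configuration could be drawn."""


@dataclass
class PosteriorDraws:
    """Labeled MCMC sample with chain structure.

    ``group[name]`` has shape (chains, draws, n_cells); ``tau[name]`` has
    shape (chains, draws); ``subject[name]`` (chains, draws, n_subjects,
    n_cells) where kept.  ``cells``/``factors`` describe the design cells of
    each parameter family; ``meta`` records sampler settings.
    """

    group: Dict[str, np.ndarray]
    tau: Dict[str, np.ndarray]
    cells: Dict[str, List[Tuple[str, ...]]]
    factors: Dict[str, Tuple[str, ...]]
    subject: Dict[str, np.ndarray] = field(default_factory=dict)
    subjects: List = field(default_factory=list)
    meta: Dict = field(default_factory=dict)
    log_likelihood: Optional[np.ndarray] = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.group.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.group.values())).shape[1]

    def find_cell(self, family: str, **levels: str) -> int:
        fs = self.factors[family]
        if set(levels) != set(fs):
            raise KeyError(f"cell lookup for {family} must fix all of {fs}")
        key = tuple(str(levels[f]) for f in fs)
        try:
            return self.cells[family].index(key)
        except ValueError:
            raise KeyError(f"no {family} cell {key}") from None

    def matching_cells(self, family: str, **levels: str) -> List[int]:
        fs = self.factors[family]
        out = []
        for k, cell in enumerate(self.cells[family]):
            if all(cell[fs.index(f)] == str(l) for f, l in levels.items() if f in fs):
                out.append(k)
        return out

    def cell_label(self, family: str, k: int) -> str:
        fs = self.factors[family]
        if not fs:
            return "all"
        return ",".join(f"{f}={l}" for f, l in zip(fs, self.cells[family][k]))

    def group_flat(self, family: str, k: int) -> np.ndarray:
        return self.group[family][:, :, k].reshape(-1)

    def tau_flat(self, family: str) -> np.ndarray:
        return self.tau[family].reshape(-1)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, HDI, split-Rhat and ESS for every group-level mean."""
        rows = []
        for fam, arr in self.group.items():
            for k in range(arr.shape[2]):
                x = arr[:, :, k]
                lo, hi_ = hdi(x.reshape(-1), mass)
                rows.append({
                    "parameter": fam, "cell": self.cell_label(fam, k),
                    "mean": float(x.mean()), "hdi_lo": lo, "hdi_hi": hi_,
                    "rhat": rhat(x), "ess": ess(x),
                })
        for fam, arr in self.tau.items():
            lo, hi_ = hdi(arr.reshape(-1), mass)
            rows.append({
                "parameter": f"tau_{fam}", "cell": "all",
                "mean": float(arr.mean()), "hdi_lo": lo, "hdi_hi": hi_,
                "rhat": rhat(arr), "ess": ess(arr),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior difference between two condition cells of one parameter."""

    family: str
    label_a: str
    label_b: str
    mean: float
    hdi_lo: float
    hdi_hi: float
    d_mean: float
    d_hdi_lo: float
    d_hdi_hi: float

    @property
    def excludes_zero(self) -> bool:
        return self.hdi_lo > 0.0 or self.hdi_hi < 0.0


def hdi(draws: Sequence[float], mass: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass*n) sorted draws.

    Ties between equally short intervals resolve to the earliest one.
    """
    x = np.sort(np.asarray(draws, float).reshape(-1))
    n = x.size
    if n < 2:
        if n == 1:
            return float(x[0]), float(x[0])
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum
    return float(x[i]), float(x[i + m - 1])


def rhat(x: np.ndarray) -> float:
    """Split-Rhat of a (chains, draws) array."""
    import arviz as az
    return float(az.rhat(az.convert_to_dataset(np.asarray(x)))["x"].values)


def ess(x: np.ndarray) -> float:
    """Bulk effective sample size of a (chains, draws) array."""
    import arviz as az
    return float(az.ess(az.convert_to_dataset(np.asarray(x)))["x"].values)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _init_state(model: HierarchicalDDM, rng: np.random.Generator):
    pm, pr = model.pmap, model.prior
    J = pm.n_subjects
    eps = 1e-3
    mus, taus = {}, {}
    base_tau = {"beta": 150.0, "alpha": 30.0, "delta": 3.0, "ndt": 300.0}
    rng_ranges = {
        "beta": (0.35, 0.7),
        "alpha": (0.6, 2.0),
        "delta": (-2.5, 2.5),
        "ndt": (0.1, min(0.45, 0.8 * float(np.min(model.ndt_hi)))),
    }
    theta = {}
    for f in FAMILIES:
        K = pm.n_cells(f)
        lo_r, hi_r = rng_ranges[f]
        mus[f] = rng.uniform(lo_r, max(hi_r, lo_r + 1e-3), K)
        taus[f] = base_tau[f] * math.exp(rng.uniform(-0.5, 0.5))
        sd = 0.5 / math.sqrt(taus[f])
        th = mus[f][None, :] + rng.normal(0.0, sd, (J, K))
        lo, hi = pr.lo(f), pr.hi(f)
        hi_j = np.full(J, hi)
        if f == "ndt":
            hi_j = np.minimum(hi_j, model.ndt_hi - 0.005)
        th = np.clip(th, lo + eps, hi_j[:, None] - eps)
        theta[f] = th
    return GroupLevel(mu=mus, tau=taus), SubjectParams(theta=theta)


def sample_posterior(
    model: Union[HierarchicalDDM, Callable[[np.ndarray], float]],
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    x0: Optional[np.ndarray] = None,
) -> PosteriorDraws:
    """Sample the joint posterior of an assembled model.

    A :class:`HierarchicalDDM` is sampled with the blocked numba kernel; any
    callable log-density is sampled with the generic coordinate sampler (the
    callable route exists for small custom targets and for validating the
    machinery against closed forms).  Identical seeds give identical draws.
    """
    if chains < 1 or iterations < 1 or warmup < 0:
        raise ValueError("counts must be positive")
    if isinstance(model, HierarchicalDDM):
        return _sample_ddm(model, chains, iterations, warmup, seed)
    if x0 is None:
        raise ValueError("generic targets need an initial point x0")
    all_draws = []
    for c in range(chains):
        d, _ = adaptive_mwg(model, np.asarray(x0, float), warmup, iterations,
                            seed=seed * 1000003 % (2**31 - 1) + c)
        all_draws.append(d)
    arr = np.stack(all_draws)  # (chains, draws, dim)
    dim = arr.shape[2]
    return PosteriorDraws(
        group={"x": arr},
        tau={},
        cells={"x": [(str(i),) for i in range(dim)]},
        factors={"x": ("index",)},
        meta={"seed": seed, "warmup": warmup, "iterations": iterations, "chains": chains},
    )


def _sample_ddm(model: HierarchicalDDM, chains: int, iterations: int,
                warmup: int, seed: int) -> PosteriorDraws:
    pm, pr = model.pmap, model.prior
    J = pm.n_subjects
    lo4 = np.array([pr.lo(f) for f in FAMILIES])
    muhi4 = np.array([pr.hi(f) for f in FAMILIES])
    # subject NDTs are bounded by each subject's fastest response through the
    # likelihood itself (rt - ndt <= 0 has zero density), so the prior keeps
    # the fixed family bounds and its normalizer stays subject-independent
    hi_subj = {f: np.full(J, pr.hi(f)) for f in FAMILIES}
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(chains, np.uint64)]

    out = {f: [] for f in FAMILIES}
    out_tau, out_subj, out_ll = [], {f: [] for f in FAMILIES}, []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c,)))
        group = subjects = None
        for _ in range(100):
            group, subjects = _init_state(model, rng)
            ll = _sampler.total_loglik(
                model.starts, model.rt_s, model.choice, model.win_s,
                model.cell_index["beta"], model.cell_index["alpha"],
                model.cell_index["delta"], model.cell_index["ndt"],
                subjects.theta["beta"], subjects.theta["alpha"],
                subjects.theta["delta"], subjects.theta["ndt"], model.tol)
            if np.isfinite(ll) and np.isfinite(model.log_prior(group, subjects)):
                break
        else:
            raise InitializationError(
                "could not find a finite-posterior initial state in 100 draws; "
                "check response windows, rt units and truncation bounds")
        res = _sampler.run_chain(
            chain_seeds[c], warmup, iterations,
            model.starts, model.rt_s, model.choice, model.win_s,
            model.cell_index["beta"], model.cell_index["alpha"],
            model.cell_index["delta"], model.cell_index["ndt"],
            model.presence["beta"], model.presence["alpha"],
            model.presence["delta"], model.presence["ndt"],
            lo4, hi_subj["beta"], hi_subj["alpha"], hi_subj["delta"], hi_subj["ndt"],
            lo4, muhi4, pr.tau_shape, pr.tau_rate, model.tol,
            subjects.theta["beta"].copy(), subjects.theta["alpha"].copy(),
            subjects.theta["delta"].copy(), subjects.theta["ndt"].copy(),
            np.asarray(group.mu["beta"]).copy(), np.asarray(group.mu["alpha"]).copy(),
            np.asarray(group.mu["delta"]).copy(), np.asarray(group.mu["ndt"]).copy(),
            np.array([group.tau[f] for f in FAMILIES]))
        muB_d, muA_d, muD_d, muN_d, tau_d, B_d, A_d, D_d, N_d, ll_d = res
        for f, arr in zip(FAMILIES, (muB_d, muA_d, muD_d, muN_d)):
            out[f].append(arr)
        for f, arr in zip(FAMILIES, (B_d, A_d, D_d, N_d)):
            out_subj[f].append(arr)
        out_tau.append(tau_d)
        out_ll.append(ll_d)

    tau_all = np.stack(out_tau)  # (chains, draws, 4)
    return PosteriorDraws(
        group={f: np.stack(out[f]) for f in FAMILIES},
        tau={f: tau_all[:, :, i] for i, f in enumerate(FAMILIES)},
        subject={f: np.stack(out_subj[f]) for f in FAMILIES},
        cells={f: [tuple(map(str, c)) for c in pm.cells[f]] for f in FAMILIES},
        factors={f: pm.factors[f] for f in FAMILIES},
        subjects=list(pm.subjects),
        meta={"seed": seed, "warmup": warmup, "iterations": iterations,
              "chains": chains, "censoring": model.censoring},
        log_likelihood=np.stack(out_ll),
    )


def adaptive_mwg(
    logpdf: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_warmup: int,
    n_keep: int,
    seed: int,
    scales: Optional[np.ndarray] = None,
    blocks: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[np.ndarray, Dict]:
    """Generic adaptive coordinate random-walk Metropolis sampler.

    Suitable for cheap likelihoods (the signal-detection baseline, toy
    targets); the full log density is re-evaluated for each coordinate
    proposal.  ``blocks`` optionally lists index groups that additionally
    receive joint translation moves (all coordinates in a block shifted by
    one scalar), which de-correlates hierarchical location ridges such as
    a group mean moving with its subject values.  Returns (draws with
    shape (n_keep, dim), info dict).
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, float, copy=True)
    dim = x.size
    s = np.full(dim, 0.5) if scales is None else np.array(scales, float, copy=True)
    blocks = [np.asarray(b, int) for b in (blocks or [])]
    bs = np.full(len(blocks), 0.5)
    lp = float(logpdf(x))
    if not np.isfinite(lp):
        raise InitializationError("x0 has non-finite log density")
    draws = np.empty((n_keep, dim))
    acc = np.zeros(dim)
    bacc = np.zeros(len(blocks))
    batch, n_batches = 50, 0
    for it in range(n_warmup + n_keep):
        for i in range(dim):
            old = x[i]
            x[i] = old + s[i] * rng.normal()
            lp_new = float(logpdf(x))
            if math.log(rng.random()) < lp_new - lp:
                lp = lp_new
                acc[i] += 1
            else:
                x[i] = old
        for bi, idx in enumerate(blocks):
            eps = bs[bi] * rng.normal()
            x[idx] += eps
            lp_new = float(logpdf(x))
            if math.log(rng.random()) < lp_new - lp:
                lp = lp_new
                bacc[bi] += 1
            else:
                x[idx] -= eps
        if it < n_warmup and (it + 1) % batch == 0:
            n_batches += 1
            step = min(0.25, 1.0 / math.sqrt(n_batches))
            s *= np.exp(np.where(acc / batch > 0.44, step, -step))
            acc[:] = 0
            if len(blocks):
                bs *= np.exp(np.where(bacc / batch > 0.3, step, -step))
                bacc[:] = 0
        if it >= n_warmup:
            draws[it - n_warmup] = x
    return draws, {"scales": s, "acc": acc / max(n_keep, 1)}


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _contrast_from_diff(draws: PosteriorDraws, family: str, diff: np.ndarray,
                        label_a: str, label_b: str, mass: float) -> ContrastSummary:
    if family in draws.tau:
        d = diff * np.sqrt(draws.tau_flat(family))
    else:
        d = np.zeros_like(diff)
    lo, hi_ = hdi(diff, mass)
    dlo, dhi = hdi(d, mass)
    return ContrastSummary(
        family=family, label_a=label_a, label_b=label_b,
        mean=float(diff.mean()), hdi_lo=lo, hdi_hi=hi_,
        d_mean=float(d.mean()), d_hdi_lo=dlo, d_hdi_hi=dhi,
    )


def contrast(
    draws: PosteriorDraws,
    family: str,
    cell_a: Union[int, Mapping[str, str]],
    cell_b: Union[int, Mapping[str, str]],
    mass: float = 0.95,
) -> ContrastSummary:
    """Posterior contrast mu_A - mu_B with its 95% HDI and standardized d.

    d is computed draw-wise as (mu_A - mu_B) * sqrt(tau): the group-mean
    difference in units of the group-level standard deviation.
    """
    ka = cell_a if isinstance(cell_a, (int, np.integer)) else draws.find_cell(family, **cell_a)
    kb = cell_b if isinstance(cell_b, (int, np.integer)) else draws.find_cell(family, **cell_b)
    diff = draws.group_flat(family, ka) - draws.group_flat(family, kb)
    return _contrast_from_diff(draws, family, diff,
                               draws.cell_label(family, ka), draws.cell_label(family, kb), mass)


def marginal_contrast(
    draws: PosteriorDraws,
    family: str,
    factor: str,
    level_a: str,
    level_b: str,
    mass: float = 0.95,
    fixed: Optional[Mapping[str, str]] = None,
) -> ContrastSummary:
    """Level contrast on one factor, averaged over the family's other factors.

    Cells are matched into pairs that differ only in ``factor``; the
    contrast is the mean of the paired differences.
    """
    fs = draws.factors[family]
    if factor not in fs:
        raise KeyError(f"{family} does not vary over {factor!r}")
    fixed = dict(fixed or {})
    fi = fs.index(factor)
    pairs = []
    for ka, cell in enumerate(draws.cells[family]):
        if cell[fi] != str(level_a):
            continue
        if any(cell[fs.index(f)] != str(l) for f, l in fixed.items() if f in fs):
            continue
        partner = tuple(str(level_b) if i == fi else c for i, c in enumerate(cell))
        try:
            kb = draws.cells[family].index(partner)
        except ValueError:
            continue
        pairs.append((ka, kb))
    if not pairs:
        raise KeyError(f"no {factor} {level_a}/{level_b} cell pairs for {family}")
    diff = np.mean(
        [draws.group_flat(family, ka) - draws.group_flat(family, kb) for ka, kb in pairs],
        axis=0)
    return _contrast_from_diff(
        draws, family, diff,
        f"{factor}={level_a} (marginal)", f"{factor}={level_b} (marginal)", mass)


def dic(draws: PosteriorDraws, model: HierarchicalDDM) -> Tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    Deviance uses the data likelihood only.  DIC = D(theta_bar) + 2 p_D with
    p_D = mean deviance - deviance at the posterior mean of the
    subject-level parameters; if the posterior mean were outside the
    support, the highest-likelihood draw is used instead.
    """
    if draws.log_likelihood is None:
        raise ValueError("draws carry no log-likelihood trace")
    mean_dev = float(np.mean(-2.0 * draws.log_likelihood))
    theta_bar = {f: draws.subject[f].mean(axis=(0, 1)) for f in FAMILIES}
    ll_hat = _sampler.total_loglik(
        model.starts, model.rt_s, model.choice, model.win_s,
        model.cell_index["beta"], model.cell_index["alpha"],
        model.cell_index["delta"], model.cell_index["ndt"],
        theta_bar["beta"], theta_bar["alpha"], theta_bar["delta"], theta_bar["ndt"],
        model.tol)
    if not np.isfinite(ll_hat):
        c, d = np.unravel_index(int(np.argmax(draws.log_likelihood)),
                                draws.log_likelihood.shape)
        ll_hat = float(draws.log_likelihood[c, d])
    d_hat = -2.0 * float(ll_hat)
    p_d = mean_dev - d_hat
    return d_hat + 2.0 * p_d, p_d


def posterior_predictive(
    draws: PosteriorDraws,
    model: HierarchicalDDM,
    reps: int = 50,
    seed: int = 0,
    step: float = 0.001,
) -> pd.DataFrame:
    """Predicted-vs-observed summaries per drift design cell.

    For ``reps`` posterior draws the full dataset is re-simulated under the
    same design and deadlines (censored trials dropped, as in the data) and
    summarized per drift-cell: shoot proportion, mean correct response time
    and response-time deciles.  Returns a table with the observed statistic
    and the central 95% predictive interval.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    nc, nd = draws.n_chains, draws.n_draws
    idx = [(int(rng.integers(nc)), int(rng.integers(nd))) for _ in range(reps)]
    cd = model.cell_index["delta"]
    ncells = len(draws.cells["delta"])
    deciles = np.arange(0.1, 1.0, 0.1)

    def summarize(choice, rt_ms):
        rows = {}
        for k in range(ncells):
            m = cd == k
            obs = m & (choice >= 0)
            cell = draws.cell_label("delta", k)
            n_obs = int(obs.sum())
            rows[(cell, "p_shoot")] = float((choice[obs] == 1).mean()) if n_obs else np.nan
            gun = "object=gun" in cell or "object" not in cell
            corr = obs & (choice == (1 if gun else 0))
            rows[(cell, "mean_correct_rt_ms")] = float(rt_ms[corr].mean()) if corr.any() else np.nan
            if n_obs >= 10:
                qs = np.quantile(rt_ms[obs], deciles)
                for q, val in zip(deciles, qs):
                    rows[(cell, f"rt_q{int(round(q * 10)):02d}")] = float(val)
            rows[(cell, "censor_rate")] = float((choice[m] < 0).mean()) if m.any() else np.nan
        return rows

    obs_rows = summarize(model.choice, np.where(np.isnan(model.rt_s), np.nan,
                                                model.rt_s * 1000.0))
    sim_rows = []
    for c, d in idx:
        th = {f: draws.subject[f][c, d] for f in FAMILIES}
        si = model.subject_index
        a = th["alpha"][si, model.cell_index["alpha"]]
        v = th["delta"][si, cd]
        w = th["beta"][si, model.cell_index["beta"]]
        nd_ = th["ndt"][si, model.cell_index["ndt"]]
        choice, rt_s = _wfpt.simulate_table(a, v, w, nd_, step, np.inf,
                                            int(rng.integers(2**31 - 1)))
        # apply each trial's own deadline, where the study's recording censors
        late = model.censor_applies & np.isfinite(model.win_s) & (rt_s > model.win_s)
        choice = np.where(late, -1, choice)
        rt_s = np.where(late, np.nan, rt_s)
        sim_rows.append(summarize(choice, rt_s * 1000.0))

    records = []
    for key, obs_val in obs_rows.items():
        sims = np.array([r.get(key, np.nan) for r in sim_rows], float)
        ok = np.isfinite(sims)
        records.append({
            "cell": key[0], "statistic": key[1], "observed": obs_val,
            "pred_mean": float(np.nanmean(sims)) if ok.any() else np.nan,
            "pred_lo": float(np.nanquantile(sims, 0.025)) if ok.any() else np.nan,
            "pred_hi": float(np.nanquantile(sims, 0.975)) if ok.any() else np.nan,
        })
    return pd.DataFrame(records)
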