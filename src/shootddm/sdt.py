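"""Hierarchical equal-variance signal-detection baseline.

The comparison model for the diffusion analysis: each subject x condition
cell contributes hit/miss counts (gun trials) and false-alarm/correct-
rejection counts (non-gun trials) to a binomial probit model with

    P(hit)         = Phi(d'/2 - c)
    P(false alarm) = Phi(-d'/2 - c)

i.e. equal-variance SDT with the criterion c measured from the midpoint
between the noise and signal distributions (c = 0 is unbiased, negative c
is liberal -- a lower criterion to "Shoot").  Sensitivity d' and criterion
c get hierarchical normal priors per condition with group means and
parameter-level precisions, so the contrast machinery (HDI, standardized
d) is shared with the diffusion path.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .hierarchy import SchemaError
from .inference import PosteriorDraws, adaptive_mwg

__all__ = ["aggregate_counts", "fit_sdt", "probit_point_estimates"]


def probit_point_estimates(hit_rate: float, fa_rate: float) -> Tuple[float, float]:
    """Closed-form equal-variance estimates: d' = z(H) - z(F), c = -(z(H)+z(F))/2."""
    zh, zf = ndtri(hit_rate), ndtri(fa_rate)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def _condition_factors(trials: pd.DataFrame) -> List[str]:
    factors = ["race"]
    for f in ("context", "blur"):
        if f in trials.columns and len(set(trials[f].unique()) - {"none"}) > 1:
            factors.append(f)
    return factors


def aggregate_counts(
    trials: pd.DataFrame,
    factors: Optional[Sequence[str]] = None,
    censored_as_error: bool = False,
) -> pd.DataFrame:
    """Tally hits/misses/false alarms/correct rejections per subject x cell.

    Gun trials answered "shoot" are hits, "dontshoot" misses; non-gun
    trials answered "shoot" are false alarms, "dontshoot" correct
    rejections.  Censored trials are excluded by default (the deadline
    removed the response); ``censored_as_error=True`` instead counts them
    as misses / correct rejections (no "shoot" response was emitted).
    """
    if len(trials) == 0:
        return pd.DataFrame(columns=["subject", "hits", "misses",
                                     "false_alarms", "correct_rejections"])
    if "object" not in trials.columns:
        raise SchemaError("trial table lacks required column 'object'")
    factors = list(factors) if factors is not None else _condition_factors(trials)
    t = trials.copy()
    cens = t["censored"].astype(bool)
    if not censored_as_error:
        t = t.loc[~cens]
        cens = cens.loc[t.index]
    rows = []
    for (subj, *levels), g in t.groupby(["subject"] + factors, sort=True):
        gun = g["object"] == "gun"
        shoot = g["choice"] == "shoot"
        row = {"subject": subj, **dict(zip(factors, levels))}
        row["hits"] = int((gun & shoot).sum())
        row["misses"] = int((gun & ~shoot).sum())
        row["false_alarms"] = int((~gun & shoot).sum())
        row["correct_rejections"] = int((~gun & ~shoot).sum())
        if row["hits"] + row["misses"] == 0 or \
           row["false_alarms"] + row["correct_rejections"] == 0:
            warnings.warn(
                f"subject {subj} cell {levels}: no trials for one object type; "
                "cell omitted")
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def fit_sdt(
    cells: pd.DataFrame,
    chains: int = 2,
    iterations: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    mu_sd: float = 3.0,
    tau_shape: float = 0.001,
    tau_rate: float = 0.001,
) -> PosteriorDraws:
    """Sample the hierarchical SDT posterior from an aggregate-count table.

    Returns draws over group-level "dprime" and "criterion" means per
    condition cell (plus their precisions and the subject-level values),
    in the same container the diffusion fits use, so
    :func:`shootddm.inference.contrast` applies unchanged.
    """
    factors = [c for c in cells.columns
               if c not in ("subject", "hits", "misses",
                            "false_alarms", "correct_rejections")]
    subjects = sorted(cells["subject"].unique().tolist())
    subj_pos = {s: i for i, s in enumerate(subjects)}
    if factors:
        combos = sorted(set(map(tuple, cells[factors].astype(str).itertuples(index=False))))
    else:
        combos = [()]
    cell_pos = {c: i for i, c in enumerate(combos)}
    J, K = len(subjects), len(combos)

    jj = cells["subject"].map(subj_pos).to_numpy(np.int64)
    if factors:
        kk = np.array([cell_pos[t] for t in
                       map(tuple, cells[factors].astype(str).itertuples(index=False))])
    else:
        kk = np.zeros(len(cells), np.int64)
    hits = cells["hits"].to_numpy(float)
    ngun = hits + cells["misses"].to_numpy(float)
    fas = cells["false_alarms"].to_numpy(float)
    nnon = fas + cells["correct_rejections"].to_numpy(float)
    P = len(cells)

    # empirical-logit style starting values with a continuity correction
    h0 = np.clip((hits + 0.5) / (ngun + 1.0), 1e-3, 1 - 1e-3)
    f0 = np.clip((fas + 0.5) / (nnon + 1.0), 1e-3, 1 - 1e-3)
    d0 = ndtri(h0) - ndtri(f0)
    c0 = -(ndtri(h0) + ndtri(f0)) / 2.0

    def unpack(x):
        d = x[:P]
        c = x[P:2 * P]
        mu_d = x[2 * P:2 * P + K]
        mu_c = x[2 * P + K:2 * P + 2 * K]
        ltau_d, ltau_c = x[-2], x[-1]
        return d, c, mu_d, mu_c, ltau_d, ltau_c

    def logpdf(x):
        d, c, mu_d, mu_c, ltau_d, ltau_c = unpack(x)
        tau_d, tau_c = np.exp(ltau_d), np.exp(ltau_c)
        lp = 0.0
        # vague gamma priors on the precisions, with the log-scale Jacobian
        lp += tau_shape * ltau_d - tau_rate * tau_d
        lp += tau_shape * ltau_c - tau_rate * tau_c
        lp += -0.5 * np.sum(mu_d**2 + mu_c**2) / mu_sd**2
        lp += 0.5 * P * (ltau_d + ltau_c)
        lp += -0.5 * tau_d * np.sum((d - mu_d[kk]) ** 2)
        lp += -0.5 * tau_c * np.sum((c - mu_c[kk]) ** 2)
        lp += np.sum(hits * log_ndtr(d / 2 - c) + (ngun - hits) * log_ndtr(c - d / 2))
        lp += np.sum(fas * log_ndtr(-d / 2 - c) + (nnon - fas) * log_ndtr(c + d / 2))
        return lp

    mu_d0 = np.array([d0[kk == k].mean() if (kk == k).any() else 1.0 for k in range(K)])
    mu_c0 = np.array([c0[kk == k].mean() if (kk == k).any() else 0.0 for k in range(K)])
    x0 = np.concatenate([d0, c0, mu_d0, mu_c0, [0.0, 0.0]])
    scales = np.concatenate([np.full(2 * P, 0.3), np.full(2 * K, 0.2), [0.5, 0.5]])

    # joint translation blocks: each cell's subject values move with their
    # group mean, which is essential for mixing when cells hold few subjects
    blocks = []
    for k in range(K):
        sel = np.flatnonzero(kk == k)
        blocks.append(np.concatenate([sel, [2 * P + k]]))
        blocks.append(np.concatenate([P + sel, [2 * P + K + k]]))

    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(chains, np.uint64)]
    group_d = np.empty((chains, iterations, K))
    group_c = np.empty((chains, iterations, K))
    tau_d_d = np.empty((chains, iterations))
    tau_c_d = np.empty((chains, iterations))
    subj_d = np.full((chains, iterations, J, K), np.nan)
    subj_c = np.full((chains, iterations, J, K), np.nan)
    for ci in range(chains):
        draws, _ = adaptive_mwg(logpdf, x0, warmup, iterations,
                                seed=chain_seeds[ci], scales=scales, blocks=blocks)
        d, c, mu_d, mu_c, ltd, ltc = (draws[:, :P], draws[:, P:2 * P],
                                      draws[:, 2 * P:2 * P + K],
                                      draws[:, 2 * P + K:2 * P + 2 * K],
                                      draws[:, -2], draws[:, -1])
        group_d[ci] = mu_d
        group_c[ci] = mu_c
        tau_d_d[ci] = np.exp(ltd)
        tau_c_d[ci] = np.exp(ltc)
        subj_d[ci][:, jj, kk] = d
        subj_c[ci][:, jj, kk] = c

    cells_t = [tuple(map(str, c)) for c in combos]
    return PosteriorDraws(
        group={"dprime": group_d, "criterion": group_c},
        tau={"dprime": tau_d_d, "criterion": tau_c_d},
        subject={"dprime": subj_d, "criterion": subj_c},
        cells={"dprime": cells_t, "criterion": cells_t},
        factors={"dprime": tuple(factors), "criterion": tuple(factors)},
        subjects=subjects,
        meta={"seed": seed, "warmup": warmup, "iterations": iterations,
              "chains": chains, "model": "hierarchical-sdt"},
    )
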