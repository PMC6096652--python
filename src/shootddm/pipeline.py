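"""End-to-end orchestration: validate -> fit -> baseline -> contrasts -> PPC.

A run is driven by a small configuration (YAML on disk or a RunConfig in
code), is fully reproducible from config + seed, and leaves its artifacts
as delimited text plus a machine-readable JSON report in a run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import inference, sdt, synthetic
from .hierarchy import (CHOICE_LEVELS, FAMILIES, HierarchicalDDM, SchemaError,
                        VariationSpec)

__all__ = ["ValidationError", "RunConfig", "validate_input", "run_pipeline",
           "composite_fit", "draws_to_table", "draws_from_table"]

log = logging.getLogger("shootddm")

REQUIRED_COLUMNS = ("subject", "study", "race", "object", "context", "blur",
                    "choice", "rt_ms", "censored")

_LEVELS = {
    "race": {"black", "white"},
    "object": {"gun", "nongun"},
    "context": {"neutral", "dangerous", "none"},
    "blur": {"clear", "blurred", "none"},
}


class ValidationError(ValueError):
    """Input table failed schema validation; ``.report`` itemizes the issues."""

    def __init__(self, report: Dict):
        super().__init__("; ".join(report["errors"]))
        self.report = report


def validate_input(
    source: Union[str, Path, pd.DataFrame],
    min_rt_ms: float = 0.0,
) -> tuple[pd.DataFrame, Dict]:
    """Schema-check and normalize a trial table.

    Returns the normalized table and a report dict (per-subject trial
    counts, censoring rates, warnings).  Raises :class:`ValidationError`
    with an itemized report when the table cannot be used.  ``min_rt_ms``
    optionally drops anticipatory responses faster than the threshold
    (default 0 = off).
    """
    if isinstance(source, (str, Path)):
        t, _ = synthetic.read_dataset(source)
    else:
        t = source.copy()
    errors: List[str] = []
    warnings_: List[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValidationError({"errors": [f"missing column {c!r}" for c in missing],
                               "warnings": []})
    for col in ("race", "object", "context", "blur"):
        t[col] = t[col].astype(str).str.strip().str.lower()
        bad = sorted(set(t[col].unique()) - _LEVELS[col])
        if bad:
            errors.append(f"unknown {col} level(s) {bad}")
    t["choice"] = t["choice"].fillna("").astype(str).str.strip().str.lower()
    t["censored"] = t["censored"].astype(bool)
    t["rt_ms"] = pd.to_numeric(t["rt_ms"], errors="coerce")

    obs = ~t["censored"]
    bad_choice = sorted(set(t.loc[obs, "choice"].unique()) - set(CHOICE_LEVELS))
    if bad_choice:
        errors.append(f"unknown choice level(s) {bad_choice} on non-censored trials")
    n_bad_rt = int((obs & ~(t["rt_ms"] > 0)).sum())
    if n_bad_rt:
        errors.append(f"{n_bad_rt} non-censored trial(s) with missing or non-positive rt_ms")
    n_cens_rt = int((t["censored"] & t["rt_ms"].notna()).sum())
    if n_cens_rt:
        warnings_.append(f"{n_cens_rt} censored trial(s) carried an rt; rt dropped")
        t.loc[t["censored"], "rt_ms"] = np.nan
        t.loc[t["censored"], "choice"] = ""
    if min_rt_ms > 0:
        fast = obs & (t["rt_ms"] < min_rt_ms)
        if fast.any():
            warnings_.append(f"dropped {int(fast.sum())} trial(s) faster than {min_rt_ms} ms")
            t = t.loc[~fast]
    if errors:
        raise ValidationError({"errors": errors, "warnings": warnings_})

    per_subj = t.groupby("subject").agg(
        n_trials=("censored", "size"), censor_rate=("censored", "mean"))
    report = {
        "errors": [],
        "warnings": warnings_,
        "n_subjects": int(t["subject"].nunique()),
        "n_trials": int(len(t)),
        "censor_rate": float(t["censored"].mean()),
        "per_subject": per_subj.reset_index().to_dict("records"),
    }
    for w in warnings_:
        log.warning(w)
    return t.reset_index(drop=True), report


@dataclass
class RunConfig:
    """One pipeline run: input, design, priors, sampler settings, seed."""

    input: Optional[str] = None           # trial-table path; None -> simulate preset
    preset: str = "study4"
    out_dir: str = "runs/run"
    seed: int = 1
    windows_ms: Dict[str, Optional[float]] = field(default_factory=dict)
    chains: int = 2
    iterations: int = 800
    warmup: int = 800
    censoring: str = "aware"
    min_rt_ms: float = 0.0
    ppc_reps: int = 30
    n_subjects: Optional[int] = None      # preset overrides (simulation input only)
    trials_per_cell: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def _factor_contrasts(draws: inference.PosteriorDraws) -> pd.DataFrame:
    """All interpretable marginal level contrasts present in a fit."""
    pairs = {"race": ("black", "white"), "context": ("dangerous", "neutral"),
             "blur": ("blurred", "clear"), "object": ("gun", "nongun")}
    rows = []
    for fam in draws.group:
        for factor, (la, lb) in pairs.items():
            if factor not in draws.factors[fam]:
                continue
            try:
                c = inference.marginal_contrast(draws, fam, factor, la, lb)
            except KeyError:
                continue
            rows.append({
                "parameter": fam, "factor": factor, "level_a": la, "level_b": lb,
                "mean": c.mean, "hdi_lo": c.hdi_lo, "hdi_hi": c.hdi_hi,
                "d_mean": c.d_mean, "d_hdi_lo": c.d_hdi_lo, "d_hdi_hi": c.d_hdi_hi,
                "excludes_zero": c.excludes_zero,
            })
    return pd.DataFrame(rows)


def draws_to_table(draws: inference.PosteriorDraws) -> pd.DataFrame:
    """Long, chain-aware table of the group-level draws (plus precisions)."""
    rows = []
    for fam, arr in draws.group.items():
        for k in range(arr.shape[2]):
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(arr.shape[1]),
                    "parameter": fam, "cell": draws.cell_label(fam, k),
                    "value": arr[c, :, k]}))
    for fam, arr in draws.tau.items():
        for c in range(arr.shape[0]):
            rows.append(pd.DataFrame({
                "chain": c, "draw": np.arange(arr.shape[1]),
                "parameter": f"tau_{fam}", "cell": "all", "value": arr[c]}))
    return pd.concat(rows, ignore_index=True)


def draws_from_table(table: pd.DataFrame) -> inference.PosteriorDraws:
    """Rebuild a group-level PosteriorDraws from :func:`draws_to_table` output."""
    group, tau, cells, factors = {}, {}, {}, {}
    n_chains = int(table["chain"].max()) + 1
    n_draws = int(table["draw"].max()) + 1
    for fam, g in table.groupby("parameter", sort=False):
        if fam.startswith("tau_"):
            arr = np.empty((n_chains, n_draws))
            for c, gc in g.groupby("chain"):
                arr[int(c)] = gc.sort_values("draw")["value"].to_numpy()
            tau[fam[4:]] = arr
            continue
        labels = list(dict.fromkeys(g["cell"]))
        arr = np.empty((n_chains, n_draws, len(labels)))
        for k, lab in enumerate(labels):
            gl = g[g["cell"] == lab]
            for c, gc in gl.groupby("chain"):
                arr[int(c), :, k] = gc.sort_values("draw")["value"].to_numpy()
        if labels == ["all"]:
            factors[fam] = ()
            cells[fam] = [()]
        else:
            factors[fam] = tuple(p.split("=")[0] for p in labels[0].split(","))
            cells[fam] = [tuple(p.split("=")[1] for p in lab.split(","))
                          for lab in labels]
        group[fam] = arr
    return inference.PosteriorDraws(group=group, tau=tau, cells=cells, factors=factors)


def _preset_windows(trials: pd.DataFrame) -> Dict[str, float]:
    out = {}
    for s in trials["study"].astype(str).unique():
        if s in synthetic.STUDY_PRESETS:
            out[s] = synthetic.STUDY_PRESETS[s].window_ms
    return out


def run_pipeline(config: RunConfig) -> Dict:
    """Execute one full analysis run and write its report bundle.

    Stages: input validation (or preset simulation), hierarchical DDM fit,
    hierarchical SDT baseline, marginal condition contrasts for both,
    posterior predictive checks, and a JSON report tying the artifacts
    together.  Every stage derives its randomness from ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.input is None:
            trials, truth = synthetic.generate_preset(
                config.preset, seed=config.seed,
                n_subjects=config.n_subjects,
                trials_per_cell=config.trials_per_cell)
            synthetic.write_dataset(trials, truth, out / "data.csv")
        else:
            trials, _ = synthetic.read_dataset(config.input)
        trials, vreport = validate_input(trials, min_rt_ms=config.min_rt_ms)
        (out / "validation.json").write_text(json.dumps(vreport, indent=1))

        windows = dict(_preset_windows(trials))
        windows.update({str(k): v for k, v in config.windows_ms.items()})

        stage = "ddm_fit"
        model = HierarchicalDDM(trials, windows_ms=windows,
                                censoring=config.censoring)
        draws = inference.sample_posterior(
            model, chains=config.chains, iterations=config.iterations,
            warmup=config.warmup, seed=config.seed)
        summary = draws.summary()
        summary.to_csv(out / "ddm_summary.csv", index=False)
        draws_to_table(draws).to_csv(out / "ddm_draws.csv", index=False)

        stage = "sdt_fit"
        counts = sdt.aggregate_counts(trials)
        sdt_draws = sdt.fit_sdt(counts, chains=config.chains,
                                iterations=config.iterations,
                                warmup=config.warmup, seed=config.seed + 1)
        sdt_summary = sdt_draws.summary()
        sdt_summary.to_csv(out / "sdt_summary.csv", index=False)

        stage = "contrasts"
        contrasts = pd.concat([_factor_contrasts(draws),
                               _factor_contrasts(sdt_draws)], ignore_index=True)
        contrasts.to_csv(out / "contrasts.csv", index=False)

        stage = "ppc"
        ppc = inference.posterior_predictive(draws, model, reps=config.ppc_reps,
                                             seed=config.seed + 2)
        ppc.to_csv(out / "ppc.csv", index=False)

        stage = "report"
        report = {
            "config": asdict(config),
            "validation": {k: vreport[k] for k in
                           ("n_subjects", "n_trials", "censor_rate", "warnings")},
            "ddm": summary.to_dict("records"),
            "sdt": sdt_summary.to_dict("records"),
            "contrasts": contrasts.to_dict("records"),
            "ppc_coverage": float(np.mean(
                (ppc["observed"] >= ppc["pred_lo"]) &
                (ppc["observed"] <= ppc["pred_hi"]))),
            "max_rhat": float(summary["rhat"].max()),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def composite_fit(
    tables: Sequence[pd.DataFrame],
    chains: int = 2,
    iterations: int = 800,
    warmup: int = 800,
    seed: int = 1,
    windows_ms: Optional[Mapping[str, Optional[float]]] = None,
    censoring: str = "aware",
) -> tuple[inference.PosteriorDraws, pd.DataFrame]:
    """Cross-study fit on the conditions common to all studies.

    Restricts each table to neutral-or-absent context and clear-or-absent
    blur, stacks them, and fits one hierarchical model with study as an
    extra condition on every group mean.  Returns the draws and a contrast
    table holding the race contrasts marginalized across studies plus the
    per-study race contrasts (the study x race interaction pattern).
    """
    common = []
    for t in tables:
        m = t["context"].isin(["neutral", "none"]) & t["blur"].isin(["clear", "none"])
        common.append(t.loc[m])
    stacked = pd.concat(common, ignore_index=True)
    if stacked.empty:
        raise SchemaError("no common (neutral-context, clear-object) trials")
    studies = stacked["study"].astype(str).unique().tolist()
    if len(studies) < 2:
        raise SchemaError("composite fit needs at least two studies")
    # subjects must be unique across studies
    stacked["subject"] = stacked["study"].astype(str) + ":" + stacked["subject"].astype(str)

    shared = ("race", "study")
    spec = VariationSpec(beta=shared, alpha=shared,
                         delta=shared + ("object",), ndt=shared + ("object",))
    windows = dict(_preset_windows(stacked))
    windows.update({str(k): v for k, v in (windows_ms or {}).items()})
    model = HierarchicalDDM(stacked, windows_ms=windows, spec=spec,
                            censoring=censoring)
    draws = inference.sample_posterior(model, chains=chains,
                                       iterations=iterations, warmup=warmup,
                                       seed=seed)
    rows = []
    for fam in FAMILIES:
        c = inference.marginal_contrast(draws, fam, "race", "black", "white")
        rows.append({"parameter": fam, "contrast": "race(marginal)",
                     "mean": c.mean, "hdi_lo": c.hdi_lo, "hdi_hi": c.hdi_hi,
                     "d_mean": c.d_mean, "excludes_zero": c.excludes_zero})
        for s in studies:
            cs = inference.marginal_contrast(draws, fam, "race", "black", "white",
                                             fixed={"study": s})
            rows.append({"parameter": fam, "contrast": f"race|study={s}",
                         "mean": cs.mean, "hdi_lo": cs.hdi_lo, "hdi_hi": cs.hdi_hi,
                         "d_mean": cs.d_mean, "excludes_zero": cs.excludes_zero})
        for s in studies[1:]:
            cst = inference.marginal_contrast(draws, fam, "study", s, studies[0])
            rows.append({"parameter": fam, "contrast": f"study:{s}-{studies[0]}",
                         "mean": cst.mean, "hdi_lo": cst.hdi_lo, "hdi_hi": cst.hdi_hi,
                         "d_mean": cst.d_mean, "excludes_zero": cst.excludes_zero})
    return draws, pd.DataFrame(rows)
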