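"""Campaign-level analyses over a sampling-record table.

Three reporting surfaces mirror the three sampling designs:

* point scale — a diurnal series at one collar: classical ER(Ta) and
  GPP(rs) fits, with an AIC check of whether any extra driver helps;
* site scale — the full campaign: partial-correlation screen, candidate
  multi-regression specs, AIC selection, optional randomization pruning,
  driver-weight attribution and residual diagnostics, stratified by
  vegetation class (All, V, NV, MIX; bare soil excluded);
* species — per-species fits plus pairwise randomization comparisons of
  variables and of the GFC-related model responses (a1 for ER; for GPP the
  reference-irradiance response R1, see models.RS_REF).

All entry points take a records DataFrame in the SamplingRecord schema
(SCHEMA.md) and an AnalysisConfig; every excluded record or class appears in
the run log with a machine-readable reason code.  Reports are plain nested
dicts (JSON-serializable via :func:`jsonify`) and are byte-identical across
reruns with the same config and seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .models import (
    FitError,
    FitResult,
    ModelSpec,
    driver_weight,
    fit_model,
    partial_correlation_screen,
    q10_from_b,
    select_model,
)
from .randomization import mean_difference_test, model_parameter_difference_test

REQUIRED_COLUMNS = (
    "point_id", "day", "hour", "ER", "NEE", "GPP",
    "Ta", "Ts", "rs", "RH", "Pr", "VWC", "GFC", "cover_class", "species",
)

PAIRWISE_VARIABLES = ("ER", "NEE", "GPP", "Ta", "Ts", "rs", "RH", "Pr", "VWC", "GFC")


@dataclass
class AnalysisConfig:
    candidate_drivers: tuple[str, ...] = ("GFC", "VWC", "Ts", "RH", "Pr", "h", "DOY")
    max_drivers: int = 2
    alpha: float = 0.05
    n_shuffles: int = 999
    seed: int = 0
    prune: bool = True
    min_species_n: int = 10
    r2_threshold: float = 0.70
    n_bartlett_groups: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# record IO and validation


def load_records(path_or_buffer) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a SamplingRecord CSV.

    Returns (records, log).  Rows with out-of-range values are quarantined
    (removed, logged with a reason code); a missing required column or a
    duplicate point_id (pseudoreplicate) is an error.  Sign-convention
    violations (ER < 0 or GPP > 0) are flagged, not removed.
    """
    df = pd.read_csv(path_or_buffer, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if df["point_id"].duplicated().any():
        dups = sorted(df.loc[df["point_id"].duplicated(), "point_id"].astype(str))
        raise ValueError(f"duplicate point_id (pseudoreplicates): {', '.join(dups)}")
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    log: list[dict] = []
    bad = pd.Series(False, index=df.index)

    def _quarantine(mask: pd.Series, code: str) -> None:
        nonlocal bad
        for pid in df.loc[mask & ~bad, "point_id"]:
            log.append({"code": code, "point_id": str(pid)})
        bad |= mask

    _quarantine((df["GFC"] < 0) | (df["GFC"] > 1), "gfc_out_of_range")
    _quarantine(df["rs"] <= 0, "nonpositive_irradiance")
    _quarantine((df["hour"] < 0) | (df["hour"] >= 24), "hour_out_of_range")
    _quarantine((df["day"] < 0) | (df["day"] > 365), "doy_out_of_range")
    _quarantine(~df["cover_class"].isin(["V", "NV", "MIX", "BS"]), "unknown_cover_class")

    records = df.loc[~bad].copy()
    records["sign_flag"] = (records["ER"] < 0) | (records["GPP"] > 0)
    for pid in records.loc[records["sign_flag"], "point_id"]:
        log.append({"code": "sign_convention_flag", "point_id": str(pid)})
    return records, log


# ---------------------------------------------------------------------------
# report plumbing


def _fit_summary(fit: FitResult) -> dict:
    out = {
        "spec": fit.spec.describe(),
        "params": {k: float(v) for k, v in fit.params.items()},
        "ident_params": {k: float(v) for k, v in fit.ident_params.items()},
        "sigma2_expl": float(fit.sigma2_expl),
        "aic": float(fit.aic),
        "n": fit.n,
        "k": fit.k,
        "residual_mean": float(fit.residuals.mean()),
        "lilliefors_p": fit.lilliefors_p,
        "bartlett_p": fit.bartlett_p,
        "pruned": list(fit.pruned),
    }
    if fit.spec.target == "ER":
        out["Q10"] = q10_from_b(fit.params["b0"]).q10
    return out


def jsonify(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return jsonify(obj.to_dict(orient="records"))
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(jsonify(report), indent=2, sort_keys=True)


def _header(config: AnalysisConfig, analysis: str) -> dict:
    return {
        "analysis": analysis,
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_shuffles": config.n_shuffles,
        "config_hash": hash_config(config),
    }


def hash_config(config: AnalysisConfig) -> str:
    import hashlib

    text = repr(sorted(config.__dict__.items()))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _available_drivers(records: pd.DataFrame, candidates) -> list[str]:
    cols = {"h": "hour", "DOY": "day"}
    out = []
    for d in candidates:
        col = cols.get(d, d)
        if col in records.columns and records[col].std() > 0:
            out.append(d)
    return out


def _with_driver_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Expose the h and DOY candidate drivers under their model names."""
    df = records.copy()
    df["h"] = df["hour"]
    df["DOY"] = df["day"]
    return df


# ---------------------------------------------------------------------------
# analyses


def run_point_scale(records: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Diurnal single-point analysis: classical fits, Q10, and an AIC check
    that no extra driver improves on them."""
    if len(records) < 8:
        raise ValueError(f"point-scale analysis needs >= 8 records, got {len(records)}")
    if records["Ta"].std() == 0:
        raise FitError("constant air temperature: ER(Ta) fit is degenerate")
    data = _with_driver_columns(records)
    report = {"header": _header(config, "point"), "targets": {}}
    for target in ("ER", "GPP"):
        classical = fit_model(data, ModelSpec(target), n_groups=min(config.n_bartlett_groups, len(data) // 3))
        extras = {}
        for d in _available_drivers(data, config.candidate_drivers):
            try:
                f = fit_model(data, ModelSpec(target, (d,)), diagnostics=False)
                extras[d] = {"aic": float(f.aic), "improves": bool(f.aic < classical.aic)}
            except FitError as exc:
                extras[d] = {"error": str(exc)}
        report["targets"][target] = {
            "classical": _fit_summary(classical),
            "extra_driver_aic": extras,
            "any_extra_improves": any(e.get("improves") for e in extras.values()),
        }
    return report


def _candidate_specs(target: str, drivers: list[str], forbidden: set, max_drivers: int):
    specs = [ModelSpec(target)]
    for r in range(1, max_drivers + 1):
        for combo in itertools.combinations(sorted(drivers), r):
            if any(frozenset(p) in forbidden for p in itertools.combinations(combo, 2)):
                continue
            specs.append(ModelSpec(target, combo))
    return specs


def run_site_scale(records: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Full site-scale workflow per vegetation class (All, V, NV, MIX)."""
    data = _with_driver_columns(records)
    log: list[dict] = []
    bs = data["cover_class"] == "BS"
    if bs.any():
        for pid in data.loc[bs, "point_id"]:
            log.append({"code": "bare_soil_excluded", "point_id": str(pid)})
        data = data.loc[~bs]

    drivers = _available_drivers(data, config.candidate_drivers)
    screen = partial_correlation_screen(data, drivers, alpha=config.alpha)
    report = {
        "header": _header(config, "site"),
        "screen": {
            "forbidden_pairs": sorted(sorted(p) for p in screen.forbidden_pairs),
            "table": screen.table,
        },
        "classes": {},
        "log": log,
    }
    for cls in ("All", "V", "NV", "MIX"):
        subset = data if cls == "All" else data.loc[data["cover_class"] == cls]
        entry: dict = {"n": int(len(subset))}
        for target in ("ER", "GPP"):
            specs = _candidate_specs(target, drivers, screen.forbidden_pairs, config.max_drivers)
            kmax = max(s.k for s in specs)
            if len(subset) < kmax + 2:
                entry[target] = {"skipped": f"n={len(subset)} below k+2={kmax + 2}"}
                log.append({"code": "class_skipped", "class": cls, "target": target})
                continue
            try:
                fits, failures = select_model(
                    subset,
                    specs,
                    prune_alpha=config.alpha if config.prune else None,
                    n_shuffles=config.n_shuffles,
                    seed=config.seed,
                )
            except FitError as exc:
                entry[target] = {"skipped": str(exc)}
                log.append({"code": "class_failed", "class": cls, "target": target})
                continue
            best = fits[0]
            entry[target] = {
                "best": _fit_summary(best),
                "ranking": [
                    {"spec": f.spec.describe(), "aic": float(f.aic), "sigma2_expl": float(f.sigma2_expl)}
                    for f in fits
                ],
                "failures": failures,
                "driver_weights": driver_weight(subset, best.spec),
            }
        report["classes"][cls] = entry
    return report


def run_species(records: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Per-species fits plus pairwise randomization comparisons.

    Species below the minimum sample size are excluded (logged); pairwise
    blocks compare variable means and the GFC-related parameters a1 / A1
    between species, and a merged all-species fit is reported alongside.
    """
    data = _with_driver_columns(records)
    data = data.loc[(data["species"] != "none") & data["species"].notna()]
    log: list[dict] = []
    counts = data["species"].value_counts()
    keep = sorted(counts[counts >= config.min_species_n].index)
    for sp in sorted(set(counts.index) - set(keep)):
        log.append({"code": "species_below_min_n", "species": sp, "n": int(counts[sp])})
    data = data.loc[data["species"].isin(keep)]

    spec_er = ModelSpec("ER", ("GFC", "VWC"))
    spec_gpp = ModelSpec("GPP", ("GFC", "VWC"))
    report = {"header": _header(config, "species"), "species": {}, "pairwise": {}, "log": log}

    for i, sp in enumerate(keep):
        sub = data.loc[data["species"] == sp]
        entry = {"n": int(len(sub))}
        for target, spec in (("ER", spec_er), ("GPP", spec_gpp)):
            try:
                entry[target] = _fit_summary(fit_model(sub, spec))
            except (FitError, ValueError) as exc:
                entry[target] = {"skipped": str(exc)}
        report["species"][sp] = entry
    if len(keep) >= 2:
        merged_entry = {"n": int(len(data))}
        for target, spec in (("ER", spec_er), ("GPP", spec_gpp)):
            merged_entry[target] = _fit_summary(fit_model(data, spec))
        report["species"]["all_spp"] = merged_entry

    mean_rows, param_rows = [], []
    for idx, (sa, sb) in enumerate(itertools.combinations(keep, 2)):
        da = data.loc[data["species"] == sa]
        db = data.loc[data["species"] == sb]
        for var in PAIRWISE_VARIABLES:
            nd = mean_difference_test(
                da[var], db[var], n_shuffles=config.n_shuffles,
                seed=config.seed + idx,
            )
            mean_rows.append(
                {"a": sa, "b": sb, "variable": var,
                 "difference": nd.observed, "p": nd.p_two_tailed}
            )
        # a1 is the ER GFC response; R1 = F*A1*rs_ref/(rho+rs_ref) is the stable
        # gauge-invariant GPP counterpart (see models.RS_REF)
        for param, spec in (("a1", spec_er), ("R1", spec_gpp)):
            try:
                nd = model_parameter_difference_test(
                    da, db, spec, param,
                    n_shuffles=config.n_shuffles, seed=config.seed + idx,
                )
                param_rows.append(
                    {"a": sa, "b": sb, "parameter": param,
                     "difference": nd.observed, "p": nd.p_two_tailed}
                )
            except FitError as exc:
                param_rows.append(
                    {"a": sa, "b": sb, "parameter": param,
                     "difference": np.nan, "p": np.nan, "error": str(exc)}
                )
    report["pairwise"]["mean_differences"] = pd.DataFrame(mean_rows)
    report["pairwise"]["parameter_differences"] = pd.DataFrame(param_rows)
    return report
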