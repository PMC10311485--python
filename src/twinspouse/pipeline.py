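"""End-to-end analysis pipeline: load or simulate, describe, fit, test, report.

The pipeline reproduces the full analysis sequence on a family table:
harmonization (when level codes are present), descriptive correlations and
group means, the full FIML fit, the three nested submodels (no phenotypic
assortment, no social homogamy, neither), likelihood-ratio tests, and the
variance/spousal-correlation decomposition.  All randomness derives from one
mandatory master seed, so a report regenerates bit-identically from the same
configuration.

Configuration is a flat YAML mapping with sections ``data`` *or*
``simulate``, and optional ``model``, ``tests``, ``output``; see
:func:`run_full_analysis`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptives import CorrelationSet, group_means, pairwise_correlations, rank_order_diagnostic
from .fitting import (
    FitResult,
    GroupedFamilies,
    ModelSpec,
    ProfileInterval,
    fit_model,
    lrt,
    profile_ci,
)
from .harmonize import HARMONIZATION_METADATA, harmonize_table
from .model import ROLES, DecompositionResult, ParameterSet, Zygosity, decompose
from .presets import preset_counts, preset_parameters
from .simulate import FAMILY_COLUMNS, SimulationDesign, simulate_families

__all__ = [
    "PipelineError",
    "ValidationLog",
    "AnalysisReport",
    "load_families",
    "run_full_analysis",
]

_YEARS_RANGE = (0.0, 30.0)


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ValidationLog:
    """Row-level validation outcomes from :func:`load_families`."""

    n_input: int = 0
    n_kept: int = 0
    issues: list[str] = field(default_factory=list)

    def flag(self, row_id: Any, problem: str) -> None:
        self.issues.append(f"row {row_id}: {problem}")


@dataclass
class AnalysisReport:
    """Everything :func:`run_full_analysis` computes, plus run metadata."""

    correlations: CorrelationSet
    rank_order: Mapping[str, str]
    means: pd.DataFrame
    fits: Mapping[str, FitResult]
    lrt_table: pd.DataFrame
    decomposition: DecompositionResult
    profile_intervals: list[ProfileInterval]
    metadata: Mapping[str, Any]
    validation: ValidationLog | None = None

    def decomposition_frame(self) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(
            [
                {"quantity": "h2", "value": d.h2},
                {"quantity": "s2", "value": d.s2},
                {"quantity": "e2", "value": d.e2},
                {"quantity": "spousal_part_phenotypic", "value": d.part_phenotypic},
                {"quantity": "spousal_part_social", "value": d.part_social},
                {"quantity": "spousal_correlation", "value": d.mu_spouse},
            ]
        )


def load_families(
    path: str | Path,
    *,
    mapping_path: str | None = None,
) -> tuple[pd.DataFrame, ValidationLog]:
    """Read and validate a family CSV; harmonize level codes when present.

    Required columns: ``zygosity`` and ``twin1_years`` (or ``twin1_level``
    plus ``country``).  Rows with unknown zygosity, out-of-range years
    (outside 0-30) or a missing twin1 phenotype are excluded and logged,
    never silently dropped.
    """
    df = pd.read_csv(path)
    log = ValidationLog(n_input=len(df))
    if "zygosity" not in df.columns:
        raise PipelineError("load", "missing required column 'zygosity'")
    has_levels = any(f"{r}_level" in df.columns or f"{r}_level7" in df.columns for r in ROLES)
    if has_levels:
        try:
            df = harmonize_table(df)
        except Exception as exc:  # surface with stage tag
            raise PipelineError("harmonize", str(exc)) from exc
    if "twin1_years" not in df.columns:
        raise PipelineError(
            "load", "missing 'twin1_years' (and no level codes to harmonize)"
        )
    if "family_id" not in df.columns:
        df = df.copy()
        df["family_id"] = np.arange(len(df))

    keep = np.ones(len(df), dtype=bool)
    valid_zyg = {z.value for z in Zygosity}
    zyg = df["zygosity"].astype(str)
    for i, (fid, z) in enumerate(zip(df["family_id"], zyg)):
        if z not in valid_zyg:
            keep[i] = False
            log.flag(fid, f"unknown zygosity {z!r}; excluded")
    for role in ROLES:
        col = f"{role}_years"
        if col not in df.columns:
            df[col] = np.nan
        y = pd.to_numeric(df[col], errors="coerce")
        df[col] = y
        bad = y.notna() & ((y < _YEARS_RANGE[0]) | (y > _YEARS_RANGE[1]))
        for i in np.flatnonzero(bad.to_numpy()):
            keep[i] = False
            log.flag(df["family_id"].iloc[i], f"{col}={y.iloc[i]} outside {_YEARS_RANGE}; excluded")
    no_twin1 = df["twin1_years"].isna().to_numpy()
    for i in np.flatnonzero(no_twin1 & keep):
        keep[i] = False
        log.flag(df["family_id"].iloc[i], "missing twin1 phenotype; excluded")
    if {"twin1_sex", "twin2_sex"} <= set(df.columns):
        s1 = df["twin1_sex"].astype("string").str.upper()
        s2 = df["twin2_sex"].astype("string").str.upper()
        same_sex_osdz = (
            (zyg == "OSDZ")
            & s1.notna().to_numpy()
            & (s1 == s2).to_numpy(dtype=bool, na_value=False)
        )
        for i in np.flatnonzero(same_sex_osdz & keep):
            keep[i] = False
            log.flag(df["family_id"].iloc[i], "OSDZ twins must be opposite-sex; excluded")

    out = df.loc[keep].reset_index(drop=True)
    log.n_kept = len(out)
    return out, log


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _params_from_config(section: Mapping[str, Any]) -> ParameterSet:
    if "preset" in section:
        base = preset_parameters(section["preset"])
        over = {k: v for k, v in section.items() if k in ParameterSet(1, 1, 1).as_dict()}
        return base.replace(**over) if over else base
    keys = ("a", "s", "e", "delta_p", "delta_y", "beta_sex", "mu")
    values = {k: float(section[k]) for k in keys if k in section}
    return ParameterSet(**values)


def run_full_analysis(
    config: Mapping[str, Any] | str | Path,
    *,
    write: bool = True,
) -> AnalysisReport:
    """Run the complete analysis described by a configuration mapping.

    Minimal configurations::

        seed: 1
        simulate: {preset: finland, total_families: 2000}

    or::

        seed: 1
        data: {path: families.csv}

    Optional sections: ``model: {starts: 5, profile_ci: [delta_p, delta_y]}``,
    ``tests: {alpha: 0.05}``, ``output: {dir: out}``.  A seed is mandatory —
    reports must regenerate bit-identically.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    if "seed" not in config:
        raise PipelineError("config", "an explicit integer seed is required")
    seed = int(config["seed"])
    alpha = float(config.get("tests", {}).get("alpha", 0.05))
    model_cfg = config.get("model", {}) or {}
    starts = int(model_cfg.get("starts", 5))

    validation: ValidationLog | None = None
    if "data" in config and config["data"]:
        table, validation = load_families(config["data"]["path"])
        source = {"kind": "data", "path": str(config["data"]["path"])}
    elif "simulate" in config and config["simulate"]:
        sim = dict(config["simulate"])
        try:
            gen = _params_from_config(sim)
            counts = preset_counts(sim.get("preset", "finland"))
            design = SimulationDesign.from_counts(
                counts, gen, seed, total=sim.get("total_families")
            )
            table = simulate_families(design)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        source = {"kind": "simulate", "generating": gen.as_dict(),
                  "n_families": design.n_families}
    else:
        raise PipelineError("config", "need a 'data' or 'simulate' section")

    try:
        correlations = pairwise_correlations(table)
        rank = rank_order_diagnostic(correlations)
        means = group_means(table)
    except Exception as exc:
        raise PipelineError("descriptives", str(exc)) from exc

    try:
        grouped = GroupedFamilies(table)
        full_spec = ModelSpec.full()
        fits: dict[str, FitResult] = {}
        fits["full"] = fit_model(full_spec, grouped, starts=starts, seed=seed)
        fits["no_phenotypic_assortment"] = fit_model(
            full_spec.drop("delta_p"), grouped, starts=starts, seed=seed + 1
        )
        fits["no_social_homogamy"] = fit_model(
            full_spec.drop("delta_y"), grouped, starts=starts, seed=seed + 2
        )
        fits["no_assortment"] = fit_model(
            full_spec.drop("delta_p", "delta_y"), grouped, starts=starts, seed=seed + 3
        )
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        rows = []
        for name in ("no_phenotypic_assortment", "no_social_homogamy", "no_assortment"):
            res = lrt(fits["full"], fits[name])
            rows.append(
                {
                    "comparison": f"full vs {name}",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "significant": res.significant(alpha),
                }
            )
        lrt_table = pd.DataFrame(rows)
        decomposition = decompose(fits["full"].estimates)
    except Exception as exc:
        raise PipelineError("tests", str(exc)) from exc

    intervals: list[ProfileInterval] = []
    for pname in model_cfg.get("profile_ci", []) or []:
        try:
            intervals.append(
                profile_ci(full_spec, grouped, pname, fit=fits["full"], seed=seed)
            )
        except Exception as exc:
            raise PipelineError("profile", str(exc)) from exc

    metadata = {
        "seed": seed,
        "alpha": alpha,
        "config_hash": _config_hash(config),
        "version": __version__,
        "source": source,
        "harmonization": dict(HARMONIZATION_METADATA),
        "descriptives": {"double_entry": True},
    }
    report = AnalysisReport(
        correlations=correlations,
        rank_order=rank,
        means=means,
        fits=fits,
        lrt_table=lrt_table,
        decomposition=decomposition,
        profile_intervals=intervals,
        metadata=metadata,
        validation=validation,
    )
    out_dir = (config.get("output") or {}).get("dir")
    if write and out_dir:
        _write_report(report, table, Path(out_dir))
    return report


def _write_report(report: AnalysisReport, table: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.correlations.to_frame().to_csv(out_dir / "correlations.csv", index=False)
    report.means.to_csv(out_dir / "group_means.csv", index=False)
    report.lrt_table.to_csv(out_dir / "lrt.csv", index=False)
    report.decomposition_frame().to_csv(out_dir / "decomposition.csv", index=False)
    table[list(FAMILY_COLUMNS)].to_csv(out_dir / "families.csv", index=False)
    fit_rows = []
    for name, fit in report.fits.items():
        s = fit.summary()
        s.insert(0, "model", name)
        s["loglik"] = fit.loglik
        s["converged"] = fit.converged
        fit_rows.append(s)
    pd.concat(fit_rows, ignore_index=True).to_csv(out_dir / "fits.csv", index=False)
    if report.profile_intervals:
        pd.DataFrame(
            [
                {
                    "parameter": pi.parameter,
                    "level": pi.level,
                    "lower": pi.lower,
                    "upper": pi.upper,
                    "lower_open": pi.lower_open,
                    "upper_open": pi.upper_open,
                }
                for pi in report.profile_intervals
            ]
        ).to_csv(out_dir / "profile_ci.csv", index=False)
    with open(out_dir / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True, default=str)
    lines = ["twinspouse analysis log", "=" * 30]
    if report.validation is not None:
        lines.append(
            f"[load] kept {report.validation.n_kept}/{report.validation.n_input} rows"
        )
        lines.extend(f"[load] {msg}" for msg in report.validation.issues)
    lines.append(f"[descriptives] rank-order labels: {dict(report.rank_order)}")
    for name, fit in report.fits.items():
        lines.append(
            f"[fit] {name}: loglik={fit.loglik:.4f} converged={fit.converged}"
        )
    d = report.decomposition
    lines.append(
        f"[decompose] spousal correlation {d.mu_spouse:.4f} = "
        f"phenotypic {d.part_phenotypic:.4f} + social {d.part_social:.4f}"
    )
    (out_dir / "run.log").write_text("\n".join(lines) + "\n", encoding="utf-8")
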