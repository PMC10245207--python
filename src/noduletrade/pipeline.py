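"""End-to-end survey analysis: validation, traits, isoquant fit, tests.

``run_pipeline`` reads the two survey CSVs (nodules, nests), reduces
them to per-nest and per-clade traits, fits the isoquant
production-limit model, runs the three ANOVAs (head width ~ genus,
diameter ~ clade, density ~ clade) and the two head-width correlations,
and writes every stage's table plus ``report.json`` and a text summary.
The pipeline is deterministic given its inputs: no randomness, no
timestamps in the report, floats serialized at 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import groupstats, traits
from .isoquant import IsoquantModel, IsoquantResults

logger = logging.getLogger(__name__)

NODULE_COLUMNS = ("nest_id", "genus", "clade", "diameter_mm")
NEST_BASE_COLUMNS = ("nest_id", "genus", "clade", "density_per_g")


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    line: int  # 1-based file line (header = line 1); 0 = file-level
    message: str

    def __str__(self) -> str:
        where = f"{self.file}:{self.line}" if self.line else self.file
        return f"{where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def summary(self) -> str:
        if self.ok:
            return "validation OK: 0 violations"
        return "\n".join(
            [f"validation FAILED: {len(self.issues)} violation(s)"]
            + [str(i) for i in self.issues]
        )


def _check_numeric(
    df: pd.DataFrame, column: str, fname: str, issues: list[ValidationIssue]
) -> pd.Series:
    """Coerce a column to numeric, reporting non-numeric cells by line."""
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[coerced.isna() & df[column].notna()]
    for idx in bad:
        issues.append(
            ValidationIssue(
                fname, int(idx) + 2,
                f"non-numeric value {df.loc[idx, column]!r} in column "
                f"{column!r}",
            )
        )
    missing = df.index[df[column].isna()]
    for idx in missing:
        issues.append(
            ValidationIssue(
                fname, int(idx) + 2, f"missing value in column {column!r}"
            )
        )
    return coerced


def validate_tables(
    nodules_csv: str | Path, nests_csv: str | Path
) -> ValidationReport:
    """Schema and consistency checks on the two survey tables.

    Reports every violation with its file and line: missing columns,
    non-numeric cells, non-positive diameters or head widths, negative
    densities, duplicate nests, and nest_ids present in one table but
    not the other.
    """
    issues: list[ValidationIssue] = []
    nodules_csv, nests_csv = Path(nodules_csv), Path(nests_csv)
    frames = {}
    for path in (nodules_csv, nests_csv):
        try:
            frames[path] = pd.read_csv(path, dtype=str)
        except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
            issues.append(ValidationIssue(path.name, 0, f"unreadable: {exc}"))
    if issues:
        return ValidationReport(issues)
    nodules, nests = frames[nodules_csv], frames[nests_csv]
    nod_name, nest_name = nodules_csv.name, nests_csv.name

    for col in NODULE_COLUMNS:
        if col not in nodules.columns:
            issues.append(
                ValidationIssue(nod_name, 1, f"missing column {col!r}")
            )
    for col in NEST_BASE_COLUMNS:
        if col not in nests.columns:
            issues.append(
                ValidationIssue(nest_name, 1, f"missing column {col!r}")
            )
    hw_cols = [c for c in nests.columns if c.startswith("head_width_")]
    if "nest_id" in nests.columns and not hw_cols:
        issues.append(
            ValidationIssue(nest_name, 1, "no head_width_<k>_mm columns")
        )
    if issues:
        return ValidationReport(issues)

    diam = _check_numeric(nodules, "diameter_mm", nod_name, issues)
    for idx in nodules.index[diam <= 0]:
        issues.append(
            ValidationIssue(
                nod_name, int(idx) + 2,
                f"diameter_mm must be > 0 (got {diam[idx]!r})",
            )
        )
    dens = _check_numeric(nests, "density_per_g", nest_name, issues)
    for idx in nests.index[dens < 0]:
        issues.append(
            ValidationIssue(
                nest_name, int(idx) + 2,
                f"density_per_g must be >= 0 (got {dens[idx]!r})",
            )
        )
    for col in hw_cols:
        hw = _check_numeric(nests, col, nest_name, issues)
        for idx in nests.index[hw <= 0]:
            issues.append(
                ValidationIssue(
                    nest_name, int(idx) + 2,
                    f"{col} must be > 0 (got {hw[idx]!r})",
                )
            )
    dup = nests["nest_id"][nests["nest_id"].duplicated()]
    for idx in dup.index:
        issues.append(
            ValidationIssue(
                nest_name, int(idx) + 2,
                f"duplicate nest_id {nests.loc[idx, 'nest_id']!r}",
            )
        )
    nod_ids = set(nodules["nest_id"].dropna())
    nest_ids = set(nests["nest_id"].dropna())
    for orphan in sorted(nod_ids - nest_ids):
        issues.append(
            ValidationIssue(
                nod_name, 0,
                f"nest_id {orphan!r} has nodules but no nest record",
            )
        )
    for orphan in sorted(nest_ids - nod_ids):
        issues.append(
            ValidationIssue(
                nest_name, 0,
                f"nest_id {orphan!r} has a nest record but no nodules",
            )
        )
    return ValidationReport(issues)


@dataclass
class PipelineOptions:
    """Analysis switches for :func:`run_pipeline`.

    ``response`` selects the isoquant regression response;
    ``unit`` selects the ANOVA analysis unit for diameter ("nest" uses
    the 43 independent nest means, "nodule" pools all measurements and
    is flagged pseudoreplicated); ``per_clade_mean`` fits the isoquant
    on clade-mean points instead of per-nest points.
    """

    out_dir: str | Path | None = None
    response: str = "density"
    unit: str = "nest"
    per_clade_mean: bool = False
    strict_nodule_count: bool = False
    expected_nodules: int = traits.EXPECTED_NODULES_PER_NEST
    seed: int | None = None  # provenance only; the analysis draws nothing


@dataclass
class PipelineReport:
    """Everything the analysis produced, plus provenance."""

    nest_traits: pd.DataFrame
    clade_summary: pd.DataFrame
    isoquant: IsoquantResults
    anovas: dict[str, groupstats.AnovaResult]
    correlations: dict[str, groupstats.CorrelationResult]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "provenance": dict(self.provenance),
            "clade_summary": self.clade_summary.to_dict(orient="records"),
            "isoquant": {
                "method": self.isoquant.method,
                "response": self.isoquant.response,
                "L_hat": self.isoquant.L_hat,
                "se_L": self.isoquant.se_L,
                "t_stat": self.isoquant.t_stat,
                "p_value": self.isoquant.p_value,
                "n": self.isoquant.nobs,
                "sse": self.isoquant.sse,
                "degenerate": self.isoquant.degenerate,
            },
            "anovas": {
                name: {
                    "f_stat": a.f_stat,
                    "df_between": a.df_between,
                    "df_within": a.df_within,
                    "p_value": a.p_value,
                    "group_means": dict(a.group_means),
                }
                for name, a in self.anovas.items()
            },
            "correlations": {
                name: dataclasses.asdict(c)
                for name, c in self.correlations.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(
            _round_floats(self.to_dict()), indent=2, sort_keys=True,
        )

    def text_summary(self) -> str:
        lines = ["Nodule trait-matching analysis", "=" * 60]
        lines.append(
            f"nests: {len(self.nest_traits)}   "
            f"clades: {len(self.clade_summary)}"
        )
        lines.append("")
        lines.append("Per-clade traits (CV in %):")
        for row in self.clade_summary.itertuples(index=False):
            lines.append(
                f"  clade {row.clade}: n={row.n_nests}, "
                f"d={row.mean_diameter_mm:.3f} mm "
                f"(CV {row.cv_diameter_pct:.1f}%), "
                f"D={row.mean_density_per_g:.1f}/g "
                f"(CV {row.cv_density_pct:.1f}%)"
            )
        lines.append("")
        lines.append(self.isoquant.summary())
        lines.append("")
        for name, a in self.anovas.items():
            lines.append(
                f"ANOVA {name}: F({a.df_between},{a.df_within}) = "
                f"{a.f_stat:.3f}, p = {a.p_value:.3g}"
            )
        for name, c in self.correlations.items():
            lines.append(f"correlation {name}: {c.summary()}")
        return "\n".join(lines)


def _round_floats(obj):
    """Recursively coerce floats to 12 significant digits for stable JSON."""
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        # NaN/inf (e.g. undefined CVs at n=1) serialize as null
        return float(f"{f:.12g}") if np.isfinite(f) else None
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    nodules_csv: str | Path,
    nests_csv: str | Path,
    options: PipelineOptions | None = None,
) -> PipelineReport:
    """Full analysis of a survey; raises ValueError on invalid tables.

    Stage order: validate -> per-nest traits -> per-clade summary ->
    isoquant fit -> ANOVAs -> correlations. If ``options.out_dir`` is
    set, writes nest_traits.csv, clade_summary.csv, isoquant_fit.csv,
    group_stats.csv, correlations.csv, report.json and summary.txt.
    """
    from . import __version__

    opts = options or PipelineOptions()
    nodules_csv, nests_csv = Path(nodules_csv), Path(nests_csv)
    t0 = time.perf_counter()
    validation = validate_tables(nodules_csv, nests_csv)
    if not validation.ok:
        raise ValueError(validation.summary())
    logger.info("validation ok (%.2fs)", time.perf_counter() - t0)

    nodules = pd.read_csv(nodules_csv)
    nests = pd.read_csv(nests_csv)

    t1 = time.perf_counter()
    nest_tr = traits.nest_traits_table(
        nodules,
        nests,
        expected_nodules=opts.expected_nodules,
        strict=opts.strict_nodule_count,
    )
    clade_sum = traits.clade_summary_table(
        nest_tr, nodules=nodules, diameter_unit="nest"
    )
    logger.info("traits computed (%.2fs)", time.perf_counter() - t1)

    t2 = time.perf_counter()
    if opts.per_clade_mean:
        fit_data = (
            nest_tr.groupby("clade", sort=True)[
                ["volume_mm3", "density_per_g"]
            ]
            .mean()
            .reset_index()
        )
    else:
        fit_data = nest_tr
    iso = IsoquantModel.from_dataframe(fit_data, response=opts.response).fit()
    logger.info("isoquant fitted (%.2fs)", time.perf_counter() - t2)

    t3 = time.perf_counter()
    anovas = {
        "head_width_by_genus": groupstats.anova_oneway(
            nest_tr["mean_head_width_mm"], nest_tr["genus"]
        ),
        "density_by_clade": groupstats.anova_oneway(
            nest_tr["density_per_g"], nest_tr["clade"]
        ),
    }
    if opts.unit == "nodule":
        anovas["diameter_by_clade"] = groupstats.anova_oneway(
            nodules["diameter_mm"], nodules["clade"]
        )
    else:
        anovas["diameter_by_clade"] = groupstats.anova_oneway(
            nest_tr["mean_diameter_mm"], nest_tr["clade"]
        )
    correlations = {
        "head_width_vs_diameter": groupstats.correlate(
            nest_tr["mean_head_width_mm"], nest_tr["mean_diameter_mm"]
        ),
        "head_width_vs_density": groupstats.correlate(
            nest_tr["mean_head_width_mm"], nest_tr["density_per_g"]
        ),
    }
    logger.info("group statistics done (%.2fs)", time.perf_counter() - t3)

    provenance = {
        "tool": "noduletrade",
        "version": __version__,
        "nodules_sha256": _sha256(nodules_csv),
        "nests_sha256": _sha256(nests_csv),
        "seed": opts.seed,
        "response": opts.response,
        "anova_unit": opts.unit,
        "per_clade_mean": opts.per_clade_mean,
    }
    report = PipelineReport(
        nest_traits=nest_tr,
        clade_summary=clade_sum,
        isoquant=iso,
        anovas=anovas,
        correlations=correlations,
        provenance=provenance,
    )
    if opts.out_dir is not None:
        _write_outputs(report, Path(opts.out_dir))
    return report


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.nest_traits.to_csv(out_dir / "nest_traits.csv", index=False)
    report.clade_summary.to_csv(out_dir / "clade_summary.csv", index=False)
    report.isoquant.to_frame().to_csv(
        out_dir / "isoquant_fit.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "test": name,
                "f_stat": a.f_stat,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "p_value": a.p_value,
            }
            for name, a in report.anovas.items()
        ]
    ).to_csv(out_dir / "group_stats.csv", index=False)
    pd.DataFrame(
        [
            {"pair": name, **dataclasses.asdict(c)}
            for name, c in report.correlations.items()
        ]
    ).to_csv(out_dir / "correlations.csv", index=False)
    (out_dir / "report.json").write_text(
        report.to_json() + "\n", encoding="utf-8"
    )
    (out_dir / "summary.txt").write_text(
        report.text_summary() + "\n", encoding="utf-8"
    )
    logger.info("outputs written to %s", out_dir)
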