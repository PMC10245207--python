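"""Per-nest and per-clade trait summaries of nodule surveys.

Raw measurements (individual nodule diameters, per-nest density counts,
minor-worker head widths) are reduced to the quantities the trade-off
analysis works with: per nest the mean nodule diameter d, the volume
V = (4*pi/3) * (d/2)^3 of the *mean* diameter, the density D and the mean
head width; per clade the across-nest coefficients of variation (CV) of
diameter and density plus a Shapiro-Wilk normality p-value.

A low diameter CV across nests marks nodule size as a stabilized clade
trait, while a high density CV marks nodule number as plastic -- the
contrast that motivates fitting a constant-product (isoquant) model to
volume and density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Survey design: nodule diameters measured per nest.
EXPECTED_NODULES_PER_NEST = 50


def sphere_volume(diameter):
    """Volume of an ideal sphere from its diameter: (4*pi/3) * (d/2)^3.

    Accepts a scalar or array of diameters in mm and returns mm^3.
    Negative diameters are rejected.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be >= 0")
    volume = (4.0 * np.pi / 3.0) * (d / 2.0) ** 3
    return volume if volume.ndim else float(volume)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV in percent: 100 * sd / mean, sd with the n-1 denominator.

    Requires at least two values and a nonzero mean; the CV is unitless
    and invariant to positive rescaling.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation needs >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass(frozen=True)
class NoduleMeasurement:
    """One nodule's diameter (mm) in one nest."""

    nest_id: str
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("nodule diameter must be > 0")


@dataclass(frozen=True)
class NestRecord:
    """Per-nest field observations.

    ``density`` is the nodule count per gram of fresh fungus garden;
    ``head_widths`` are the minor-worker head widths (mm), three per
    nest by survey design.
    """

    nest_id: str
    genus: str
    clade: str
    density: float
    head_widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if not self.head_widths or any(h <= 0 for h in self.head_widths):
            raise ValueError("head widths must be positive and non-empty")
        object.__setattr__(self, "head_widths", tuple(self.head_widths))


@dataclass(frozen=True)
class NestTraits:
    """Derived per-nest traits: mean diameter, volume of it, density."""

    nest_id: str
    mean_diameter: float
    volume: float
    density: float
    mean_head_width: float


@dataclass(frozen=True)
class CladeTraitSummary:
    """Across-nest trait summary for one cultivar clade.

    ``normality_p`` is the Shapiro-Wilk p-value on per-nest mean
    diameters, NaN when fewer than three nests are available.
    """

    clade: str
    n_nests: int
    mean_diameter: float
    cv_diameter: float
    mean_density: float
    cv_density: float
    normality_p: float


def summarize_nest(
    measurements: Sequence[NoduleMeasurement], record: NestRecord
) -> NestTraits:
    """Reduce one nest's measurements to its trait vector.

    The volume is the sphere volume of the *mean* diameter, not the mean
    of per-nodule volumes -- the model's d is the average diameter, and
    Jensen's gap makes the two differ on dispersed data.
    """
    if not measurements:
        raise ValueError("at least one nodule measurement is required")
    for m in measurements:
        if m.nest_id != record.nest_id:
            raise ValueError(
                f"measurement nest_id {m.nest_id!r} does not match record "
                f"{record.nest_id!r}"
            )
    mean_diameter = float(np.mean([m.diameter for m in measurements]))
    return NestTraits(
        nest_id=record.nest_id,
        mean_diameter=mean_diameter,
        volume=sphere_volume(mean_diameter),
        density=record.density,
        mean_head_width=float(np.mean(record.head_widths)),
    )


def _normality_p(values: np.ndarray) -> float:
    if values.size < 3 or np.ptp(values) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        return float(stats.shapiro(values).pvalue)


def summarize_clade(
    nest_traits: Sequence[NestTraits], clade_of: Mapping[str, str]
) -> list[CladeTraitSummary]:
    """Across-nest trait summaries per clade, in clade-name order.

    Every nest must be mapped to exactly one clade. CVs are computed on
    per-nest values (nests are the independent replicates); clades with
    a single nest get NaN CVs, and the normality p-value is NaN below
    three nests.
    """
    by_clade: dict[str, list[NestTraits]] = {}
    for nt in nest_traits:
        if nt.nest_id not in clade_of:
            raise ValueError(f"nest {nt.nest_id!r} has no clade mapping")
        by_clade.setdefault(clade_of[nt.nest_id], []).append(nt)
    summaries = []
    for clade in sorted(by_clade):
        traits = by_clade[clade]
        diameters = np.array([t.mean_diameter for t in traits])
        densities = np.array([t.density for t in traits])
        summaries.append(
            CladeTraitSummary(
                clade=clade,
                n_nests=len(traits),
                mean_diameter=float(diameters.mean()),
                cv_diameter=(
                    coefficient_of_variation(diameters)
                    if diameters.size >= 2
                    else float("nan")
                ),
                mean_density=float(densities.mean()),
                cv_density=(
                    coefficient_of_variation(densities)
                    if densities.size >= 2 and densities.mean() != 0
                    else float("nan")
                ),
                normality_p=_normality_p(diameters),
            )
        )
    return summaries


# -- table-level API ------------------------------------------------------


def nest_traits_table(
    nodules: pd.DataFrame,
    nests: pd.DataFrame,
    expected_nodules: int = EXPECTED_NODULES_PER_NEST,
    strict: bool = False,
) -> pd.DataFrame:
    """Vectorized nest summaries from the survey's two CSV tables.

    Parameters
    ----------
    nodules
        Columns nest_id, genus, clade, diameter_mm (one row per nodule).
    nests
        Columns nest_id, genus, clade, density_per_g and one
        ``head_width_<k>_mm`` column per measured worker.
    expected_nodules
        Nests with fewer measurements are accepted with a logged
        warning (field losses happen) unless ``strict`` is set, in
        which case any deviation from the expected count raises.

    Returns a frame with columns nest_id, genus, clade,
    mean_diameter_mm, volume_mm3, density_per_g, mean_head_width_mm.
    """
    counts = nodules.groupby("nest_id", sort=False)["diameter_mm"].count()
    off_count = counts[counts != expected_nodules]
    if len(off_count):
        msg = (
            f"{len(off_count)} nest(s) deviate from {expected_nodules} "
            f"nodules: {dict(off_count.head(10))}"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    mean_d = (
        nodules.groupby("nest_id", sort=False)["diameter_mm"]
        .mean()
        .rename("mean_diameter_mm")
    )
    hw_cols = [c for c in nests.columns if c.startswith("head_width_")]
    if not hw_cols:
        raise ValueError("nests table has no head_width_<k>_mm columns")
    out = nests[["nest_id", "genus", "clade", "density_per_g"]].copy()
    out["mean_head_width_mm"] = nests[hw_cols].mean(axis=1)
    out = out.merge(mean_d, on="nest_id", validate="one_to_one")
    out["volume_mm3"] = sphere_volume(out["mean_diameter_mm"].to_numpy())
    return out[
        [
            "nest_id",
            "genus",
            "clade",
            "mean_diameter_mm",
            "volume_mm3",
            "density_per_g",
            "mean_head_width_mm",
        ]
    ]


def clade_summary_table(
    nest_traits: pd.DataFrame,
    nodules: pd.DataFrame | None = None,
    diameter_unit: str = "nest",
) -> pd.DataFrame:
    """Per-clade trait summary as a DataFrame.

    ``diameter_unit="nest"`` (default) computes the diameter CV on
    per-nest mean diameters, treating nests as replicates.
    ``diameter_unit="nodule"`` pools all individual nodule diameters of
    the clade instead (requires ``nodules``); pooling mixes within- and
    among-nest variation and matches the generator's configured clade
    CV at large sample sizes.
    """
    if diameter_unit not in ("nest", "nodule"):
        raise ValueError("diameter_unit must be 'nest' or 'nodule'")
    if diameter_unit == "nodule" and nodules is None:
        raise ValueError("diameter_unit='nodule' requires the nodules table")
    rows = []
    for clade, grp in nest_traits.groupby("clade", sort=True):
        if diameter_unit == "nest":
            diam_values = grp["mean_diameter_mm"].to_numpy()
        else:
            diam_values = nodules.loc[
                nodules["clade"] == clade, "diameter_mm"
            ].to_numpy()
        dens = grp["density_per_g"].to_numpy()
        rows.append(
            {
                "clade": clade,
                "n_nests": len(grp),
                "mean_diameter_mm": diam_values.mean(),
                "cv_diameter_pct": (
                    coefficient_of_variation(diam_values)
                    if diam_values.size >= 2
                    else np.nan
                ),
                "mean_density_per_g": dens.mean(),
                "cv_density_pct": (
                    coefficient_of_variation(dens)
                    if dens.size >= 2 and dens.mean() != 0
                    else np.nan
                ),
                "normality_p": _normality_p(
                    grp["mean_diameter_mm"].to_numpy()
                ),
            }
        )
    return pd.DataFrame(rows)
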