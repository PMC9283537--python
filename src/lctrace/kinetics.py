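"""Incorporation kinetics: corrected label ratios, slopes, class summaries.

Turns isotopologue intensity distributions into the tracer read-outs:
heavy/light ("leading") ratios, natural-abundance-corrected ratios, ordinary
least-squares incorporation slopes over the early labeling window (first two
weeks by default), log10 maximum-isotopologue ratios against unlabeled
controls, and class-by-compartment summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chem import MolecularFormula, natural_isotope_fraction

__all__ = [
    "IsotopologueDistribution",
    "KineticSeries",
    "SlopeFit",
    "leading_ratio",
    "correct_natural_abundance",
    "fit_incorporation_slope",
    "log_max_isotopologue_ratio",
    "summarize_class_slopes",
    "series_from_distributions",
]


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Per-sample isotopologue intensities for one compound."""

    compound_id: str
    sample_id: str
    intensities: dict[int, float]

    def __post_init__(self) -> None:
        if 0 not in self.intensities:
            raise ValueError("label count 0 (monoisotopic) must be present")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be >= 0")

    @property
    def max_label(self) -> int:
        return max(self.intensities)


@dataclass
class KineticSeries:
    """Corrected label ratio vs time for one compound in one compartment."""

    compound_id: str
    compartment: str
    points: list[tuple[float, float, str]]  # (time weeks, ratio, replicate)

    def __post_init__(self) -> None:
        if any(t < 0 for t, _, _ in self.points):
            raise ValueError("times must be >= 0")


@dataclass(frozen=True)
class SlopeFit:
    slope: float          # ratio per week
    intercept: float
    stderr: float
    n: int
    window: float


def leading_ratio(d: IsotopologueDistribution, label_count: int) -> float:
    """intensity(label_count) / intensity(0); the raw heavy/light ratio."""
    if label_count not in d.intensities:
        raise KeyError(
            f"label count {label_count} absent from distribution of "
            f"{d.compound_id!r}"
        )
    light = d.intensities[0]
    if light <= 0:
        raise ValueError(
            f"{d.compound_id}/{d.sample_id}: monoisotopic intensity is zero"
        )
    return d.intensities[label_count] / light


def correct_natural_abundance(
    measured_ratio: float, f: MolecularFormula, isotope: str
) -> tuple[float, bool]:
    """Subtract the natural single-substitution heavy/light term, floor at 0.

    Returns (corrected ratio, floored flag). For a formula without the
    isotope's element the correction term is 0 and the ratio is unchanged.
    """
    if measured_ratio < 0:
        raise ValueError("measured ratio must be >= 0")
    corrected = measured_ratio - natural_isotope_fraction(f, isotope)
    if corrected < 0:
        return 0.0, True
    return corrected, False


def fit_incorporation_slope(s: KineticSeries,
                            window: float = 2.0) -> SlopeFit:
    """OLS of corrected ratio on time over points with time <= window.

    The window includes t = 0; requires >=3 points at >=2 distinct times.
    """
    pts = [(t, r) for t, r, _ in s.points if t <= window]
    if len(pts) < 3:
        raise ValueError(
            f"{s.compound_id}: need >=3 points with time <= {window}, "
            f"got {len(pts)}"
        )
    times = np.array([t for t, _ in pts])
    ratios = np.array([r for _, r in pts])
    if len(np.unique(times)) < 2:
        raise ValueError(f"{s.compound_id}: need >=2 distinct time points")
    res = stats.linregress(times, ratios)
    stderr = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    stderr=stderr, n=len(pts), window=window)


def log_max_isotopologue_ratio(
    labeled: IsotopologueDistribution,
    control: IsotopologueDistribution,
    floor: float = 1.0,
) -> float:
    """log10 of the maximal-label channel, labeled over unlabeled control.

    Both distributions must describe the same species. Returns NaN
    (flagged undefined, to be excluded from summaries) when both channels
    are zero.
    """
    if labeled.compound_id != control.compound_id:
        raise ValueError("distributions describe different compounds")
    k = labeled.max_label
    top_l = labeled.intensities.get(k, 0.0)
    top_c = control.intensities.get(k, 0.0)
    if top_l <= 0 and top_c <= 0:
        return float("nan")
    return math.log10(max(top_l, floor) / max(top_c, floor))


def summarize_class_slopes(
    slopes: dict[str, SlopeFit],
    class_map: dict[str, str],
    compartment_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-compound slopes to a class x compartment long table.

    Emits both the summed slope (as used for flow/Sankey rendering) and the
    mean with SD and n, since sums are sensitive to class size.
    """
    missing = sorted(set(slopes) - set(class_map))
    if missing:
        raise KeyError(f"compounds without a class mapping: {missing}")
    rows = []
    for cid, fit in slopes.items():
        rows.append({
            "compound_id": cid,
            "compound_class": class_map[cid],
            "compartment": (compartment_map or {}).get(cid, "all"),
            "slope": fit.slope,
        })
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["compound_class", "compartment"])["slope"]
        .agg(sum_slope="sum", n="count", mean_slope="mean", sd_slope="std")
        .reset_index()
    )
    out["sd_slope"] = out["sd_slope"].fillna(0.0)
    return out


def series_from_distributions(
    distributions: pd.DataFrame,
    formula_map: dict[str, MolecularFormula],
    isotope_map: dict[str, str],
    label_count_map: dict[str, int],
    compartment: str = "all",
    corrected: bool = True,
) -> dict[str, KineticSeries]:
    """Build per-compound kinetic series from a long intensity table.

    Expects columns compound_id, sample_id, time_weeks, label_count,
    intensity (the shared schema of the generator and both detectors).
    Ratios are the leading heavy/light ratios, natural-abundance corrected
    by default.
    """
    required = {"compound_id", "sample_id", "time_weeks", "label_count",
                "intensity"}
    missing = required - set(distributions.columns)
    if missing:
        raise ValueError(f"distribution table missing: {sorted(missing)}")
    series: dict[str, KineticSeries] = {}
    for (cid, sid), grp in distributions.groupby(["compound_id",
                                                  "sample_id"]):
        if cid not in label_count_map:
            continue
        dist = IsotopologueDistribution(
            compound_id=cid, sample_id=sid,
            intensities=dict(zip(grp["label_count"].astype(int),
                                 grp["intensity"])),
        )
        t = float(grp["time_weeks"].iloc[0])
        try:
            ratio = leading_ratio(dist, label_count_map[cid])
        except (ValueError, KeyError):
            continue    # missing monoisotopic or channel: skip the point
        if corrected:
            ratio, _ = correct_natural_abundance(
                ratio, formula_map[cid], isotope_map[cid]
            )
        series.setdefault(
            cid, KineticSeries(compound_id=cid, compartment=compartment,
                               points=[])
        ).points.append((t, ratio, sid))
    return series
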