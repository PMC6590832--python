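"""Per-line evolutionary response measures.

Quantifies how each experimental line changed over the ten generations on
stressful medium: ordinary-least-squares slopes of trait means across
generations (the response measure), viability change with its
variance-sum-law standard error, between-line coefficients of variation,
the 200-adult extinction rule, the productivity rate, and the baseline
stress-level (acid concentration) selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseSlope",
    "ViabilityChange",
    "productivity_rate",
    "response_slope",
    "slopes_table",
    "viability_delta",
    "viability_change_table",
    "between_line_cv",
    "classify_extinction",
    "select_stress_level",
    "assay_layout",
]

MIN_SLOPE_POINTS = 3
EXTINCTION_THRESHOLD = 200


@dataclass
class ResponseSlope:
    line_id: str
    trait: str
    slope: float  # trait units per generation
    intercept: float
    n_points: int
    r_squared: float


@dataclass
class ViabilityChange:
    line_id: str
    medium: str  # benign / stress
    delta: float  # viability(gen 10) - viability(gen 0)
    se: float


def productivity_rate(total_flies: int, n_parents: int, laying_days: float = 4.0) -> float:
    """Adult flies produced per female per day, assuming a 1:1 sex ratio.

    The egg-laying window defaults to 4 days (two 48-h laying bottles).
    """
    if n_parents <= 0:
        raise ValueError("n_parents must be > 0")
    if laying_days <= 0:
        raise ValueError("laying_days must be > 0")
    if total_flies < 0:
        raise ValueError("total_flies must be >= 0")
    return total_flies / ((n_parents / 2.0) * laying_days)


def response_slope(
    generations: Sequence[float],
    values: Sequence[float],
    line_id: str = "",
    trait: str = "",
    min_points: int = MIN_SLOPE_POINTS,
) -> ResponseSlope | None:
    """OLS slope of trait means on generation index.

    Returns ``None`` (ineligible, not an error) with fewer than
    ``min_points`` observations — short series from lines that went
    extinct early give unreliable slopes.  Missing generations are
    allowed; the regression is unweighted.
    """
    g = np.asarray(generations, dtype=float)
    y = np.asarray(values, dtype=float)
    if g.size != y.size:
        raise ValueError("generations and values must have equal length")
    if g.size < min_points:
        return None
    if np.ptp(g) == 0:
        raise ValueError("zero variance in generation index")
    res = stats.linregress(g, y)
    return ResponseSlope(
        line_id=line_id,
        trait=trait,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=int(g.size),
        r_squared=float(res.rvalue**2),
    )


def slopes_table(
    traits: pd.DataFrame,
    eligible_ids: Iterable[str] | None = None,
    min_points: int = MIN_SLOPE_POINTS,
) -> pd.DataFrame:
    """Per-line, per-trait response slopes from a long traits table.

    ``traits`` columns: line_id, generation, trait, value.  If
    ``eligible_ids`` is given, other lines are excluded up front
    (typically: non-extinct lines with a diversity estimate).  Lines with
    too few generations are dropped with their reason recorded in the
    returned frame's ``attrs['excluded']``.
    """
    eligible = None if eligible_ids is None else set(eligible_ids)
    rows, excluded = [], []
    for (lid, trait), sub in traits.groupby(["line_id", "trait"], sort=True):
        if eligible is not None and lid not in eligible:
            excluded.append((lid, trait, "ineligible"))
            continue
        res = response_slope(
            sub["generation"], sub["value"], line_id=lid, trait=trait,
            min_points=min_points,
        )
        if res is None:
            excluded.append((lid, trait, f"<{min_points} generations"))
            continue
        rows.append(
            {
                "line_id": lid,
                "trait": trait,
                "slope": res.slope,
                "intercept": res.intercept,
                "n_points": res.n_points,
                "r_squared": res.r_squared,
            }
        )
    out = pd.DataFrame(rows, columns=["line_id", "trait", "slope", "intercept", "n_points", "r_squared"])
    out.attrs["excluded"] = excluded
    return out


def viability_delta(
    v0: float, v10: float, var0: float, n0: int, var10: float, n10: int,
    line_id: str = "", medium: str = "",
) -> ViabilityChange:
    """Viability change gen 10 - gen 0 with variance-sum-law SE.

    se = sqrt(var10 / n10 + var0 / n0): the variance of a difference of
    independent means is the sum of the variances of the means.
    """
    if n0 < 1 or n10 < 1:
        raise ValueError("sample sizes must be >= 1")
    if var0 < 0 or var10 < 0:
        raise ValueError("variances must be >= 0")
    return ViabilityChange(
        line_id=line_id,
        medium=medium,
        delta=float(v10 - v0),
        se=float(np.sqrt(var10 / n10 + var0 / n0)),
    )


def viability_change_table(viability: pd.DataFrame) -> pd.DataFrame:
    """Per-line, per-medium viability change from a counts table.

    ``viability`` columns: line_id, medium, generation (0 or 10), eggs,
    survivors.  The per-assay binomial variance p(1-p) stands in for the
    between-vial variance; only lines assayed at both generations appear.
    """
    df = viability.copy()
    df["viab"] = df["survivors"] / df["eggs"]
    rows = []
    for (lid, medium), sub in df.groupby(["line_id", "medium"], sort=True):
        byg = sub.set_index("generation")
        if 0 not in byg.index or 10 not in byg.index:
            continue
        v0, v10 = float(byg.loc[0, "viab"]), float(byg.loc[10, "viab"])
        n0, n10 = int(byg.loc[0, "eggs"]), int(byg.loc[10, "eggs"])
        ch = viability_delta(
            v0, v10, v0 * (1 - v0), n0, v10 * (1 - v10), n10, line_id=lid, medium=medium
        )
        rows.append({"line_id": lid, "medium": medium, "delta": ch.delta, "se": ch.se})
    return pd.DataFrame(rows, columns=["line_id", "medium", "delta", "se"])


def between_line_cv(values: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean) across lines, in %."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 lines for a CV")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined: mean is zero")
    return float(v.std(ddof=1) / mean * 100.0)


def classify_extinction(
    collected_counts: Sequence[int], threshold: int = EXTINCTION_THRESHOLD
) -> int | None:
    """First generation (1-based) where fewer than ``threshold`` adults
    could be collected, or ``None`` if the line never fell below it."""
    for g, count in enumerate(collected_counts, start=1):
        if count < threshold:
            return g
    return None


def select_stress_level(
    viability_by_level: Mapping[float, float], target: float = 0.5
) -> float:
    """Acid concentration whose baseline viability is closest to the target.

    Ties break toward the lower concentration.
    """
    if not viability_by_level:
        raise ValueError("no viability estimates")
    # round the distance so exact ties (e.g. 0.55 vs 0.45) break on level
    return min(
        viability_by_level,
        key=lambda lvl: (round(abs(viability_by_level[lvl] - target), 9), lvl),
    )


def assay_layout(
    n_lines: int, n_media: int, n_vials: int, eggs_per_vial: int = 15
) -> tuple[int, int]:
    """(total eggs, total vials) of a viability assay layout.

    Baseline: 132 lines x 5 media x 5 vials x 15 eggs = 49,500 eggs in
    3,300 vials; generation 10: 96 lines x 2 media x 10 vials x 15 eggs =
    28,800 eggs in 1,920 vials.
    """
    if min(n_lines, n_media, n_vials, eggs_per_vial) < 1:
        raise ValueError("all layout counts must be >= 1")
    vials = n_lines * n_media * n_vials
    return vials * eggs_per_vial, vials
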