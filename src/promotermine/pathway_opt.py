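"""Combinatorial promoter-pair selection for a two-gene desaturase pathway.

The linoleic-acid route runs through two sequential desaturations (FAD9:
Δ9, FAD12: Δ12). Designs assign one promoter to each gene; all ordered
pairs (with repetition) over a promoter pool are enumerated, scored with a
bottleneck saturation heuristic, and compared against measured titers.
A mixed-sugar utilisation summary covers fermentations on hydrolysate.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .models import PathwayDesign, PromoterMineError

SAT_K = 1.0
SCORING_PHASE = "logarithmic"  # expression during growth drives enzyme levels


def enumerate_designs(
    promoter_pool: Sequence[str], genes: tuple[str, str] = ("FAD9", "FAD12")
) -> list[PathwayDesign]:
    """All ordered promoter pairs (with repetition), in pool order.

    A pool of n promoters yields n² designs named ``<gene1>:<p>|<gene2>:<q>``.
    """
    if not promoter_pool:
        raise PromoterMineError("empty promoter pool")
    designs = []
    for a in promoter_pool:
        for b in promoter_pool:
            designs.append(
                PathwayDesign(
                    design_id=f"{genes[0]}:{a}|{genes[1]}:{b}",
                    promoter_fad9=a,
                    promoter_fad12=b,
                )
            )
    return designs


def _sat(f: float, k: float) -> float:
    return f / (f + k)


def predict_score(
    design: PathwayDesign,
    strength_matrix: pd.DataFrame,
    medium: str,
    phase: str = SCORING_PHASE,
    k: float = SAT_K,
) -> float:
    """Bottleneck score min(sat(f9), sat(f12)), sat(f) = f/(f+k).

    A two-step sequential pathway is limited by its weaker stage; the
    saturation keeps the score in [0, 1) and monotone in each fold. Folds
    come from the ``medium:phase`` column of the strength matrix.
    """
    col = f"{medium}:{phase}"
    if col not in strength_matrix.columns:
        raise PromoterMineError(f"no strengths for condition {col!r}")
    folds = []
    for pid in (design.promoter_fad9, design.promoter_fad12):
        if pid not in strength_matrix.index:
            raise PromoterMineError(f"promoter {pid!r} missing from strength matrix")
        f = float(strength_matrix.at[pid, col])
        if math.isnan(f):
            raise PromoterMineError(f"fold for {pid!r} in {col!r} is missing")
        folds.append(f)
    return min(_sat(f, k) for f in folds)


def percent_improvement(
    engineered_titer: float, parental_titer: float, decimals: int | None = 1
) -> float:
    """100 · (engineered − parental) / parental.

    Rounded half away from zero to ``decimals`` places (``None`` disables
    rounding, e.g. for exact reciprocal identities).
    """
    if parental_titer <= 0:
        raise PromoterMineError(
            f"parental titer must be positive, got {parental_titer}"
        )
    p = 100.0 * (engineered_titer - parental_titer) / parental_titer
    if decimals is None:
        return p
    q = 10.0**decimals
    return math.copysign(math.floor(abs(p) * q + 0.5) / q, p)


def best_design(titer_table: pd.DataFrame, medium: str) -> list[str]:
    """Strain(s) with maximal C18:2 titer in ``medium``; ties all reported.

    Expects columns ``strain_id``, ``medium``, ``c18_2_mg_per_l``. The
    parental strain, if present, is not a design and is excluded.
    """
    sub = titer_table[
        (titer_table["medium"] == medium)
        & (titer_table["strain_id"] != "parental")
    ]
    if sub.empty:
        raise PromoterMineError(f"no designs measured in medium {medium!r}")
    top = sub["c18_2_mg_per_l"].max()
    winners = sorted(sub.loc[sub["c18_2_mg_per_l"] == top, "strain_id"].tolist())
    return winners


def sugar_summary(
    series: pd.DataFrame,
    horizon_h: float = 30.0,
    threshold: float = 0.8,
    exhaustion_frac: float = 0.05,
) -> dict:
    """Consumption fractions at the horizon and sugar exhaustion order.

    ``series`` has a ``time_h`` column plus one ``<sugar>_g_l`` column per
    sugar. Concentrations at the horizon are linearly interpolated. A sugar
    is exhausted when it first drops below ``exhaustion_frac`` of its
    initial concentration (linear-interpolated crossing time); sugars that
    never cross are omitted from the order. Sugars starting at zero are
    skipped with a warning.
    """
    t = series["time_h"].to_numpy(dtype=float)
    if not (np.diff(t) > 0).all():
        raise PromoterMineError("time grid must be strictly increasing")
    if t[0] > 0 or t[-1] < horizon_h:
        raise PromoterMineError(
            f"series must cover t=0 through the horizon {horizon_h} h"
        )
    sugars = [c[: -len("_g_l")] for c in series.columns if c.endswith("_g_l")]
    consumed: dict[str, float] = {}
    exhaustion: dict[str, float] = {}
    total0 = 0.0
    total_h = 0.0
    for s in sugars:
        c = series[f"{s}_g_l"].to_numpy(dtype=float)
        if c[0] <= 0:
            warnings.warn(f"sugar {s!r} has zero initial concentration; skipped")
            continue
        c_h = float(np.interp(horizon_h, t, c))
        consumed[s] = 1.0 - c_h / c[0]
        total0 += c[0]
        total_h += c_h
        cut = exhaustion_frac * c[0]
        below = np.nonzero(c < cut)[0]
        if below.size:
            i = int(below[0])
            if i == 0:
                exhaustion[s] = float(t[0])
            else:
                # linear crossing between the bracketing grid points
                t0, t1, c0, c1 = t[i - 1], t[i], c[i - 1], c[i]
                exhaustion[s] = float(t0 + (c0 - cut) / (c0 - c1) * (t1 - t0))
    total_fraction = 1.0 - total_h / total0 if total0 > 0 else 0.0
    order = [s for s, _ in sorted(exhaustion.items(), key=lambda kv: kv[1])]
    return {
        "consumed_fraction": consumed,
        "total_consumed_fraction": total_fraction,
        "exhaustion_order": order,
        "exhaustion_time_h": exhaustion,
        "meets_threshold": total_fraction >= threshold,
    }


def score_designs(
    designs: Sequence[PathwayDesign],
    strength_matrix: pd.DataFrame,
    medium: str,
    phase: str = SCORING_PHASE,
    k: float = SAT_K,
) -> pd.DataFrame:
    """Score a design list in one medium; returns a ranked table."""
    rows = []
    for d in designs:
        score = predict_score(d, strength_matrix, medium, phase, k)
        d.predicted_score = score
        rows.append(
            {
                "design_id": d.design_id,
                "promoter_fad9": d.promoter_fad9,
                "promoter_fad12": d.promoter_fad12,
                "medium": medium,
                "predicted_score": score,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["predicted_score", "design_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
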