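"""Reporter-based promoter strength quantification.

From raw plate-reader wells to promoter strength: blank subtraction,
fluorescence-per-OD normalization, replicate aggregation, fold relative to
the reference promoter, detection-limit and strength classification, and
medium/phase responsiveness.

Because folds are ratios of within-condition signals, they are invariant
both to the plate gain and to any uniform rescaling of raw fluorescence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    CLASS_ORDER,
    Condition,
    PromoterMineError,
    StrengthProfile,
    class_index,
)

BLANK_ID = "blank"


class NonGrowthError(PromoterMineError):
    pass


class ReferenceError_(PromoterMineError):
    pass


@dataclass(frozen=True)
class ClassThresholds:
    """Fold-vs-reference cut points for the qualitative strength labels.

    A condition is called ``none`` when the raw signal is at the detection
    limit (blank mean + 3·blank sd); above it, the fold decides:
    very_weak < 0.1 ≤ weak < 0.5 ≤ medium < 2.0 ≤ strong < 5.0 ≤ extreme.
    """

    very_weak: float = 0.1
    weak: float = 0.5
    medium: float = 2.0
    strong: float = 5.0

    def label(self, fold: float) -> str:
        if fold < self.very_weak:
            return "very_weak"
        if fold < self.weak:
            return "weak"
        if fold < self.medium:
            return "medium"
        if fold < self.strong:
            return "strong"
        return "extreme"


def normalize_signal(
    wells: pd.DataFrame, blanks: pd.DataFrame
) -> tuple[float, float, int]:
    """Blank-subtracted fluorescence per OD for one promoter × condition.

    Per replicate: ``(F − mean blank F) / (OD − mean blank OD)``. Returns
    (mean, sample sd, n) across replicates; a single replicate reports
    sd 0. Negative per-replicate signals are clipped to 0 with a warning.
    """
    if wells.empty:
        raise PromoterMineError("no sample wells to normalize")
    if blanks.empty:
        raise PromoterMineError("no blank wells to normalize against")
    blank_f = float(blanks["fluorescence"].mean())
    blank_od = float(blanks["od600"].mean())
    signals = []
    for _, w in wells.iterrows():
        denom = float(w["od600"]) - blank_od
        if denom <= 0:
            raise NonGrowthError(
                f"sample OD {w['od600']:.4g} at or below blank OD {blank_od:.4g} "
                f"(promoter {w.get('promoter_id', '?')})"
            )
        s = (float(w["fluorescence"]) - blank_f) / denom
        if s < 0:
            warnings.warn(
                "negative normalized signal clipped to 0", stacklevel=2
            )
            s = 0.0
        signals.append(s)
    arr = np.asarray(signals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


def relative_strength(
    signals: pd.DataFrame, reference_id: str
) -> pd.DataFrame:
    """fold(p, c) = signal(p, c) / signal(reference, c).

    ``signals`` is promoter × condition of normalized means. The reference
    must be measured with positive signal in every condition; its own folds
    come out exactly 1.
    """
    if reference_id not in signals.index:
        raise ReferenceError_(f"reference {reference_id!r} not measured")
    ref = signals.loc[reference_id]
    for cond, v in ref.items():
        if not (v > 0):
            raise ReferenceError_(
                f"reference {reference_id!r} has non-positive signal in {cond}"
            )
    return signals.div(ref, axis=1)


def blank_statistics(plate: pd.DataFrame) -> dict[Condition, tuple[float, float]]:
    """Per-condition (mean, sd) of blank-well fluorescence."""
    out = {}
    blanks = plate[plate["promoter_id"] == BLANK_ID]
    for cond, grp in blanks.groupby(["medium", "phase"], sort=False):
        f = grp["fluorescence"].to_numpy(dtype=float)
        sd = float(f.std(ddof=1)) if len(f) > 1 else 0.0
        out[tuple(cond)] = (float(f.mean()), sd)
    return out


def _overall_class(per_condition: list[str]) -> str:
    """Modal class across conditions; ties resolve toward the lower class."""
    counts: dict[str, int] = {}
    for c in per_condition:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    return min(tied, key=class_index)


def quantify_plate(
    plate: pd.DataFrame,
    reference_id: str = "P_GPD1",
    thresholds: ClassThresholds | None = None,
    phase_ratio_flag: float = 2.0,
    medium_cv_flag: float = 0.5,
) -> dict[str, StrengthProfile]:
    """Full quantification: wells → profiles with folds, classes and flags.

    Phases for the stationary/logarithmic ratio are taken in the order they
    appear in the plate (first seen = logarithmic).
    """
    thresholds = thresholds or ClassThresholds()
    conds: list[Condition] = [
        tuple(c) for c in plate[["medium", "phase"]].drop_duplicates().itertuples(index=False)
    ]
    media = list(dict.fromkeys(m for m, _ in conds))
    phases = list(dict.fromkeys(p for _, p in conds))
    blanks_stats = blank_statistics(plate)
    samples = plate[plate["promoter_id"] != BLANK_ID]
    promoters = sorted(samples["promoter_id"].unique())
    if reference_id not in promoters:
        raise ReferenceError_(f"reference {reference_id!r} absent from plate")

    profiles = {p: StrengthProfile(promoter_id=p) for p in promoters}
    raw_means: dict[tuple[str, Condition], float] = {}
    for (pid, medium, phase), grp in samples.groupby(
        ["promoter_id", "medium", "phase"], sort=False
    ):
        cond = (medium, phase)
        blanks = plate[
            (plate["promoter_id"] == BLANK_ID)
            & (plate["medium"] == medium)
            & (plate["phase"] == phase)
        ]
        mean, sd, n = normalize_signal(grp, blanks)
        prof = profiles[pid]
        prof.signal_mean[cond] = mean
        prof.signal_sd[cond] = sd
        prof.n_replicates[cond] = n
        raw_means[(pid, cond)] = float(grp["fluorescence"].mean())

    signal_df = pd.DataFrame(
        {c: {p: profiles[p].signal_mean.get(c, np.nan) for p in promoters} for c in conds}
    )
    fold_df = relative_strength(signal_df, reference_id)

    for pid in promoters:
        prof = profiles[pid]
        per_cond_classes = []
        for cond in conds:
            fold = float(fold_df.at[pid, cond])
            prof.fold[cond] = fold
            bmean, bsd = blanks_stats.get(cond, (0.0, 0.0))
            detected = raw_means[(pid, cond)] > bmean + 3.0 * bsd
            prof.detected[cond] = detected
            cls = thresholds.label(fold) if detected else "none"
            prof.condition_class[cond] = cls
            per_cond_classes.append(cls)
        prof.overall_class = _overall_class(per_cond_classes)
        prof.extreme_in_all_media = all(
            prof.condition_class.get((m, p)) == "extreme"
            for m in media
            for p in phases
        )
        # responsiveness
        if len(phases) >= 2:
            p_log, p_stat = phases[0], phases[-1]
            for m in media:
                f_log = prof.fold.get((m, p_log))
                f_stat = prof.fold.get((m, p_stat))
                if f_log is None or f_stat is None:
                    continue
                prof.phase_ratio[m] = (
                    math.inf if f_log == 0 else f_stat / f_log
                )
            prof.phase_responsive = any(
                r >= phase_ratio_flag or r <= 1.0 / phase_ratio_flag
                for r in prof.phase_ratio.values()
            )
        for ph in phases:
            folds = np.array([prof.fold[(m, ph)] for m in media if (m, ph) in prof.fold])
            if len(folds) > 1 and folds.mean() > 0:
                prof.medium_cv[ph] = float(folds.std(ddof=1) / folds.mean())
        prof.medium_variable = any(v >= medium_cv_flag for v in prof.medium_cv.values())
    return profiles


def classify(
    profile: StrengthProfile, thresholds: ClassThresholds | None = None
) -> str:
    """(Re)derive per-condition labels and the overall modal class."""
    thresholds = thresholds or ClassThresholds()
    per = []
    for cond, fold in profile.fold.items():
        cls = (
            thresholds.label(fold) if profile.detected.get(cond, True) else "none"
        )
        profile.condition_class[cond] = cls
        per.append(cls)
    profile.overall_class = _overall_class(per)
    return profile.overall_class


def responsiveness(profile: StrengthProfile) -> tuple[dict[str, float], dict[str, float]]:
    """(phase_ratio per medium, medium_cv per phase) as already computed."""
    return profile.phase_ratio, profile.medium_cv


def strength_matrix(profiles: dict[str, StrengthProfile]) -> pd.DataFrame:
    """Dense promoter × condition fold table.

    Rows are sorted by descending overall median fold (promoter id breaks
    ties) — heatmap-ready and the scoring input for pathway design.
    Columns are labelled ``medium:phase``.
    """
    conds = sorted({c for p in profiles.values() for c in p.fold})
    cond_sets = {frozenset(p.fold) for p in profiles.values()}
    if len(cond_sets) > 1:
        raise PromoterMineError("profiles do not share a common condition set")
    rows = {}
    for pid, prof in profiles.items():
        rows[pid] = {f"{m}:{ph}": prof.fold[(m, ph)] for m, ph in conds}
    df = pd.DataFrame.from_dict(rows, orient="index")
    med = df.median(axis=1)
    order = sorted(df.index, key=lambda p: (-med[p], p))
    df = df.loc[order]
    df.index.name = "promoter_id"
    return df


def class_counts(profiles: dict[str, StrengthProfile]) -> dict[str, int]:
    counts = {c: 0 for c in CLASS_ORDER}
    for prof in profiles.values():
        counts[prof.overall_class] += 1
    return counts


def profiles_to_frame(profiles: dict[str, StrengthProfile]) -> pd.DataFrame:
    """Long-form per promoter × condition table for strengths.tsv."""
    rows = []
    for pid in sorted(profiles):
        prof = profiles[pid]
        for cond in sorted(prof.fold):
            m, ph = cond
            rows.append(
                {
                    "promoter_id": pid,
                    "medium": m,
                    "phase": ph,
                    "signal_mean": prof.signal_mean.get(cond),
                    "signal_sd": prof.signal_sd.get(cond),
                    "n": prof.n_replicates.get(cond),
                    "fold_vs_reference": prof.fold[cond],
                    "detected": prof.detected.get(cond),
                    "class": prof.condition_class.get(cond),
                }
            )
    return pd.DataFrame(rows)
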