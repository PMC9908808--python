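"""Domain types shared across the pipeline.

Coordinates follow the GFF3 convention (1-based, inclusive) in all public
dataclasses; internal slicing converts to 0-based half-open at the point of
use. A "condition" is always a ``(medium, phase)`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

Condition = tuple[str, str]

#: Ordered strength classes from undetectable to extreme.
CLASS_ORDER = ("none", "very_weak", "weak", "medium", "strong", "extreme")


class PromoterMineError(Exception):
    """Base class for all pipeline errors."""


class ConsistencyError(PromoterMineError):
    """Raised when derived counts or invariants would become negative/invalid."""


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its translational start.

    ``cds_start`` is the genomic coordinate (1-based) of the first base of
    the start codon; for minus-strand genes this is the *highest* coordinate
    of the coding sequence.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    cds_start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_id}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if not (self.start <= self.cds_start <= self.end):
            raise ValueError(
                f"{self.gene_id}: cds_start {self.cds_start} outside gene body "
                f"{self.start}..{self.end}"
            )


@dataclass
class PromoterCandidate:
    """An upstream promoter region, 5'→3' on the gene's coding strand.

    The sequence ends immediately before the start codon, so offset ``-k``
    (as used by the CT-box scan) is the k-th base counted back from the 3'
    end.
    """

    promoter_id: str
    gene_id: str
    sequence: str
    provenance: frozenset[Condition] = frozenset()
    status: str = "selected"
    truncated: bool = False

    VALID_STATUS = ("selected", "clone_fail", "null", "weak", "strong")

    def __post_init__(self) -> None:
        if self.status not in self.VALID_STATUS:
            raise ValueError(f"invalid status {self.status!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScreeningLedger:
    """Tallies of the candidate filter cascade.

    selected → amplified (candidates − clone failures) → fluorescent, the
    latter split into none / very weak / strong; controls (already-known
    promoters assayed alongside) add to the strong tally.
    """

    n_candidates: int
    n_clone_fail: int
    n_assayed: int
    n_null: int
    n_weak: int
    n_strong: int
    n_controls: int
    n_strong_incl_controls: int

    @classmethod
    def from_counts(
        cls,
        candidates: int,
        clone_fail: int,
        null: int,
        weak: int,
        controls: int = 0,
    ) -> "ScreeningLedger":
        for name, v in (
            ("candidates", candidates),
            ("clone_fail", clone_fail),
            ("null", null),
            ("weak", weak),
            ("controls", controls),
        ):
            if v < 0:
                raise ConsistencyError(f"negative count for {name}: {v}")
        assayed = candidates - clone_fail
        if assayed < 0:
            raise ConsistencyError(
                f"clone failures ({clone_fail}) exceed candidates ({candidates})"
            )
        strong = assayed - null - weak
        if strong < 0:
            raise ConsistencyError(
                f"null ({null}) + weak ({weak}) exceed assayed ({assayed})"
            )
        return cls(
            n_candidates=candidates,
            n_clone_fail=clone_fail,
            n_assayed=assayed,
            n_null=null,
            n_weak=weak,
            n_strong=strong,
            n_controls=controls,
            n_strong_incl_controls=strong + controls,
        )


@dataclass
class MotifReport:
    """Per-promoter core-element and splice-risk diagnostics."""

    promoter_id: str
    caat_positions: list[int] = field(default_factory=list)
    gc_box_positions: list[int] = field(default_factory=list)
    ct_box_found: bool = False
    #: ((start_offset, end_offset) from the start codon, max pyrimidine fraction)
    ct_box_best_window: tuple[tuple[int, int], float] | None = None
    ct_scan_truncated: bool = False
    splice_risk: bool = False
    #: offset of the donor G relative to the promoter 3' end (negative)
    splice_donor_offset: int | None = None
    #: offset of the acceptor relative to the reporter head 5' end
    splice_acceptor_offset: int | None = None


@dataclass
class StrengthProfile:
    """Normalized reporter signal and fold-vs-reference for one promoter."""

    promoter_id: str
    signal_mean: dict[Condition, float] = field(default_factory=dict)
    signal_sd: dict[Condition, float] = field(default_factory=dict)
    n_replicates: dict[Condition, int] = field(default_factory=dict)
    detected: dict[Condition, bool] = field(default_factory=dict)
    fold: dict[Condition, float] = field(default_factory=dict)
    condition_class: dict[Condition, str] = field(default_factory=dict)
    overall_class: str = "none"
    phase_ratio: dict[str, float] = field(default_factory=dict)
    phase_responsive: bool = False
    medium_cv: dict[str, float] = field(default_factory=dict)
    medium_variable: bool = False
    extreme_in_all_media: bool = False


@dataclass
class PathwayDesign:
    """An ordered promoter pair assigned to the (FAD9, FAD12) desaturase steps."""

    design_id: str
    promoter_fad9: str
    promoter_fad12: str
    predicted_score: float | None = None
    #: medium → (linoleic C18:2 mg/L, total fatty acid mg/L)
    titers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for medium, (c18, total) in self.titers.items():
            if c18 < 0 or total < 0 or c18 > total:
                raise ValueError(
                    f"{self.design_id}/{medium}: need 0 <= C18:2 <= total fatty acid"
                )


def class_index(name: str) -> int:
    try:
        return CLASS_ORDER.index(name)
    except ValueError:
        raise ValueError(f"unknown strength class {name!r}") from None


def conditions_of(media: list[str], phases: list[str]) -> list[Condition]:
    """All (medium, phase) pairs in medium-major order."""
    return [(m, p) for m in media for p in phases]
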