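"""Candidate promoter mining from condition-ranked expression.

The mining strategy: rank genes by abundance within each (medium, phase)
condition, take the top N per condition, merge the lists into a
deduplicated candidate set (keeping, per gene, the set of conditions in
which it ranked), then extract a fixed-length upstream window anchored at
the translational start codon — strand-aware, reverse-complemented for
minus-strand genes so every promoter is transcript-oriented.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .models import (
    Condition,
    GeneModel,
    PromoterCandidate,
    PromoterMineError,
    ScreeningLedger,
)

logger = logging.getLogger(__name__)

UPSTREAM_LENGTH = 1000  # bp upstream of the start codon
TOP_N = 15  # top-expressed genes taken per condition


class UnknownConditionError(PromoterMineError):
    pass


class UpstreamExtractionError(PromoterMineError):
    pass


def rank_top_genes(
    matrix: pd.DataFrame, condition: Condition, n: int
) -> list[str]:
    """The ``n`` genes with highest abundance in ``condition``, descending.

    ``matrix`` is gene × condition with a (medium, phase) column MultiIndex.
    Ties are broken by gene_id ascending so the ranking is deterministic and
    data-independent. If ``n`` is at least the number of genes, all genes
    are returned (still sorted).
    """
    if n < 1:
        raise PromoterMineError(f"n must be >= 1, got {n}")
    cond = tuple(condition)
    if cond not in matrix.columns:
        raise UnknownConditionError(f"condition {cond!r} not present in matrix")
    col = matrix[cond]
    if (col < 0).any():
        raise PromoterMineError("negative abundances in expression matrix")
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:n]]


def merge_candidates(
    per_condition: Mapping[Condition, Sequence[str]],
) -> dict[str, frozenset[Condition]]:
    """Deduplicate per-condition top lists, keeping provenance.

    Returns gene → set of conditions in which it appeared, ordered by
    (number of conditions descending, gene_id ascending) for reproducible
    downstream numbering.
    """
    prov: dict[str, set[Condition]] = {}
    for cond, genes in per_condition.items():
        for g in genes:
            prov.setdefault(g, set()).add(tuple(cond))
    ordered = sorted(prov.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return {g: frozenset(cs) for g, cs in ordered}


def extract_upstream(
    genome: Mapping[str, str], gene: GeneModel, length: int = UPSTREAM_LENGTH
) -> tuple[str, bool]:
    """Upstream window of ``length`` bp ending immediately before the start codon.

    Plus strand: genomic slice [cds_start − length, cds_start − 1] (1-based
    inclusive) as-is. Minus strand: [cds_start + 1, cds_start + length]
    reverse-complemented. Windows running off the contig edge are truncated
    to the available portion with the ``truncated`` flag set; zero available
    upstream bases is an error. The returned sequence concatenated with the
    coding sequence read from ``cds_start`` reconstructs a contiguous
    transcript-oriented string.
    """
    if gene.contig not in genome:
        raise UpstreamExtractionError(
            f"{gene.gene_id}: contig {gene.contig!r} not in genome"
        )
    if length < 1:
        raise PromoterMineError(f"length must be >= 1, got {length}")
    contig = genome[gene.contig]
    if gene.strand == "+":
        hi = gene.cds_start - 1  # 0-based exclusive end
        lo = max(0, hi - length)
        seq = contig[lo:hi]
    else:
        lo = gene.cds_start  # 0-based inclusive start just past the start codon
        hi = min(len(contig), lo + length)
        seq = str(Seq(contig[lo:hi]).reverse_complement())
    if not seq:
        raise UpstreamExtractionError(
            f"{gene.gene_id}: no upstream bases on {gene.contig} "
            f"(cds_start={gene.cds_start}, strand={gene.strand})"
        )
    return seq.upper(), len(seq) < length


def _overlap_warning(genes: Sequence[GeneModel], gene: GeneModel, length: int) -> None:
    """Log when the fixed window runs into the upstream neighbouring gene."""
    if gene.strand == "+":
        win_lo, win_hi = gene.cds_start - length, gene.cds_start - 1
    else:
        win_lo, win_hi = gene.cds_start + 1, gene.cds_start + length
    for other in genes:
        if other.gene_id == gene.gene_id or other.contig != gene.contig:
            continue
        if other.start <= win_hi and other.end >= win_lo:
            logger.warning(
                "upstream window of %s overlaps gene %s", gene.gene_id, other.gene_id
            )


def mine_candidates(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    matrix: pd.DataFrame,
    top_n: int = TOP_N,
    length: int = UPSTREAM_LENGTH,
    warn_overlaps: bool = False,
) -> list[PromoterCandidate]:
    """Full mining pass: rank per condition, merge, extract upstream windows.

    Promoters are named ``P_<gene_id>``. Conditions are taken from the
    matrix columns.
    """
    gene_list = list(genes)
    by_id = {g.gene_id: g for g in gene_list}
    per_cond = {
        tuple(c): rank_top_genes(matrix, tuple(c), top_n) for c in matrix.columns
    }
    merged = merge_candidates(per_cond)
    candidates = []
    for gene_id, provenance in merged.items():
        if gene_id not in by_id:
            raise PromoterMineError(f"top-ranked gene {gene_id!r} has no annotation")
        gene = by_id[gene_id]
        if warn_overlaps:
            _overlap_warning(gene_list, gene, length)
        seq, truncated = extract_upstream(genome, gene, length)
        candidates.append(
            PromoterCandidate(
                promoter_id=f"P_{gene_id}",
                gene_id=gene_id,
                sequence=seq,
                provenance=provenance,
                status="selected",
                truncated=truncated,
            )
        )
    return candidates


def screening_ledger(
    candidates: int,
    clone_fail: int,
    null: int,
    weak: int,
    controls: int = 0,
) -> ScreeningLedger:
    """Fill the cascade tallies; refuses inconsistent inputs.

    assayed = candidates − clone_fail; strong = assayed − null − weak;
    strong including controls = strong + controls.
    """
    return ScreeningLedger.from_counts(candidates, clone_fail, null, weak, controls)
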