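"""Core promoter element scanning and cryptic splice-site risk.

Promoter sequences arriving here are transcript-oriented (5'→3' on the
coding strand, ending immediately before the start codon), so every scan is
forward-strand only.

Three diagnostics are computed per promoter:

* literal/IUPAC motif occurrences (CAAT motif, GC box ``GGGCGGG``),
* the pyrimidine-rich CT box just upstream of the start codon, scored as the
  maximal C+T fraction of a sliding window inside −90..−10,
* cryptic intron risk at the promoter–reporter junction: a ``G|GT`` splice
  donor near the promoter 3' end paired with a downstream ``AG|G`` acceptor
  in the junction string (promoter tail + reporter head).
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

from .models import MotifReport, PromoterCandidate, PromoterMineError

#: First 22 bp of the EGFP coding sequence — the fixed reporter head used
#: for junction analysis. Contains AG|G acceptor trigrams.
REPORTER_HEAD = "ATGGTGAGCAAGGGCGAGGAGC"

#: Default element patterns.
CAAT_PATTERN = "CAAT"
GC_BOX_PATTERN = "GGGCGGG"

#: CT-box scan defaults: window −90..−10 from the start codon, 20 bp sliding
#: window, called present at C+T fraction >= 0.6.
CT_WINDOW_START = -90
CT_WINDOW_END = -10
CT_MIN_FRACTION = 0.6
CT_WIN_LEN = 20

#: How deep into the promoter 3' end to look for a splice donor.
JUNCTION_DEPTH = 25

# standard IUPAC nucleotide codes only (drop Biopython's legacy "X")
_IUPAC = {
    k.upper(): set(v.upper())
    for k, v in ambiguous_dna_values.items()
    if k.upper() != "X"
}


def _pattern_sets(pattern: str) -> list[set[str]]:
    sets = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise PromoterMineError(f"invalid IUPAC nucleotide code {ch!r} in pattern")
        sets.append(_IUPAC[ch])
    return sets


def find_motif(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) forward-strand match offsets, ascending.

    ``pattern`` may use IUPAC ambiguity codes; offsets are 0-based from the
    promoter 5' end.
    """
    if not pattern:
        raise PromoterMineError("empty motif pattern")
    sets = _pattern_sets(pattern)
    seq = sequence.upper()
    m = len(sets)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in sets[j] for j in range(m)):
            hits.append(i)
    return hits


def scan_elements(
    candidate: PromoterCandidate,
    caat_pattern: str = CAAT_PATTERN,
    gc_box_pattern: str = GC_BOX_PATTERN,
) -> MotifReport:
    """CAAT-motif and GC-box occurrences for one promoter."""
    if not candidate.sequence:
        raise PromoterMineError(f"{candidate.promoter_id}: empty promoter sequence")
    return MotifReport(
        promoter_id=candidate.promoter_id,
        caat_positions=find_motif(candidate.sequence, caat_pattern),
        gc_box_positions=find_motif(candidate.sequence, gc_box_pattern),
    )


def ct_box_scan(
    candidate: PromoterCandidate,
    window_start: int = CT_WINDOW_START,
    window_end: int = CT_WINDOW_END,
    min_fraction: float = CT_MIN_FRACTION,
    win_len: int = CT_WIN_LEN,
) -> MotifReport:
    """Maximal C+T fraction of a ``win_len`` window within −90..−10.

    Offsets are counted from the start codon: the promoter ends immediately
    before it, so offset −k is the k-th base from the promoter 3' end. On
    ties the 5'-most window is reported. Promoters shorter than the scan
    window are scanned over the available range and flagged.
    """
    seq = candidate.sequence.upper()
    n = len(seq)
    if n == 0:
        raise PromoterMineError(f"{candidate.promoter_id}: empty promoter sequence")
    if window_start >= window_end or window_end > 0:
        raise PromoterMineError("need window_start < window_end <= -1")
    report = MotifReport(promoter_id=candidate.promoter_id)
    eff_start = max(window_start, -n)  # most 5' offset available
    report.ct_scan_truncated = eff_start != window_start or n < -window_end
    if n < -window_end:
        # nothing of the scan region exists
        return report
    # region indices: offset -k maps to index n-k
    lo = n + eff_start
    hi = n + window_end + 1  # exclusive
    region = seq[lo:hi]
    w = min(win_len, len(region))
    if w == 0:
        return report
    best_frac = -1.0
    best_i = 0
    for i in range(len(region) - w + 1):
        window = region[i : i + w]
        frac = sum(1 for ch in window if ch in "CT") / w
        if frac > best_frac:
            best_frac = frac
            best_i = i
    start_off = eff_start + best_i
    end_off = start_off + w - 1
    report.ct_box_best_window = ((start_off, end_off), best_frac)
    report.ct_box_found = best_frac >= min_fraction
    return report


def splice_risk(
    candidate: PromoterCandidate,
    reporter_head: str = REPORTER_HEAD,
    junction_depth: int = JUNCTION_DEPTH,
) -> MotifReport:
    """Flag a cryptic-intron junction: G|GT donor in the promoter tail,
    AG|G acceptor strictly downstream within the junction string.

    The junction string is the last ``junction_depth`` bp of the promoter
    followed by the reporter head. A donor qualifies when the G of its
    ``GGT`` trigram lies within the promoter portion (the GT may extend into
    the reporter). The 5'-most qualifying donor and its nearest downstream
    acceptor are reported: the donor offset is relative to the promoter 3'
    end (negative), the acceptor offset relative to the reporter head 5'
    end.
    """
    if not candidate.sequence:
        raise PromoterMineError(f"{candidate.promoter_id}: empty promoter sequence")
    if len(reporter_head) < 3:
        raise PromoterMineError("reporter head must be at least 3 bp")
    tail = candidate.sequence.upper()[-junction_depth:]
    head = reporter_head.upper()
    junction = tail + head
    plen = len(tail)
    report = MotifReport(promoter_id=candidate.promoter_id)
    acceptors = [a for a in find_motif(junction, "AGG")]
    for d in find_motif(junction, "GGT"):
        if d >= plen:
            break  # donor G must sit inside the promoter portion
        downstream = [a for a in acceptors if a > d]
        if downstream:
            a = downstream[0]
            report.splice_risk = True
            report.splice_donor_offset = d - plen
            report.splice_acceptor_offset = a - plen
            break
    return report


def analyze_promoter(
    candidate: PromoterCandidate,
    reporter_head: str = REPORTER_HEAD,
    caat_pattern: str = CAAT_PATTERN,
    gc_box_pattern: str = GC_BOX_PATTERN,
    ct_min_fraction: float = CT_MIN_FRACTION,
    ct_win_len: int = CT_WIN_LEN,
    junction_depth: int = JUNCTION_DEPTH,
) -> MotifReport:
    """All three diagnostics merged into one report."""
    rep = scan_elements(candidate, caat_pattern, gc_box_pattern)
    ct = ct_box_scan(
        candidate, min_fraction=ct_min_fraction, win_len=ct_win_len
    )
    rep.ct_box_found = ct.ct_box_found
    rep.ct_box_best_window = ct.ct_box_best_window
    rep.ct_scan_truncated = ct.ct_scan_truncated
    sp = splice_risk(candidate, reporter_head, junction_depth)
    rep.splice_risk = sp.splice_risk
    rep.splice_donor_offset = sp.splice_donor_offset
    rep.splice_acceptor_offset = sp.splice_acceptor_offset
    return rep
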