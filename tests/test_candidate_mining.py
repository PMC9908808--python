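"""Ranking, dedup/merge, strand-aware upstream extraction, cascade ledger."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from promotermine.candidate_mining import (
    UnknownConditionError,
    UpstreamExtractionError,
    extract_upstream,
    merge_candidates,
    mine_candidates,
    rank_top_genes,
    screening_ledger,
)
from promotermine.models import ConsistencyError, GeneModel

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def matrix_of(d, condition=("YPD", "logarithmic")):
    cols = pd.MultiIndex.from_tuples([condition], names=["medium", "phase"])
    return pd.DataFrame({cols[0]: pd.Series(d)}, columns=cols)


COND = ("YPD", "logarithmic")


class TestRankTopGenes:
    def test_simple_descending_order(self):
        m = matrix_of({"g1": 5.0, "g2": 9.0, "g3": 1.0})
        assert rank_top_genes(m, COND, 2) == ["g2", "g1"]

    def test_n_equal_gene_count_returns_full_permutation(self):
        m = matrix_of({"g1": 5.0, "g2": 9.0, "g3": 1.0})
        assert rank_top_genes(m, COND, 3) == ["g2", "g1", "g3"]
        assert rank_top_genes(m, COND, 99) == ["g2", "g1", "g3"]

    def test_ties_break_by_gene_id(self):
        m = matrix_of({"b": 2.0, "a": 2.0, "c": 2.0})
        assert rank_top_genes(m, COND, 2) == ["a", "b"]

    def test_unknown_condition_named_in_error(self):
        m = matrix_of({"g1": 1.0})
        with pytest.raises(UnknownConditionError, match="MM"):
            rank_top_genes(m, ("MM", "stationary"), 1)

    def test_matches_full_sort_oracle_on_random_matrix(self, rng):
        vals = {f"g{i:03d}": float(v) for i, v in enumerate(rng.gamma(2, 50, 200))}
        m = matrix_of(vals)
        oracle = [g for g, _ in sorted(vals.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert rank_top_genes(m, COND, 15) == oracle[:15]


class TestMergeCandidates:
    def test_provenance_tracked_across_conditions(self):
        c1, c2 = ("YPD", "log"), ("MM", "log")
        merged = merge_candidates({c1: ["g1", "g2"], c2: ["g2", "g3"]})
        assert merged == {
            "g2": frozenset({c1, c2}),
            "g1": frozenset({c1}),
            "g3": frozenset({c2}),
        }
        assert list(merged) == ["g2", "g1", "g3"]  # breadth first, then id

    def test_identical_lists_collapse(self):
        conds = [(m, p) for m in "ABCD" for p in ("log", "stat")]
        lists = {c: [f"g{i}" for i in range(15)] for c in conds}
        merged = merge_candidates(lists)
        assert len(merged) == 15
        assert all(len(v) == 8 for v in merged.values())

    def test_disjoint_lists_concatenate(self):
        merged = merge_candidates({("A", "x"): ["g1", "g2"], ("B", "x"): ["g3", "g4"]})
        assert len(merged) == 4


GENOME = {"chr1": "AAACCCGGGTTT"}


class TestExtractUpstream:
    def test_plus_strand_hand_slice(self):
        g = GeneModel("g", "chr1", "+", 10, 12, 10)
        seq, truncated = extract_upstream(GENOME, g, 3)
        assert (seq, truncated) == ("GGG", False)

    def test_minus_strand_hand_slice_revcomp(self):
        g = GeneModel("g", "chr1", "-", 1, 3, 3)
        seq, truncated = extract_upstream(GENOME, g, 4)
        assert (seq, truncated) == ("CGGG", False)  # revcomp("CCCG")

    def test_contig_edge_truncates_with_flag(self):
        g = GeneModel("g", "chr1", "+", 3, 5, 3)
        seq, truncated = extract_upstream(GENOME, g, 10)
        assert seq == "AA" and truncated

    def test_zero_upstream_bases_is_error(self):
        g = GeneModel("g", "chr1", "+", 1, 3, 1)
        with pytest.raises(UpstreamExtractionError):
            extract_upstream(GENOME, g, 5)
        g2 = GeneModel("g", "chr1", "-", 10, 12, 12)
        with pytest.raises(UpstreamExtractionError):
            extract_upstream(GENOME, g2, 5)

    def _random_gene(self, rng, contig_len):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, contig_len - 10))
        end = int(rng.integers(start, contig_len + 1))
        cds = int(rng.integers(start, end + 1))
        return GeneModel(f"g{start}", "c", strand, start, end, cds)

    def test_equals_naive_slice_revcomp_oracle(self, rng):
        """100+ random genes, both strands, against a one-line slice oracle."""
        n_checked = 0
        while n_checked < 120:
            contig = "".join(rng.choice(list("ACGT"), size=400))
            genome = {"c": contig}
            g = self._random_gene(rng, 400)
            length = int(rng.integers(1, 60))
            if g.strand == "+":
                oracle = contig[max(0, g.cds_start - 1 - length) : g.cds_start - 1]
            else:
                oracle = revcomp(contig[g.cds_start : g.cds_start + length])
            if not oracle:
                with pytest.raises(UpstreamExtractionError):
                    extract_upstream(genome, g, length)
                continue
            seq, truncated = extract_upstream(genome, g, length)
            assert seq == oracle
            assert truncated == (len(oracle) < length)
            n_checked += 1

    def test_strand_mirror_symmetry(self, rng):
        """Extraction is invariant under reverse-complementing the genome."""
        contig = "".join(rng.choice(list("ACGT"), size=300))
        L = len(contig)
        for _ in range(40):
            g = self._random_gene(rng, L)
            mirrored = GeneModel(
                g.gene_id,
                "c",
                "-" if g.strand == "+" else "+",
                L - g.end + 1,
                L - g.start + 1,
                L - g.cds_start + 1,
            )
            length = int(rng.integers(1, 50))
            try:
                s1, t1 = extract_upstream({"c": contig}, g, length)
            except UpstreamExtractionError:
                with pytest.raises(UpstreamExtractionError):
                    extract_upstream({"c": revcomp(contig)}, mirrored, length)
                continue
            s2, t2 = extract_upstream({"c": revcomp(contig)}, mirrored, length)
            assert (s1, t1) == (s2, t2)

    def test_promoter_plus_cds_is_contiguous_transcript(self, rng):
        """Concatenating window + coding sequence reconstructs the transcript."""
        contig = "".join(rng.choice(list("ACGT"), size=500))
        plus = GeneModel("p", "c", "+", 200, 300, 200)
        minus = GeneModel("m", "c", "-", 200, 300, 300)
        sp, _ = extract_upstream({"c": contig}, plus, 50)
        assert sp + contig[199:300] == contig[149:300]
        sm, _ = extract_upstream({"c": contig}, minus, 50)
        assert sm + revcomp(contig[199:300]) == revcomp(contig[199:350])


class TestScreeningLedger:
    def test_study_cascade_counts(self):
        led = screening_ledger(52, 3, 11, 7, controls=3)
        assert led.n_assayed == 49
        assert led.n_strong == 31
        assert led.n_strong_incl_controls == 34

    def test_all_pass_through(self):
        assert screening_ledger(10, 0, 0, 0, 0).n_strong == 10

    def test_negative_derived_count_rejected(self):
        with pytest.raises(ConsistencyError):
            screening_ledger(5, 6, 0, 0, 0)
        with pytest.raises(ConsistencyError):
            screening_ledger(10, 2, 5, 5, 0)
        with pytest.raises(ConsistencyError):
            screening_ledger(-1, 0, 0, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(0, 100),
        st.integers(0, 100),
        st.integers(0, 100),
        st.integers(0, 100),
        st.integers(0, 10),
    )
    def test_invariants_hold_or_rejected(self, cand, fail, null, weak, controls):
        try:
            led = screening_ledger(cand, fail, null, weak, controls)
        except ConsistencyError:
            assert cand - fail < 0 or cand - fail - null - weak < 0
            return
        assert led.n_assayed == cand - fail >= 0
        assert led.n_strong == led.n_assayed - null - weak >= 0
        assert led.n_strong_incl_controls == led.n_strong + controls


class TestEndToEndMining:
    def test_recovers_planted_candidate_set(self, world0, candidates0, config0):
        mined_genes = {c.gene_id for c in candidates0}
        assert mined_genes == set(world0.candidate_gene_ids)
        assert len(candidates0) == config0.n_candidates_target
        for c in candidates0:
            assert c.length == 1000 and not c.truncated
            assert c.provenance  # every candidate ranked somewhere

    def test_disjoint_support_yields_k_times_n(self, rng):
        genes, genome, rows = [], {}, {}
        contig = "".join(rng.choice(list("ACGT"), size=4000))
        for i in range(6):
            genes.append(GeneModel(f"g{i}", "c", "+", 600 * i + 101, 600 * i + 200, 600 * i + 101))
        genome["c"] = contig
        conds = [("A", "x"), ("B", "x")]
        cols = pd.MultiIndex.from_tuples(conds, names=["medium", "phase"])
        data = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=cols)
        data.loc[["g0", "g1", "g2"], conds[0]] = [30, 20, 10]
        data.loc[["g3", "g4", "g5"], conds[1]] = [30, 20, 10]
        out = mine_candidates(genome, genes, data, top_n=3, length=50)
        assert len(out) == 6  # 2 conditions × top-3, disjoint support
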