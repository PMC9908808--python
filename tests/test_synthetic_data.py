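"""Generator invariants: determinism, planted truth, and recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from promotermine.candidate_mining import extract_upstream, rank_top_genes
from promotermine.models import PathwayDesign
from promotermine.motif_analysis import find_motif
from promotermine.synthetic_data import (
    GAIN,
    GenerationError,
    ROLE_EXTREME,
    SimConfig,
    SimConfigError,
    generate_expression,
    generate_genome,
    generate_plate_reader,
    generate_sugar_series,
    generate_titers,
)
from promotermine.io import write_fasta, write_gff3

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=7, n_genes=60, n_contigs=2)
        paths = []
        for tag in ("a", "b"):
            world = generate_genome(cfg)
            fa = tmp_path / f"{tag}.fasta"
            gff = tmp_path / f"{tag}.gff3"
            write_fasta(world.genome, fa)
            write_gff3(world.genes, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_different_seed_changes_genome(self):
        w1 = generate_genome(SimConfig(seed=1, n_genes=60, n_contigs=2))
        w2 = generate_genome(SimConfig(seed=2, n_genes=60, n_contigs=2))
        assert w1.genome != w2.genome


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clone_fail": 30, "n_null": 15, "n_weak": 10},  # cascade overflow
            {"strength_fold_range": (0.0, 19.0)},
            {"strength_fold_range": (2.0, 1.0)},
            {"fluor_cv": 1.5},
            {"n_genes": 40},  # cannot host 52 candidates
            {"media": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs)


class TestGenomeTruth:
    def test_class_counts_match_config(self, world0, config0):
        classes = list(world0.screening_class_truth.values())
        assert classes.count("clone_fail") == config0.n_clone_fail
        assert classes.count("null") == config0.n_null
        assert classes.count("weak") == config0.n_weak
        assert classes.count("strong") == (
            config0.n_candidates_target
            - config0.n_clone_fail
            - config0.n_null
            - config0.n_weak
        )
        assert classes.count("reference") == 1
        assert classes.count("control") == 2

    def test_reference_strength_is_unity_everywhere(self, world0):
        ref = world0.true_strength[world0.reference_id]
        assert all(v == 1.0 for v in ref.values())

    def test_genes_within_contigs_and_separated(self, world0, config0):
        by_contig = {}
        for g in world0.genes:
            assert 1 <= g.start <= g.end <= len(world0.genome[g.contig])
            by_contig.setdefault(g.contig, []).append(g)
        for genes in by_contig.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end - 1 >= config0.intergenic_min

    def test_candidate_windows_exist_in_full(self, world0):
        for gid in world0.candidate_gene_ids:
            contig, start, end, _ = world0.promoter_windows[f"P_{gid}"]
            assert end - start + 1 == 1000
            assert start >= 1 and end <= len(world0.genome[contig])

    def test_minus_strand_window_matches_recorded_slice(self, world0):
        """Extraction equals the reverse complement of the recorded genomic slice."""
        checked = 0
        genes = {g.gene_id: g for g in world0.genes}
        for gid in world0.candidate_gene_ids:
            g = genes[gid]
            if g.strand != "-":
                continue
            contig, start, end, strand = world0.promoter_windows[f"P_{gid}"]
            assert strand == "-"
            raw = world0.genome[contig][start - 1 : end]
            seq, truncated = extract_upstream(world0.genome, g, 1000)
            assert not truncated
            assert seq == revcomp(raw)
            checked += 1
        assert checked > 5  # both strands are exercised

    def test_planted_gc_box_is_detectable(self, world0, candidates0):
        seqs = {c.promoter_id: c.sequence for c in candidates0}
        planted = [
            pid
            for pid, els in world0.planted_elements.items()
            if "GC_BOX" in els and pid in seqs
        ]
        assert planted
        for pid in planted:
            hits = find_motif(seqs[pid], "GGGCGGG")
            assert world0.planted_offsets[pid]["GC_BOX"][0] in hits


class TestExpression:
    def test_top_lists_union_is_candidate_set(self, world0, expression0, config0):
        union = set()
        for cond in expression0.columns:
            union |= set(rank_top_genes(expression0, tuple(cond), config0.top_n))
        assert union == set(world0.candidate_gene_ids)
        assert len(union) == config0.n_candidates_target

    def test_single_condition_full_topn_is_all_genes(self):
        cfg = SimConfig(
            seed=3, n_genes=60, top_n=60, media=("YPD",), phases=("logarithmic",)
        )
        world = generate_genome(cfg)
        expr = generate_expression(world, cfg)
        top = rank_top_genes(expr, ("YPD", "logarithmic"), cfg.top_n)
        assert set(top) == {g.gene_id for g in world.genes}

    def test_zero_boost_matches_brute_force_sort(self, world0, config0):
        expr = generate_expression(world0, config0, boost=0)
        cond = tuple(expr.columns[0])
        oracle = [
            g for g, _ in sorted(
                expr[cond].items(), key=lambda kv: (-kv[1], kv[0])
            )[:15]
        ]
        assert rank_top_genes(expr, cond, 15) == oracle


class TestPlateReader:
    def test_clone_failures_never_assayed(self, world0, plate0):
        failed = {
            p for p, c in world0.screening_class_truth.items() if c == "clone_fail"
        }
        assert failed
        assert not failed & set(plate0["promoter_id"])

    def test_blanks_present_per_condition(self, plate0, config0):
        blanks = plate0[plate0["promoter_id"] == "blank"]
        per_cond = blanks.groupby(["medium", "phase"]).size()
        assert len(per_cond) == len(config0.conditions)
        assert (per_cond >= 3).all()

    def test_noiseless_forward_model_is_exact(self, world0, plate0):
        """raw F = blank_F + (OD − blank_OD)·gain·strength, replicates identical."""
        blanks = plate0[plate0["promoter_id"] == "blank"]
        bf = blanks["fluorescence"].iloc[0]
        bod = blanks["od600"].iloc[0]
        sample = plate0[plate0["promoter_id"] != "blank"]
        for (pid, m, p), grp in sample.groupby(["promoter_id", "medium", "phase"]):
            strength = world0.true_strength[pid][(m, p)]
            expect = bf + (grp["od600"] - bod) * GAIN * strength
            np.testing.assert_allclose(grp["fluorescence"], expect, rtol=1e-12)

    def test_missing_strength_raises_naming_promoter(self, config0):
        world = generate_genome(config0)
        victim = next(
            p for p, c in world.screening_class_truth.items() if c == "strong"
        )
        del world.true_strength[victim]
        with pytest.raises(GenerationError, match=victim):
            generate_plate_reader(world, config0)


def _pool_designs(world):
    pool = sorted(world.ch_strength)
    return [
        PathwayDesign(f"{a}|{b}", a, b) for a in pool for b in pool
    ]


class TestTiters:
    def test_identical_pairs_identical_titers_at_zero_noise(self, world0, config0):
        designs = [
            PathwayDesign("x", "P_RT12", "P_RT14"),
            PathwayDesign("y", "P_RT12", "P_RT14"),
        ]
        df = generate_titers(world0, designs, config0)
        for medium, grp in df[df["strain_id"] != "parental"].groupby("medium"):
            assert grp["c18_2_mg_per_l"].nunique() == 1

    def test_strongest_promoters_win_in_every_medium(self, world0, config0):
        """Exhaustive pair evaluation of the bottleneck model.

        With repetition allowed the argmax design doubles the single
        strongest promoter; any design using a non-extreme promoter loses
        to the distinct extreme pair.
        """
        df = generate_titers(world0, _pool_designs(world0), config0)
        extreme = {f"P_{g}" for g in ROLE_EXTREME}
        for medium in config0.media:
            folds = {
                p: world0.true_strength[p][(medium, config0.phases[0])]
                for p in world0.ch_strength
            }
            strongest = max(folds, key=folds.get)
            sub = df[(df["medium"] == medium) & (df["strain_id"] != "parental")]
            best = sub.loc[sub["c18_2_mg_per_l"].idxmax()]
            assert {best["promoter_fad9"], best["promoter_fad12"]} == {strongest}
            pair_titer = {
                frozenset((r["promoter_fad9"], r["promoter_fad12"])): r["c18_2_mg_per_l"]
                for _, r in sub.iterrows()
            }
            for pair, titer in pair_titer.items():
                if not pair <= extreme:
                    assert titer < pair_titer[frozenset(extreme)]

    def test_titer_monotone_in_each_promoter_strength(self, world0, config0):
        df = generate_titers(world0, _pool_designs(world0), config0)
        strengths = {
            p: world0.true_strength[p][("YPD", "logarithmic")]
            for p in world0.ch_strength
        }
        sub = df[(df["medium"] == "YPD") & (df["strain_id"] != "parental")]
        titer = {
            (r["promoter_fad9"], r["promoter_fad12"]): r["c18_2_mg_per_l"]
            for _, r in sub.iterrows()
        }
        for (a, b), t in titer.items():
            for (a2, b2), t2 in titer.items():
                if strengths[a2] >= strengths[a] and strengths[b2] >= strengths[b]:
                    assert t2 >= t - 1e-9

    def test_unknown_promoter_in_design_errors(self, world0, config0):
        with pytest.raises(GenerationError, match="P_NOPE"):
            generate_titers(world0, [PathwayDesign("z", "P_NOPE", "P_RT12")], config0)

    def test_c18_never_exceeds_total(self, world0, noisy_config):
        df = generate_titers(world0, None, noisy_config)
        assert (df["c18_2_mg_per_l"] <= df["total_fa_mg_per_l"] + 1e-9).all()


class TestSugars:
    def test_xylose_starts_higher_but_glucose_exhausts_first(self):
        df = generate_sugar_series()
        assert df["xylose_g_l"].iloc[0] > df["glucose_g_l"].iloc[0]
        t_glc = df.loc[df["glucose_g_l"] == 0, "time_h"].min()
        t_xyl = df.loc[df["xylose_g_l"] == 0, "time_h"].min()
        assert t_glc < t_xyl

    def test_concentrations_non_negative_and_time_increasing(self):
        df = generate_sugar_series()
        assert (df.drop(columns="time_h") >= 0).all().all()
        assert (df["time_h"].diff().dropna() > 0).all()
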