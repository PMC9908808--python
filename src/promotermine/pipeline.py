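"""Pipeline orchestration: simulate → mine → motifs → strength → pathway.

Each stage reads its inputs from disk and writes its outputs before the
next stage starts, so any stage can be re-run in isolation from on-disk
intermediates. All TSV outputs carry a header comment with the tool
version, the seed, and a hash of the effective configuration; nothing
time-dependent is written, so identical configs produce byte-identical
output trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .models import PromoterMineError, ScreeningLedger
from . import candidate_mining as cm
from . import motif_analysis as ma
from . import pathway_opt as po
from . import strength_quant as sq
from . import synthetic_data as sd
from .io import (
    expression_from_long,
    expression_to_long,
    read_fasta,
    read_gff3,
    read_tsv,
    write_fasta,
    write_gff3,
    write_tsv,
)

logger = logging.getLogger(__name__)


class StageError(PromoterMineError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    #: SimConfig keyword overrides; None disables the simulate stage, in
    #: which case the input paths below must point at existing files.
    simulate: dict | None = field(default_factory=dict)
    genome: Path | None = None
    gff: Path | None = None
    expression: Path | None = None
    plate: Path | None = None
    titers: Path | None = None
    sugars: Path | None = None
    top_n: int = cm.TOP_N
    length: int = cm.UPSTREAM_LENGTH
    reference_id: str = sd.REFERENCE_ID
    caat_pattern: str = ma.CAAT_PATTERN
    gc_box_pattern: str = ma.GC_BOX_PATTERN
    ct_min_fraction: float = ma.CT_MIN_FRACTION
    ct_win_len: int = ma.CT_WIN_LEN
    junction_depth: int = ma.JUNCTION_DEPTH
    reporter_head: str = ma.REPORTER_HEAD
    sat_k: float = po.SAT_K
    horizon_h: float = 30.0
    sugar_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("genome", "gff", "expression", "plate", "titers", "sugars"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        inputs = raw.pop("inputs", {})
        params = raw.pop("params", {})
        return cls(**{**raw, **inputs, **params})

    def sim_config(self) -> sd.SimConfig:
        kwargs = dict(self.simulate or {})
        kwargs.setdefault("seed", self.seed)
        for key in ("media", "phases", "gene_length_range", "strength_fold_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return sd.SimConfig(**kwargs)

    def header(self) -> list[str]:
        # hash only the scientific parameters, not filesystem locations, so
        # equal analyses in different directories share a config id
        path_fields = {"outdir", "genome", "gff", "expression", "plate", "titers", "sugars"}
        blob = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in path_fields
        }
        digest = hashlib.sha1(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return [f"promotermine v{__version__}", f"seed={self.seed}", f"config={digest}"]


def _out(cfg: PipelineConfig, name: str) -> Path:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    return cfg.outdir / name


def run_simulate(cfg: PipelineConfig) -> None:
    sim = cfg.sim_config()
    bundle = sd.generate_all(sim)
    world = bundle["world"]
    write_fasta(world.genome, _out(cfg, "genome.fasta"))
    write_gff3(world.genes, _out(cfg, "genes.gff3"), cfg.header())
    write_tsv(expression_to_long(bundle["expression"]), _out(cfg, "expression.tsv"), cfg.header())
    write_tsv(bundle["plate"], _out(cfg, "plate.tsv"), cfg.header(), float_format="%.8g")
    write_tsv(bundle["titers"], _out(cfg, "titers.tsv"), cfg.header())
    write_tsv(bundle["sugars"], _out(cfg, "sugars.tsv"), cfg.header())
    write_tsv(sd.truth_table(world), _out(cfg, "truth.tsv"), cfg.header())
    cfg.genome = _out(cfg, "genome.fasta")
    cfg.gff = _out(cfg, "genes.gff3")
    cfg.expression = _out(cfg, "expression.tsv")
    cfg.plate = _out(cfg, "plate.tsv")
    cfg.titers = _out(cfg, "titers.tsv")
    cfg.sugars = _out(cfg, "sugars.tsv")


def run_mine(cfg: PipelineConfig) -> list:
    genome = read_fasta(cfg.genome)
    genes = read_gff3(cfg.gff)
    matrix = expression_from_long(read_tsv(cfg.expression))
    candidates = cm.mine_candidates(
        genome, genes, matrix, top_n=cfg.top_n, length=cfg.length, warn_overlaps=False
    )
    rows = [
        {
            "promoter_id": c.promoter_id,
            "gene_id": c.gene_id,
            "provenance": ";".join(f"{m}:{p}" for m, p in sorted(c.provenance)),
            "n_conditions": len(c.provenance),
            "truncated": c.truncated,
        }
        for c in candidates
    ]
    write_tsv(pd.DataFrame(rows), _out(cfg, "candidates.tsv"), cfg.header())
    write_fasta(
        {c.promoter_id: c.sequence for c in candidates}, _out(cfg, "promoters.fasta")
    )
    return candidates


def run_motifs(cfg: PipelineConfig) -> pd.DataFrame:
    from .models import PromoterCandidate

    promoters = read_fasta(cfg.outdir / "promoters.fasta")
    rows = []
    for pid, seq in promoters.items():
        cand = PromoterCandidate(promoter_id=pid, gene_id=pid.removeprefix("P_"), sequence=seq)
        rep = ma.analyze_promoter(
            cand,
            reporter_head=cfg.reporter_head,
            caat_pattern=cfg.caat_pattern,
            gc_box_pattern=cfg.gc_box_pattern,
            ct_min_fraction=cfg.ct_min_fraction,
            ct_win_len=cfg.ct_win_len,
            junction_depth=cfg.junction_depth,
        )
        window, frac = rep.ct_box_best_window or ((None, None), float("nan"))
        rows.append(
            {
                "promoter_id": pid,
                "n_caat": len(rep.caat_positions),
                "caat_offsets": ",".join(map(str, rep.caat_positions)),
                "n_gc_box": len(rep.gc_box_positions),
                "gc_box_offsets": ",".join(map(str, rep.gc_box_positions)),
                "ct_fraction": frac,
                "ct_window_start": window[0],
                "ct_window_end": window[1],
                "ct_box_found": rep.ct_box_found,
                "splice_risk": rep.splice_risk,
                "splice_donor_offset": rep.splice_donor_offset,
                "splice_acceptor_offset": rep.splice_acceptor_offset,
            }
        )
    df = pd.DataFrame(rows).sort_values("promoter_id", kind="mergesort").reset_index(drop=True)
    write_tsv(df, _out(cfg, "motifs.tsv"), cfg.header())
    return df


def run_strength(cfg: PipelineConfig) -> dict:
    plate = read_tsv(cfg.plate)
    profiles = sq.quantify_plate(plate, reference_id=cfg.reference_id)
    write_tsv(sq.profiles_to_frame(profiles), _out(cfg, "strengths.tsv"), cfg.header())
    matrix = sq.strength_matrix(profiles)
    write_tsv(matrix, _out(cfg, "strength_matrix.tsv"), cfg.header(), index=True)
    rows = []
    for pid in sorted(profiles):
        prof = profiles[pid]
        ratios = prof.phase_ratio.values()
        rows.append(
            {
                "promoter_id": pid,
                "overall_class": prof.overall_class,
                "extreme_in_all_media": prof.extreme_in_all_media,
                "phase_responsive": prof.phase_responsive,
                "max_phase_ratio": max(ratios) if ratios else float("nan"),
                "medium_variable": prof.medium_variable,
            }
        )
    write_tsv(pd.DataFrame(rows), _out(cfg, "classes.tsv"), cfg.header())
    return profiles


def run_pathway(cfg: PipelineConfig, matrix: pd.DataFrame) -> dict:
    titers = read_tsv(cfg.titers)
    pool = list(
        dict.fromkeys(
            p
            for col in ("promoter_fad9", "promoter_fad12")
            for p in titers[col].dropna()
            if isinstance(p, str) and p
        )
    )
    media = [
        m
        for m in dict.fromkeys(titers["medium"])
        if any(c.startswith(f"{m}:") for c in matrix.columns)
    ]
    design_frames = []
    for medium in media:
        designs = po.enumerate_designs(pool)
        design_frames.append(po.score_designs(designs, matrix, medium, k=cfg.sat_k))
    designs_df = pd.concat(design_frames, ignore_index=True)
    write_tsv(designs_df, _out(cfg, "designs.tsv"), cfg.header())

    imp_rows = []
    for medium in dict.fromkeys(titers["medium"]):
        sub = titers[titers["medium"] == medium]
        parental = sub.loc[sub["strain_id"] == "parental", "c18_2_mg_per_l"]
        if parental.empty:
            continue
        winners = po.best_design(titers, medium)
        best = float(
            sub.loc[sub["strain_id"] == winners[0], "c18_2_mg_per_l"].iloc[0]
        )
        imp_rows.append(
            {
                "medium": medium,
                "parental_c18_2": float(parental.iloc[0]),
                "best_strain": ";".join(winners),
                "best_c18_2": best,
                "improvement_pct": po.percent_improvement(best, float(parental.iloc[0])),
            }
        )
    improvement = pd.DataFrame(imp_rows)
    write_tsv(improvement, _out(cfg, "improvement.tsv"), cfg.header())

    summary = None
    if cfg.sugars is not None and Path(cfg.sugars).exists():
        series = read_tsv(cfg.sugars)
        summary = po.sugar_summary(
            series, horizon_h=cfg.horizon_h, threshold=cfg.sugar_threshold
        )
        rows = [
            {
                "sugar": s,
                "consumed_fraction": summary["consumed_fraction"][s],
                "exhaustion_time_h": summary["exhaustion_time_h"].get(s),
            }
            for s in summary["consumed_fraction"]
        ]
        rows.append(
            {
                "sugar": "total",
                "consumed_fraction": summary["total_consumed_fraction"],
                "exhaustion_time_h": None,
            }
        )
        write_tsv(pd.DataFrame(rows), _out(cfg, "sugar_summary.tsv"), cfg.header())
    return {"designs": designs_df, "improvement": improvement, "sugar": summary}


def _ledger_from_outputs(candidates, profiles) -> ScreeningLedger:
    mined = {c.promoter_id for c in candidates}
    assayed = set(profiles)
    clone_fail = sorted(mined - assayed)
    controls = sorted(assayed - mined)
    null = [p for p in sorted(mined & assayed) if profiles[p].overall_class == "none"]
    weak = [
        p for p in sorted(mined & assayed) if profiles[p].overall_class == "very_weak"
    ]
    return cm.screening_ledger(
        candidates=len(mined),
        clone_fail=len(clone_fail),
        null=len(null),
        weak=len(weak),
        controls=len(controls),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the artifact bundle."""
    results: dict = {}
    stage = "simulate"
    try:
        if cfg.simulate is not None:
            run_simulate(cfg)
        stage = "mine"
        candidates = run_mine(cfg)
        results["candidates"] = candidates
        stage = "motifs"
        results["motifs"] = run_motifs(cfg)
        stage = "strength"
        profiles = run_strength(cfg)
        results["profiles"] = profiles
        matrix = sq.strength_matrix(profiles)
        results["strength_matrix"] = matrix
        stage = "ledger"
        ledger = _ledger_from_outputs(candidates, profiles)
        results["ledger"] = ledger
        stage = "pathway"
        if cfg.titers is not None and Path(cfg.titers).exists():
            results["pathway"] = run_pathway(cfg, matrix)
        else:
            logger.info("no titer table configured; pathway stage skipped")
            results["pathway"] = None
        stage = "report"
        results["report"] = write_report(cfg, results)
    except PromoterMineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise StageError(stage, exc) from exc
    return results


def write_report(cfg: PipelineConfig, results: dict) -> pd.DataFrame:
    """Consolidated report.tsv: ledger, strength extremes, best designs."""
    rows: list[tuple[str, str, str]] = []
    ledger: ScreeningLedger = results["ledger"]
    for k in (
        "n_candidates",
        "n_clone_fail",
        "n_assayed",
        "n_null",
        "n_weak",
        "n_strong",
        "n_controls",
        "n_strong_incl_controls",
    ):
        rows.append(("ledger", k, str(getattr(ledger, k))))

    profiles = results["profiles"]
    mined = {c.promoter_id for c in results["candidates"]}
    strong = [
        p
        for p in sorted(mined & set(profiles))
        if profiles[p].overall_class not in ("none", "very_weak")
    ]
    if strong:
        fold_items = [
            (profiles[p].fold[c], p, c) for p in strong for c in profiles[p].fold
        ]
        fmin = min(fold_items)
        fmax = max(fold_items)
        rows.append(("strength", "min_fold", f"{fmin[0]:.4g}"))
        rows.append(("strength", "min_fold_at", f"{fmin[1]}|{fmin[2][0]}:{fmin[2][1]}"))
        rows.append(("strength", "max_fold", f"{fmax[0]:.4g}"))
        rows.append(("strength", "max_fold_at", f"{fmax[1]}|{fmax[2][0]}:{fmax[2][1]}"))
        extreme = [p for p in strong if profiles[p].extreme_in_all_media]
        rows.append(("strength", "extreme_in_all_media", ";".join(extreme)))
        ratios = [
            (r, p, m)
            for p in strong
            for m, r in profiles[p].phase_ratio.items()
            if r != float("inf")
        ]
        if ratios:
            rmax = max(ratios)
            rows.append(("strength", "max_phase_ratio", f"{rmax[0]:.4g}"))
            rows.append(("strength", "max_phase_ratio_at", f"{rmax[1]}|{rmax[2]}"))

    pathway = results.get("pathway")
    if pathway:
        for _, r in pathway["improvement"].iterrows():
            rows.append(
                ("pathway", f"best_design_{r['medium']}", str(r["best_strain"]))
            )
            rows.append(
                (
                    "pathway",
                    f"improvement_pct_{r['medium']}",
                    f"{r['improvement_pct']:.1f}",
                )
            )
        if pathway["sugar"] is not None:
            s = pathway["sugar"]
            rows.append(
                ("sugars", "total_consumed_fraction", f"{s['total_consumed_fraction']:.4f}")
            )
            rows.append(("sugars", "exhaustion_order", ";".join(s["exhaustion_order"])))
            rows.append(("sugars", "meets_threshold", str(s["meets_threshold"])))

    report = pd.DataFrame(rows, columns=["section", "key", "value"])
    write_tsv(report, _out(cfg, "report.tsv"), cfg.header())
    return report
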