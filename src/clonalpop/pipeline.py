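"""End-to-end orchestration: simulate, classify, analyse, report.

One YAML config drives every stage; all randomness derives from the single
top-level seed, so a config+seed pair reproduces its run report byte for
byte (timestamps excluded by construction — none are recorded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ClonalpopError, ValidationError
from . import enrichment, karyotype, ld_decay, phylo, ploidy, synthetic, variant_stats
from .io_formats import (
    read_assembly_stats,
    read_depth_tsv,
    read_fasta_alignment,
    read_genotype_vcf,
    read_strain_table,
)

log = logging.getLogger("clonalpop")


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping, invariant to key order."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "clonalpop_run")
    return cfg


def _sim_config(cfg: dict) -> synthetic.SimConfig:
    section = dict(cfg.get("simulate", {}))
    allowed = {f.name for f in dc_fields(synthetic.SimConfig)}
    unknown = set(section) - allowed
    if unknown:
        raise ValidationError(f"unknown simulate options: {sorted(unknown)}")
    section.setdefault("seed", cfg["seed"])
    if "aneuploid_segments" in section:
        section["aneuploid_segments"] = [
            synthetic.AneuploidSegmentSpec(**d) for d in section["aneuploid_segments"]
        ]
    if "loh_tracts" in section:
        section["loh_tracts"] = [
            synthetic.LOHTractSpec(**d) for d in section["loh_tracts"]
        ]
    for key in ("descendants_per_event", "region_length_range"):
        if key in section:
            section[key] = tuple(section[key])
    return synthetic.SimConfig(**section)


def run_pipeline(config_path: str | Path) -> dict:
    """Run every enabled stage in dependency order and write report.json.

    A stage failure stops the run; the partial report (with the failing
    stage's error) is still written.  Returns the report dict.
    """
    cfg = load_config(config_path)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
    }
    stages = [
        ("simulate", _stage_simulate),
        ("ploidy", _stage_ploidy),
        ("stats", _stage_stats),
        ("ld", _stage_ld),
        ("karyotype", _stage_karyotype),
        ("phylo", _stage_phylo),
        ("enrich", _stage_enrich),
    ]
    enabled = cfg.get("stages", [name for name, _ in stages])
    if "simulate" in enabled:
        _sim_config(cfg)  # pre-flight: reject bad configs before any stage runs
    context: dict = {"cfg": cfg, "out": out}
    failed = False
    for name, fn in stages:
        if name not in enabled:
            report["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        try:
            result = fn(context)
        except ClonalpopError as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            log.error("stage %s failed: %s", name, exc)
            failed = True
            break
        elapsed = time.perf_counter() - t0
        log.info("stage %s ok (%.2f s)", name, elapsed)
        report["stages"][name] = {"status": "ok", **result}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if failed:
        raise ClonalpopError("pipeline stopped at a failed stage (see report.json)")
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(ctx: dict) -> dict:
    sim_cfg = _sim_config(ctx["cfg"])
    truth = synthetic.write_simulation(sim_cfg, ctx["out"])
    ctx["sim_cfg"] = sim_cfg
    ctx["truth"] = truth
    return {
        "n_strains": len(truth.ploidy),
        "n_events_planted": len(truth.events),
    }


def _require(ctx: dict, name: str, path: Path) -> Path:
    if not path.exists():
        raise ValidationError(f"stage {name}: missing input {path}")
    return path


def _stage_ploidy(ctx: dict) -> dict:
    path = _require(ctx, "ploidy", ctx["out"] / "assembly_stats.tsv")
    calls = ploidy.classify_many(read_assembly_stats(path))
    rows = [
        f"{c.strain_id}\t{c.call}\t{c.size_band}\t{c.genes_band}\t{c.copy_band}"
        for c in calls
    ]
    (ctx["out"] / "ploidy_calls.tsv").write_text(
        "strain_id\tcall\tsize_band\tgenes_band\tcopy_band\n" + "\n".join(rows) + "\n"
    )
    ctx["ploidy_calls"] = {c.strain_id: c.call for c in calls}
    return {"calls": {c.strain_id: str(c.call) for c in calls}}


def _load_gm(ctx: dict):
    if "gm" not in ctx:
        meta = read_strain_table(
            _require(ctx, "stats", ctx["out"] / "strains.tsv")
        )
        ploidy_map = {m.strain_id: int(m.ploidy_label) for m in meta}
        ctx["meta"] = meta
        ctx["gm"] = read_genotype_vcf(ctx["out"] / "genotypes.vcf", ploidy_map)
    return ctx["gm"]


def _stage_stats(ctx: dict) -> dict:
    gm = _load_gm(ctx)
    genome_length = ctx["sim_cfg"].genome_length if "sim_cfg" in ctx else int(
        ctx["cfg"].get("genome_length", 0)
    )
    if genome_length <= 0:
        raise ValidationError("stats stage needs a genome_length")
    summaries = variant_stats.snp_summaries(gm, genome_length)
    with open(ctx["out"] / "snp_summaries.tsv", "w") as fh:
        fh.write("strain_id\ttotal_snp_density\thet_snp_density\thet_fraction\n")
        for s in summaries:
            fh.write(
                f"{s.strain_id}\t{s.total_snp_density:.6f}\t{s.het_snp_density:.6f}"
                f"\t{s.het_fraction_of_snps:.4f}\n"
            )
    pc = variant_stats.pca(gm, n_components=2)
    np.savetxt(
        ctx["out"] / "pca_scores.tsv",
        pc.scores,
        delimiter="\t",
        header="\t".join(["PC1", "PC2"]),
        comments="",
    )
    return {
        "mean_total_snp_density": float(
            np.mean([s.total_snp_density for s in summaries])
        ),
        "pc12_variance_explained": float(pc.variance_explained.sum()),
    }


def _stage_ld(ctx: dict) -> dict:
    gm = _load_gm(ctx)
    opts = ctx["cfg"].get("ld", {})
    filtered = ld_decay.filter_ld_loci(gm)
    pairs = ld_decay.pairwise_r2(filtered, max_dist=int(opts.get("max_dist", 10_000)))
    curve = ld_decay.ld_curve(
        pairs,
        bin_width=int(opts.get("bin_width", 100)),
        smoother_span=float(opts.get("smoother_span", 0.3)),
    )
    with open(ctx["out"] / "ld_curve.tsv", "w") as fh:
        fh.write("bin_mid\tn_pairs\tmean_r2\tsmoothed_r2\n")
        for k in range(len(curve.bin_mid)):
            fh.write(
                f"{curve.bin_mid[k]:.0f}\t{curve.n_pairs[k]}\t"
                f"{curve.mean_r2[k]:.5f}\t{curve.smoothed_r2[k]:.5f}\n"
            )
    return {
        "max_observed": curve.max_observed,
        "half_max": curve.half_max,
        "half_decay_distance": curve.half_decay_distance,
    }


def _stage_karyotype(ctx: dict) -> dict:
    cfg = ctx["cfg"]
    kopts = cfg.get("karyotype", {})
    acfg = karyotype.AnalysisConfig(
        **{k: v for k, v in kopts.items() if k in karyotype.AnalysisConfig.__dataclass_fields__}
    )
    depth_dir = _require(ctx, "karyotype", ctx["out"] / "depth")
    gm = _load_gm(ctx)
    sim_cfg = ctx.get("sim_cfg")
    contig_lengths = (
        {name: end - start for name, start, end in sim_cfg.contig_table()}
        if sim_cfg
        else {}
    )
    aneuploid = []
    loh = []
    for meta in ctx["meta"]:
        sid = meta.strain_id
        pl = int(meta.ploidy_label)
        raw = read_depth_tsv(depth_dir / f"{sid}.tsv")
        track = karyotype.window_depth(raw, acfg)
        aneuploid += karyotype.call_aneuploid_segments(track, pl, acfg, strain_id=sid)
        if pl == 2:
            try:
                het = karyotype.window_heterozygosity(gm, sid, contig_lengths, acfg)
            except ValidationError:
                continue
            loh += karyotype.call_loh_segments(het, track, acfg, strain_id=sid)
    with open(ctx["out"] / "segments.bed", "w") as fh:
        for seg in aneuploid:
            fh.write(
                f"{seg.contig}\t{seg.start}\t{seg.end}\t"
                f"{seg.strain_id}:copy{seg.copy_state}\t{seg.mean_ratio:.3f}\n"
            )
        for seg in loh:
            fh.write(
                f"{seg.contig}\t{seg.start}\t{seg.end}\t"
                f"{seg.strain_id}:LOH_{seg.classification}\t{seg.mean_depth_ratio:.3f}\n"
            )
    ctx["aneuploid_segments"] = aneuploid
    return {"n_aneuploid_segments": len(aneuploid), "n_loh_segments": len(loh)}


def _stage_phylo(ctx: dict) -> dict:
    regions_dir = _require(ctx, "phylo", ctx["out"] / "regions")
    meta = ctx["meta"]
    ploidy_map = {m.strain_id: int(m.ploidy_label) for m in meta}
    alignments = []
    for path in sorted(regions_dir.glob("*.fasta")):
        seqs = read_fasta_alignment(path)
        alignments.append(
            phylo.RegionAlignment(path.stem, seqs, len(next(iter(seqs.values()))))
        )
    popts = ctx["cfg"].get("phylo", {})
    selected = phylo.select_regions(
        alignments,
        ploidy_map,
        n=int(popts.get("n_regions", 50)),
        gap_threshold=float(popts.get("gap_threshold", 0.15)),
    )
    trees = [phylo.region_tree(a) for a in selected]
    score = phylo.concordance_score(trees)
    labels, avg = phylo.average_distance_matrix(selected)
    assignment = phylo.assign_subgenomes(labels, avg, ploidy_map)
    events = phylo.infer_hybrid_events(assignment, labels, avg, ploidy_map)
    with open(ctx["out"] / "events.tsv", "w") as fh:
        fh.write("event_id\tparents\tmembers\n")
        for g in events.groups:
            fh.write(f"{g.event_id}\t{'+'.join(g.parents)}\t{','.join(g.members)}\n")
    groups = {}
    for g in events.groups:
        for m in g.members:
            groups[m] = f"event{g.event_id}"
    for (strain, letter), lin in assignment.assignments.items():
        if letter == "":  # haploid strains group with their own lineage
            groups.setdefault(strain, f"lineage_{lin}")
    ctx["groups"] = groups
    return {
        "n_regions": len(selected),
        "concordance": score,
        "n_events": len(events.groups),
        "n_unplaced": len(events.unplaced),
    }


def _stage_enrich(ctx: dict) -> dict:
    if "groups" not in ctx:
        raise ValidationError("enrich stage requires the phylo stage")
    opts = ctx["cfg"].get("enrich", {})
    n_sim = int(opts.get("n_sim", 10_000))
    result = {}
    for field in ("habitat_class", "continent"):
        p, built = enrichment.group_enrichment(
            ctx["meta"],
            ctx["groups"],
            field=field,
            n_sim=n_sim,
            seed=int(ctx["cfg"]["seed"]),
        )
        result[field] = {"p_value": p, "n_excluded": built.n_excluded}
    return result
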