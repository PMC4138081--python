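"""End-to-end orchestration: simulate -> qc -> map -> discover -> context
-> express, with a machine-readable run report.

A single integer seed drives every stochastic stage; two runs with the
same config produce byte-identical outputs (no timestamps, stable
ordering).  The report carries a conservation ledger (reads in = reads
accounted for at every stage) that is asserted when the report is built.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import context as ctx
from . import discovery as disc
from . import expression as expr
from . import formats_io as fio
from . import read_processing as rp
from . import synthetic as syn
from .models import oyster_sample_sheet


STAGE_ORDER = ("simulate", "qc", "map", "discover", "context", "express")


@dataclass
class SyntheticConfig:
    n_scaffolds: int = 3
    scaffold_length: int = 70_000
    gene_density: float = 0.40
    n_true: int = 40
    n_decoys_per_criterion: int = 10
    n_clusters: int = 4
    cluster_size: int = 3


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "mirforge_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    noise: syn.NoiseModel = field(default_factory=syn.NoiseModel)
    thresholds: disc.CriteriaThresholds = field(
        default_factory=disc.CriteriaThresholds)
    extraction: disc.ExtractionParams = field(
        default_factory=disc.ExtractionParams)
    window_length: int = ctx.DEFAULT_WINDOW
    flanks: tuple[int, ...] = ctx.DEFAULT_FLANKS
    max_gap: int = ctx.DEFAULT_MAX_GAP
    write_fastq: bool = True
    # stage toggles; each stage depends on all earlier ones, so the
    # enabled set must form a prefix of the stage order
    stages: tuple[str, ...] = STAGE_ORDER


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data; returns the report dict and
    writes all stage outputs under config.outdir."""
    enabled = set(config.stages)
    unknown = enabled - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for i, name in enumerate(STAGE_ORDER):
        if name in enabled:
            missing = [s for s in STAGE_ORDER[:i] if s not in enabled]
            if missing:
                raise ValueError(
                    f"stage {name!r} requires disabled stage(s) {missing}")
    n_run = max(
        (i + 1 for i, s in enumerate(STAGE_ORDER) if s in enabled), default=0)
    run_upto = STAGE_ORDER[:n_run]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    samples = oyster_sample_sheet()
    if not run_upto:
        return report

    # ---- simulate
    stage = "simulate"
    try:
        specs = syn.study_plants(
            samples,
            n_true=config.synthetic.n_true,
            n_decoys_per_criterion=config.synthetic.n_decoys_per_criterion,
            seed=config.seed,
            n_clusters=config.synthetic.n_clusters,
            cluster_size=config.synthetic.cluster_size,
        )
        truth = syn.plant_genome(
            config.synthetic.n_scaffolds,
            config.synthetic.scaffold_length,
            config.synthetic.gene_density,
            specs,
            seed=config.seed + 1,
        )
        reads = syn.simulate_reads(truth, samples, config.noise,
                                   seed=config.seed + 2)
        fio.write_fasta(truth.genome, outdir / "genome.fa")
        fio.write_gene_gff(truth.genes, outdir / "genes.gff3")
        fio.write_sample_sheet(samples, outdir / "samples.tsv")
        syn.write_truth(truth, outdir / "truth.tsv", outdir / "truth.json")
        with open(outdir / "catalog.tsv", "w") as fh:
            fh.write("sequence\tfamily\tphylostratum\n")
            for seq, fam, rank in truth.catalog:
                fh.write(f"{seq}\t{fam}\t{rank}\n")
        if config.write_fastq:
            rdir = outdir / "reads"
            rdir.mkdir(exist_ok=True)
            for sid in samples.sample_ids:
                syn.write_fastq(reads[sid], rdir / f"{sid}.fastq")
        report["stages"][stage] = {
            "n_plants": len(truth.plants),
            "n_true": sum(1 for p in truth.plants
                          if p.spec.violated_criterion is None),
            "n_reads": {sid: len(reads[sid]) for sid in samples.sample_ids},
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "qc" not in enabled:
        return _finalize(report, config, outdir)

    # ---- qc + collapse
    stage = "qc"
    try:
        tags: dict[str, rp.ReadTag] = {}
        qc_tally = {"length": 0, "mean_error": 0, "q10": 0, "q13": 0}
        n_in = n_pass = 0
        for sid in samples.sample_ids:
            passed = []
            for _rid, seq, qual in reads[sid]:
                n_in += 1
                quals = [ord(c) - 33 for c in qual]
                reason = rp.qc_read(seq, quals)
                if reason is None:
                    passed.append(seq)
                else:
                    qc_tally[reason] += 1
            n_pass += len(passed)
            rp.collapse(passed, sid, into=tags)
        report["stages"][stage] = {
            "reads_in": n_in, "reads_passed": n_pass,
            "rejected": qc_tally, "distinct_tags": len(tags),
        }
        assert n_in == n_pass + sum(qc_tally.values())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "map" not in enabled:
        return _finalize(report, config, outdir)

    # ---- map + exclude
    stage = "map"
    try:
        mapres = rp.map_exact(tags, truth.genome)
        excl = rp.exclude_annotated(mapres.alignments, truth.genes)
        mapped_tags = {a.tag.sequence for a in mapres.alignments}
        mapped_reads = sum(tags[s].total_count for s in mapped_tags)
        report["stages"][stage] = {
            "tags_mapped": len(mapped_tags),
            "tags_unmapped": len(mapres.unmapped),
            "reads_mapped": mapped_reads,
            "reads_unmapped": mapres.n_unmapped_reads,
            "alignments": len(mapres.alignments),
            "alignments_retained": len(excl.retained),
            "alignments_excluded": len(excl.excluded),
            "excluded_by_class": excl.tally,
        }
        assert mapped_reads + mapres.n_unmapped_reads == sum(
            t.total_count for t in tags.values())
        fio.write_alignment_tsv(excl.retained, outdir / "alignments.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "discover" not in enabled:
        return _finalize(report, config, outdir)

    # ---- discover
    stage = "discover"
    try:
        accepted, allc = disc.discover(
            excl.retained, truth.genome, config.extraction,
            config.thresholds, truth.catalog,
        )
        fail_tally: dict[int, int] = {i: 0 for i in range(1, 7)}
        for c in allc:
            for i in c.verdict.failed:
                fail_tally[i] += 1
        report["stages"][stage] = {
            "windows_evaluated": len(allc),
            "accepted": len(accepted),
            "rejected": len(allc) - len(accepted),
            "failures_by_criterion": fail_tally,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "context" not in enabled:
        return _finalize(report, config, outdir)

    # ---- context
    stage = "context"
    try:
        annotated = [ctx.classify_location(c, truth.genes) for c in accepted]
        annotated = ctx.find_clusters(annotated, config.max_gap)
        fio.write_precursor_gff(annotated, outdir / "precursors.gff3")
        profile = ctx.flank_extension_profile(
            annotated, truth.genome, truth.genes, config.flanks,
            config.window_length,
        )
        n_intra = sum(1 for a in annotated
                      if a.location_class.startswith("intronic")
                      or a.location_class == "exonic")
        null0 = profile[0]["null"]
        chi = None
        if annotated:
            chi_stat, chi_p, low = ctx.compare_proportions(
                n_intra, len(annotated),
                null0.n_overlapping_gene, null0.n_windows,
            )
            chi = {"statistic": chi_stat, "p": chi_p, "low_expected": low}
        clustered = sum(1 for a in annotated if a.cluster_id)
        report["stages"][stage] = {
            "n_precursors": len(annotated),
            "by_class": {
                cls: sum(1 for a in annotated if a.location_class == cls)
                for cls in ("intronic_sense", "intronic_antisense",
                            "exonic", "intergenic")
            },
            "intragenic_fraction": n_intra / len(annotated) if annotated else 0.0,
            "window_null_fraction": null0.fraction,
            "chi_square": chi,
            "n_clustered": clustered,
            "n_clusters": len({a.cluster_id for a in annotated if a.cluster_id}),
            "flank_profile": [
                {k: row[k] for k in ("flank", "precursor_fraction",
                                     "null_fraction")}
                for row in profile
            ],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if "express" not in enabled:
        return _finalize(report, config, outdir)

    # ---- express
    stage = "express"
    try:
        matures = [m for c in accepted for m in c.matures()]
        per_sample_counts: dict[str, dict[str, int]] = {}
        tag_lookup = tags
        for c in accepted:
            for arm, prof in c.arm_profiles.items():
                mid = f"{c.precursor_id}-{arm}"
                counts: dict[str, int] = {s: 0 for s in samples.sample_ids}
                # sum per-sample counts of tags aligned to this arm
                s_arm, e_arm = prof.modal_interval
                for a in excl.retained:
                    if a.scaffold_id != c.scaffold_id or a.strand != c.strand:
                        continue
                    gs, ge = c.interval
                    if a.start >= gs and a.end <= ge:
                        ls = a.start - gs if c.strand == "+" else ge - a.end
                        le = ls + (a.end - a.start)
                        mid_local = (ls + le) / 2
                        if s_arm - 4 <= mid_local <= e_arm + 4:
                            for sid, n in a.tag.per_sample_counts.items():
                                counts[sid] = counts.get(sid, 0) + n
                per_sample_counts[mid] = counts
        raw = pd.DataFrame(per_sample_counts).T.fillna(0).astype(int)
        raw = raw[samples.sample_ids] if len(raw) else raw
        lib_sizes = {}
        for sid in samples.sample_ids:
            lib_sizes[sid] = max(1, sum(
                tags[s].per_sample_counts.get(sid, 0) for s in mapped_tags))
        matrix = expr.compute_rpm(raw, lib_sizes) if len(raw) else None
        result: dict = {"n_matures": len(matures)}
        if matrix is not None and len(raw):
            expressed = [m.mature_id for m in matures if m.in_expression_set
                         and m.mature_id in raw.index]
            ranks = {}
            novel = expr.novel_rank_for(truth.catalog) if truth.catalog else 1
            for m in matures:
                if m.mature_id not in raw.index:
                    continue
                ranks[m.mature_id] = (
                    expr.assign_phylostratum(m.sequence, truth.catalog, novel)
                    if truth.catalog and len(m.sequence) >= 8 else novel
                )
                m.phylostratum = ranks[m.mature_id]
            stages_dev = [s.sample_id for s in samples.development_samples()]
            sub = raw.loc[expressed] if expressed else raw
            sub_ranks = {k: ranks[k] for k in sub.index}
            profile = expr.mirpai(sub, sub_ranks, stages_dev)
            cv = {}
            for mid2 in expressed:
                v = matrix.rpm.loc[mid2]
                if v.mean() > 0:
                    cv[mid2] = expr.coefficient_of_variation(v.to_numpy())
            spec_calls = expr.specificity_screen(matrix.rpm, samples)
            result.update(
                {
                    "n_expression_set": len(expressed),
                    "mirpai": profile.values,
                    "mirpai_argmax": profile.argmax_stage(),
                    "mean_cv": (sum(cv.values()) / len(cv)) if cv else None,
                    "specific_high": int(spec_calls["high_in"].notna().sum()),
                    "specific_low": int(spec_calls["low_in"].notna().sum()),
                }
            )
            matrix.rpm.round(3).to_csv(outdir / "rpm.tsv", sep="\t")
            raw.to_csv(outdir / "counts.tsv", sep="\t")
        report["stages"][stage] = result
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    return _finalize(report, config, outdir)


def _finalize(report: dict, config: RunConfig, outdir: Path) -> dict:
    report["config"] = {
        "seed": config.seed,
        "synthetic": asdict(config.synthetic),
        "noise": asdict(config.noise),
        "window_length": config.window_length,
        "flanks": list(config.flanks),
        "max_gap": config.max_gap,
        "stages": list(config.stages),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def match_to_truth(
    candidates: list[disc.CandidatePrecursor], truth: syn.SyntheticTruth
) -> dict[str, dict]:
    """Match evaluated candidates to planted precursors by locus overlap;
    returns {precursor_id: {detected, accepted, failed}} per plant."""
    out: dict[str, dict] = {}
    for plant in truth.plants:
        loci = [(plant.scaffold_id, plant.start, plant.end)] + plant.extra_loci
        hits = []
        for c in candidates:
            cs, ce = c.interval
            for sc, s, e in loci:
                if c.scaffold_id == sc and cs < e and s < ce:
                    hits.append(c)
                    break
        best = None
        for c in hits:
            if best is None or c.total_reads > best.total_reads:
                best = c
        out[plant.precursor_id] = {
            "detected": best is not None,
            "accepted": bool(best and best.verdict.accepted),
            "failed": sorted(best.verdict.failed) if best else None,
            "n_candidates": len(hits),
        }
    return out
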