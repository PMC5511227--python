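"""Stage orchestration: simulate -> call -> targets -> stats.

Each ``run_*`` function consumes a :class:`~chlamirna.config.PipelineConfig`
plus an output directory, persists plain-text artifacts (TSV/FASTA/
FASTQ/BED/GFF3), and returns the in-memory results so the stages compose
without re-reading files.  Logging goes to stderr with per-criterion
rejection tallies, replacing manual curation with auditable reason codes.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import pandas as pd

from . import calling, seqio, stats, synthetic, targets
from .config import PipelineConfig

logger = logging.getLogger("chlamirna")


def run_simulate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Generate the planted benchmark dataset and update config paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    libraries = sorted(config.conditions) or ["TAP", "HSplusN", "HSminusN"]
    if not config.conditions:
        config.conditions = {lib: lib for lib in libraries}
    genome, truth = synthetic.benchmark_truth(
        rng_seed=config.seed,
        n_valid=config.n_valid_precursors,
        defects_per_kind=config.defects_per_kind,
        libraries=libraries,
        spacer_len=config.spacer_len,
    )
    sims = synthetic.simulate_reads(
        truth,
        genome,
        {lib: config.library_size for lib in libraries},
        predominance=config.predominance,
        offset_jitter=config.offset_jitter,
        background_fraction=config.background_fraction,
        star_fraction=config.star_fraction,
        rng_seed=config.seed,
        max_loci=config.max_loci,
    )
    seqio.write_fasta(sorted(genome.items()), outdir / "genome.fasta")
    synthetic.write_truth(truth, outdir)
    for lib, sim in sims.items():
        synthetic.write_library(sim, outdir)
        logger.info("library %s: %d reads, %d distinct", lib, sim.total_reads, len(sim.counts))
    config.genome = str(outdir / "genome.fasta")
    config.alignments = {
        lib: str(outdir / f"{lib}.alignments.tsv") for lib in libraries
    }
    return {"genome": genome, "truth": truth, "libraries": sims}


def run_call(config: PipelineConfig, outdir: str | Path) -> dict:
    """Filter, cluster, fold and call miRNAs per library; write GFF3 + TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.genome is None or not config.alignments:
        raise FileNotFoundError("run_call needs a genome and alignment tables")
    genome = dict(seqio.read_fasta(config.genome))

    exclusion = None
    if config.exclusion_bed:
        exclusion = seqio.ExclusionAnnotation(
            intervals=[
                (chrom, start, end)
                for chrom, start, end, *_ in seqio.read_bed(config.exclusion_bed)
            ]
        )

    calls_by_library: dict[str, list[calling.MirnaCandidate]] = {}
    abundances: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for lib, path in sorted(config.alignments.items()):
        reads = seqio.read_alignment_table(path)
        if exclusion is not None:
            reads = seqio.filter_excluded(reads, exclusion)
        abundances[lib] = {r.seq: r.abundance for r in reads}
        totals[lib] = sum(r.abundance for r in reads)
        if not reads:
            logger.warning("library %s: no aligned reads; nothing to call", lib)
            calls_by_library[lib] = []
            continue
        calls, clusters = calling.call_library(
            reads,
            genome,
            max_gap=config.max_gap,
            flank=config.flank,
            backend=config.fold_backend,
            predominance_min=config.predominance_min,
            max_5p_sites=config.max_5p_sites,
            max_star_mismatches=config.max_star_mismatches,
            min_site_fraction=config.min_site_fraction,
            min_stem_pairs=config.min_stem_pairs,
        )
        calls_by_library[lib] = calls
        tally = Counter(
            reason.value for c in calls for reason in c.rejection_reasons
        )
        logger.info(
            "library %s: %d clusters, %d accepted, rejections %s",
            lib,
            len(clusters),
            sum(c.accepted for c in calls),
            dict(tally),
        )

    # one row per (library, candidate); accepted loci unified across libraries
    rows = []
    for lib, calls in calls_by_library.items():
        for c in calls:
            rows.append(
                {
                    "library": lib,
                    "candidate": c.id,
                    "cluster": c.cluster_id,
                    "status": c.status,
                    "reasons": ",".join(r.value for r in c.rejection_reasons) or ".",
                    "mature_seq": c.mature_seq or ".",
                    "chrom": c.mature_locus[0] if c.mature_locus else ".",
                    "start": c.mature_locus[1] if c.mature_locus else -1,
                    "end": c.mature_locus[2] if c.mature_locus else -1,
                    "strand": c.mature_locus[3] if c.mature_locus else ".",
                    "arm": c.arm or ".",
                    "predominance": c.predominance,
                    "n_5p_sites": c.n_predominant_5p_sites,
                    "star_mismatches": c.star_mismatches,
                }
            )
    calls_df = pd.DataFrame(rows)
    seqio.write_tsv(calls_df, outdir / "mirna_calls.tsv")

    accepted: dict[tuple, calling.MirnaCandidate] = {}
    for calls in calls_by_library.values():
        for c in calls:
            if c.accepted and c.mature_locus not in accepted:
                accepted[c.mature_locus] = c
    accepted_list = [
        accepted[k] for k in sorted(accepted, key=lambda loc: (loc[0], loc[1]))
    ]
    for i, c in enumerate(accepted_list):
        c.id = f"mir_s{i + 1:03d}"
    seqio.write_gff3(
        [
            (
                c.mature_locus[0],
                c.mature_locus[1],
                c.mature_locus[2],
                c.id,
                c.mature_locus[3],
                "miRNA",
                {"arm": c.arm},
            )
            for c in accepted_list
        ],
        outdir / "mirnas.gff3",
    )
    seqio.write_tsv(
        pd.DataFrame(
            [
                {
                    "mirna_id": c.id,
                    "mature_seq": c.mature_seq,
                    "chrom": c.mature_locus[0],
                    "start": c.mature_locus[1],
                    "end": c.mature_locus[2],
                    "strand": c.mature_locus[3],
                    "arm": c.arm,
                }
                for c in accepted_list
            ],
            columns=["mirna_id", "mature_seq", "chrom", "start", "end", "strand", "arm"],
        ),
        outdir / "accepted_mirnas.tsv",
    )

    condition_sets = None
    if config.conditions:
        condition_sets = calling.assign_condition_sets(
            calls_by_library, config.conditions
        )
        venn_rows = [["conditions", "n_mirnas"]]
        for region, count in sorted(
            condition_sets.venn_counts().items(), key=lambda kv: sorted(kv[0])
        ):
            venn_rows.append(["+".join(sorted(region)), count])
        seqio.write_tsv(venn_rows, outdir / "condition_venn.tsv")

    expression = calling.expression_records(
        accepted_list, abundances, totals, cpm_cutoff=config.cpm_cutoff
    )
    seqio.write_tsv(expression, outdir / "expression.tsv")
    return {
        "calls_by_library": calls_by_library,
        "accepted": accepted_list,
        "condition_sets": condition_sets,
        "expression": expression,
        "abundances": abundances,
        "totals": totals,
    }


def run_targets(
    config: PipelineConfig,
    outdir: str | Path,
    mirnas: list[tuple[str, str]] | None = None,
) -> dict:
    """Scan a transcriptome (planted unless provided) for target sites."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mirnas is None:
        accepted_path = outdir / "accepted_mirnas.tsv"
        if not accepted_path.exists():
            raise FileNotFoundError("run_targets needs miRNAs (run call first)")
        df = pd.read_csv(accepted_path, sep="\t")
        mirnas = list(zip(df["mirna_id"], df["mature_seq"]))
    if not mirnas:
        logger.warning("no miRNAs to scan; writing empty tables")
        seqio.write_tsv(targets.sites_table([]), outdir / "target_sites.tsv")
        seqio.write_tsv(targets.target_count_table([]), outdir / "target_counts.tsv")
        return {"sites": [], "counts": targets.target_count_table([])}

    if config.transcriptome:
        transcripts = [
            (tid, seqio.to_rna(seq))
            for tid, seq in seqio.read_fasta(config.transcriptome)
        ]
        planted = []
    else:
        # per-miRNA target counts depend on the expression class when
        # known, emulating the inverse expression/target-count relation
        import numpy as np

        classes: dict[str, str] = {}
        expr_path = outdir / "expression.tsv"
        if expr_path.exists():
            expr = pd.read_csv(expr_path, sep="\t")
            classes = dict(zip(expr["mirna_id"], expr["expression_class"]))
        rng = np.random.default_rng(config.seed + 101)
        n_cleavage, n_translational = {}, {}
        for mirna_id, _seq in mirnas:
            cls = classes.get(mirna_id, "low")
            mean, disp = (5.11, 0.35) if cls == "low" else (1.78, 0.7)
            n_cleavage[mirna_id] = int(
                min(12, synthetic.shifted_nb_counts(rng, 1, mean, disp)[0])
            )
            n_translational[mirna_id] = int(
                min(12, synthetic.shifted_nb_counts(rng, 1, mean, disp)[0])
            )
        seed = config.seed + 1000
        cleav, planted_c = synthetic.plant_targets(
            mirnas, n_cleavage, "cleavage", rng_seed=seed
        )
        trans, planted_t = synthetic.plant_targets(
            mirnas, n_translational, "translational", rng_seed=seed + 1
        )
        decoy, _ = synthetic.plant_targets(mirnas, 1, "decoy", rng_seed=seed + 2)
        transcripts = cleav + trans + decoy
        planted = planted_c + planted_t
        seqio.write_fasta(
            [(tid, seqio.to_dna(seq)) for tid, seq in transcripts],
            outdir / "transcriptome.fasta",
        )

    sites = targets.scan_transcriptome(mirnas, transcripts)
    counts = targets.target_count_table(sites)
    seqio.write_tsv(targets.sites_table(sites), outdir / "target_sites.tsv")
    seqio.write_tsv(counts, outdir / "target_counts.tsv")
    logger.info("found %d sites over %d miRNAs", len(sites), len(mirnas))
    return {"sites": sites, "counts": counts, "planted": planted}


def run_stats(config: PipelineConfig, outdir: str | Path) -> dict:
    """Expression histogram, the low/high target comparison, optional DE."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t")
    counts = pd.read_csv(outdir / "target_counts.tsv", sep="\t")

    histogram = stats.bin_expression_histogram(
        expression["mean_cpm"].to_numpy(), bin_width=config.cpm_cutoff
    )
    seqio.write_tsv(
        [["bin_start", "bin_end", "n_mirnas"]]
        + [
            [i * config.cpm_cutoff, (i + 1) * config.cpm_cutoff, int(n)]
            for i, n in enumerate(histogram)
        ],
        outdir / "expression_histogram.tsv",
    )

    comparisons = {}
    frames = []
    for site_class in ("cleavage", "translational"):
        try:
            comparison = stats.compare_expression_vs_targets(
                expression, counts, site_class, cpm_cutoff=config.cpm_cutoff
            )
        except ValueError as exc:
            logger.warning("comparison for %s skipped: %s", site_class, exc)
            continue
        comparisons[site_class] = comparison
        frames.append(comparison.to_frame())
    if frames:
        seqio.write_tsv(pd.concat(frames, ignore_index=True), outdir / "comparison.tsv")

    de = None
    if config.gene_counts:
        genes = pd.read_csv(config.gene_counts, sep="\t")
        n1, n2 = genes["count_a"].sum(), genes["count_b"].sum()
        rpkm_a = [
            stats.compute_rpkm(c, n1, L) for c, L in zip(genes["count_a"], genes["length"])
        ]
        rpkm_b = [
            stats.compute_rpkm(c, n2, L) for c, L in zip(genes["count_b"], genes["length"])
        ]
        if "p" in genes.columns:
            pvalues = genes["p"].tolist()
        else:
            pvalues = [
                stats.count_test(int(ca), int(n1), int(cb), int(n2))
                for ca, cb in zip(genes["count_a"], genes["count_b"])
            ]
        de = stats.de_flag(
            rpkm_a,
            rpkm_b,
            pvalues,
            gene_ids=genes["gene"].tolist(),
            q_max=config.de_q,
            min_fold=config.de_fold,
        )
        seqio.write_tsv(de, outdir / "differential_expression.tsv")

    return {"histogram": histogram, "comparisons": comparisons, "de": de}


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    simulated = run_simulate(config, outdir)
    called = run_call(config, outdir)
    targeted = run_targets(config, outdir)
    statistics = run_stats(config, outdir)
    return {
        "simulate": simulated,
        "call": called,
        "targets": targeted,
        "stats": statistics,
    }
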