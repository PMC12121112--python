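"""End-to-end orchestration: classify -> cap calling -> tail/APA calling ->
quantification, with a reproducible manifest.

Stages are plain functions over files so they can be run individually (the
CLI exposes each) or chained by :func:`run_pipeline`.  Alignment is taken
from a SAM/BAM of the classified reads; for simulated data this is the truth
SAM emitted by :mod:`c2t.sim`, for real data the output of an external
spliced aligner run on the per-class FASTQ files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import capcall, quant, readclass, tailcall
from .capcall import CapSupportPolicy, ParacluParams
from .readclass import ProtocolProfile
from .tailcall import PeakCallerParams, TailParams


@dataclass
class RunConfig:
    """Validated configuration of a full run.

    Either ``sim`` is set (a synthetic experiment is generated under
    ``out_dir/sim`` and used as input) or the input paths must point to an
    existing experiment (paired FASTQ, sample sheet, alignment SAM, genome
    FASTA and GTF)."""

    out_dir: str = "c2t_run"
    seed: int = 42
    # inputs (filled automatically after a simulate stage)
    r1: Optional[str] = None
    r2: Optional[str] = None
    sample_sheet: Optional[str] = None
    alignment_sam: Optional[str] = None
    genome_fasta: Optional[str] = None
    gtf: Optional[str] = None
    apa_reference_bed: Optional[str] = None
    translatome_tsv: Optional[str] = None
    # stage parameters
    sim: Optional["object"] = None              # c2t.sim.SimConfig
    profile: ProtocolProfile = field(default_factory=ProtocolProfile.scm6a_c2t)
    dedup: bool = True
    dedup_k: int = 30
    cap_policy: CapSupportPolicy = CapSupportPolicy.DROP_4G_ONLY
    paraclu: ParacluParams = field(default_factory=ParacluParams)
    min_match: int = 10
    peaks: PeakCallerParams = field(default_factory=PeakCallerParams)
    tail: TailParams = field(default_factory=TailParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        from .sim import SimConfig

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        nested = {"sim": SimConfig, "profile": ProtocolProfile,
                  "paraclu": ParacluParams, "peaks": PeakCallerParams,
                  "tail": TailParams}
        for key, klass in nested.items():
            if key in data and isinstance(data[key], dict):
                block = data[key]
                block_known = {f.name for f in dataclasses.fields(klass)}
                bad = set(block) - block_known
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                data[key] = klass(**block)
        if "cap_policy" in data:
            data["cap_policy"] = CapSupportPolicy(data["cap_policy"])
        return cls(**data)

    def validate(self) -> None:
        if self.sim is None:
            required = ("r1", "r2", "alignment_sam", "genome_fasta", "gtf")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ValueError(f"missing inputs (and no sim block): {missing}")
            for k in required:
                if not Path(getattr(self, k)).exists():
                    raise FileNotFoundError(getattr(self, k))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _load_genome(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_classify(r1: str | Path, r2: str | Path, out_dir: str | Path,
                   profile: ProtocolProfile,
                   sample_sheet: Optional[str | Path] = None,
                   dedup: bool = True, dedup_k: int = 30) -> dict:
    adaptors = readclass.read_sample_sheet(sample_sheet) if sample_sheet else None
    pairs = readclass.read_paired_fastq(r1, r2, adaptors)
    classified = readclass.classify_stream(pairs, profile, dedup=dedup,
                                           dedup_k=dedup_k)
    counts = readclass.write_classified(classified, out_dir)
    return {"label_counts": counts, "n_pairs": sum(counts.values())}


def stage_capcall(alignment_sam: str | Path, class_log: str | Path,
                  genome_fasta: str | Path, out_dir: str | Path,
                  policy: CapSupportPolicy = CapSupportPolicy.DROP_4G_ONLY,
                  paraclu_params: Optional[ParacluParams] = None,
                  min_match: int = 10) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_map = readclass.read_class_log(class_log)
    cap_reads = list(capcall.read_alignments(
        alignment_sam, class_map, subsets={"cap3G", "cap4G"}))
    sites = capcall.pile_cap_sites(cap_reads, min_match)
    kept = capcall.filter_cap_sites(sites, policy)
    clusters = capcall.cluster_cap_sites(kept, paraclu_params)
    genome = _load_genome(genome_fasta)
    capcall.annotate_first_base(clusters, genome)
    capcall.write_sites_bed(sites, out_dir / "cap_sites.bed")
    capcall.write_clusters_tsv(clusters, out_dir / "cap_clusters.tsv")
    return {"n_cap_reads": len(cap_reads), "n_sites": len(sites),
            "n_sites_kept": len(kept), "n_clusters": len(clusters)}


def stage_tailcall(alignment_sam: str | Path, class_log: str | Path,
                   tail_r2_fastq: str | Path, genome_fasta: str | Path,
                   out_dir: str | Path,
                   peak_params: Optional[PeakCallerParams] = None,
                   tail_params: Optional[TailParams] = None,
                   sample_sheet: Optional[str | Path] = None,
                   gtf: Optional[str | Path] = None,
                   apa_reference_bed: Optional[str | Path] = None) -> dict:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_map = readclass.read_class_log(class_log)
    r2_lookup: dict[str, tuple[str, str]] = {}
    if Path(tail_r2_fastq).exists():
        with open(tail_r2_fastq) as fh:
            for rid, seq, qual in FastqGeneralIterator(fh):
                r2_lookup[rid.split()[0]] = (seq.upper(), qual)
    adaptor_lens = None
    if sample_sheet:
        adaptor_lens = {cell: len(adaptor) for adaptor, cell
                        in readclass.read_sample_sheet(sample_sheet).items()}
    alignments = capcall.read_alignments(alignment_sam, class_map,
                                         subsets={"tail"})
    tail_reads = tailcall.collect_tail_reads(
        alignments, class_map, r2_lookup, adaptor_lens, tail_params)
    genome = _load_genome(genome_fasta)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    peaks = tailcall.call_apa_peaks(tail_reads, chrom_lengths, peak_params)
    if gtf:
        index = quant.GeneIndex(quant.read_gene_models(gtf))
        for r in tail_reads:
            r.gene_id = index.assign(r.chrom, r.strand, r.anchor_pos - 1,
                                     r.anchor_pos)
    known = {}
    if apa_reference_bed:
        known = tailcall.match_reference_apa(
            peaks, tailcall.load_apa_bed(apa_reference_bed))
    tailcall.write_peaks(peaks, out_dir / "apa_peaks.tsv")
    tailcall.write_tail_table(tail_reads, out_dir / "tail_reads.tsv")
    per_peak, per_gene = tailcall.summarize_tail_lengths(tail_reads)
    per_peak.to_csv(out_dir / "tail_length_by_peak.tsv", sep="\t",
                    float_format="%.6g")
    per_gene.to_csv(out_dir / "tail_length_by_gene.tsv", sep="\t",
                    float_format="%.6g")
    if known:
        with open(out_dir / "apa_reference_match.tsv", "w") as fh:
            fh.write("peak_id\tknown\n")
            for pid in sorted(known):
                fh.write(f"{pid}\t{int(known[pid])}\n")
    return {"n_tail_reads": len(tail_reads), "n_peaks": len(peaks),
            "n_known_peaks": sum(known.values()) if known else None}


def stage_quant(alignment_sam: str | Path, class_log: str | Path,
                gtf: str | Path, out_dir: str | Path,
                cluster_tsv: Optional[str | Path] = None,
                tail_table: Optional[str | Path] = None,
                translatome_tsv: Optional[str | Path] = None,
                min_match: int = 10) -> dict:
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_map = readclass.read_class_log(class_log)
    genes = quant.read_gene_models(gtf)
    index = quant.GeneIndex(genes)
    gene_ids = [g.gene_id for g in genes]
    cells = sorted({rec["cell_id"] for rec in class_map.values()})

    # cap-cluster membership for the cap/genebody split
    in_cluster: set[tuple[str, str, int]] = set()
    if cluster_tsv and Path(cluster_tsv).exists():
        df = pd.read_csv(cluster_tsv, sep="\t")
        for row in df.itertuples():
            for pos in range(int(row.start), int(row.end) + 1):
                in_cluster.add((row.chrom, row.strand, pos))

    cap_records, body_records = [], []
    for read in capcall.read_alignments(alignment_sam, class_map,
                                        subsets={"cap3G", "cap4G"}):
        gene = quant.assign_gene(read, index)
        if gene is None:
            continue
        cell = class_map[read.read_id]["cell_id"]
        ok, _ = capcall.is_cap_alignment(read, min_match)
        site = capcall.cap_site_position(read)
        if ok and (not in_cluster or (read.chrom, read.strand, site) in in_cluster):
            cap_records.append((gene, cell))
        else:
            body_records.append((gene, cell))

    tail_records = []
    if tail_table and Path(tail_table).exists():
        tdf = pd.read_csv(tail_table, sep="\t")
        for row in tdf.itertuples():
            if isinstance(row.gene_id, str) and row.gene_id:
                tail_records.append((row.gene_id, row.cell_id))

    matrices = {
        "cap": quant.build_matrix(cap_records, "cap", gene_ids, cells),
        "genebody": quant.build_matrix(body_records, "genebody", gene_ids, cells),
        "tail": quant.build_matrix(tail_records, "tail", gene_ids, cells),
    }
    for m in matrices.values():
        quant.write_matrix(m, out_dir)
    cap_bulk = quant.pseudobulk(matrices["cap"]).counts["bulk"]
    body_bulk = quant.pseudobulk(matrices["genebody"]).counts["bulk"]
    cap_cpm = cap_bulk * 1e6 / max(cap_bulk.sum(), 1)
    body_cpm = body_bulk * 1e6 / max(body_bulk.sum(), 1)
    translation = (quant.read_translatome(translatome_tsv)
                   if translatome_tsv else None)
    scores = quant.gene_scores(cap_cpm, body_cpm, translation)
    quant.write_gene_scores(scores, out_dir / "gene_scores.tsv")
    return {"n_cells": len(cells),
            "counts": {k: m.total for k, m in matrices.items()}}


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> classify -> capcall -> tailcall ->
    quant and write a manifest.  Fails before any stage on invalid input;
    a stage failure leaves the manifest recording the completed stages."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "parameters": _params_dict(config), "stages": {}}
    manifest_path = out / "manifest.json"
    try:
        if config.sim is not None:
            from . import sim as simmod

            sim_config = config.sim
            sim_dir = out / "sim"
            info = simmod.simulate_experiment(sim_config, sim_dir)
            manifest["stages"]["simulate"] = info
            config.r1 = str(sim_dir / "reads.R1.fastq")
            config.r2 = str(sim_dir / "reads.R2.fastq")
            config.sample_sheet = str(sim_dir / "sample_sheet.tsv")
            config.alignment_sam = str(sim_dir / "truth.sam")
            config.genome_fasta = str(sim_dir / "genome.fa")
            config.gtf = str(sim_dir / "genes.gtf")
            config.apa_reference_bed = str(sim_dir / "known_apa.bed")
        manifest["inputs"] = {k: {"path": getattr(config, k),
                                  "sha256": _sha256(getattr(config, k))}
                              for k in ("r1", "r2", "alignment_sam",
                                        "genome_fasta", "gtf")
                              if getattr(config, k)}
        cls_dir = out / "classify"
        manifest["stages"]["classify"] = stage_classify(
            config.r1, config.r2, cls_dir, config.profile,
            config.sample_sheet, config.dedup, config.dedup_k)
        class_log = cls_dir / "reads.classes.tsv"
        manifest["stages"]["capcall"] = stage_capcall(
            config.alignment_sam, class_log, config.genome_fasta,
            out / "capcall", config.cap_policy, config.paraclu,
            config.min_match)
        manifest["stages"]["tailcall"] = stage_tailcall(
            config.alignment_sam, class_log, cls_dir / "reads.tail.R2.fastq",
            config.genome_fasta, out / "tailcall", config.peaks, config.tail,
            config.sample_sheet, config.gtf, config.apa_reference_bed)
        manifest["stages"]["quant"] = stage_quant(
            config.alignment_sam, class_log, config.gtf, out / "quant",
            out / "capcall" / "cap_clusters.tsv",
            out / "tailcall" / "tail_reads.tsv", config.translatome_tsv,
            config.min_match)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_ip_analysis(sim_config, out_dir: str | Path,
                    fold: Optional[float] = None,
                    policy: CapSupportPolicy = CapSupportPolicy.DROP_4G_ONLY,
                    paraclu_params: Optional[ParacluParams] = None,
                    cutoff: float = 0.5) -> dict:
    """Simulate an anti-m6A IP experiment and call m6Am end to end.

    Generates input / IP / supernatant libraries, classifies each, merges the
    cap reads of all three fractions for cap-peak identification, then calls
    m6Am per cluster from the IP-vs-input m7GpppA levels.  Returns the calls
    together with per-gene truth for evaluation."""
    from . import sim as simmod

    out_dir = Path(out_dir)
    simmod.simulate_ip_experiment(sim_config, out_dir, fold=fold)
    cap_reads_by_fraction: dict[str, list] = {}
    lib_sizes: dict[str, int] = {}
    for fraction in ("input", "IP", "supernatant"):
        d = out_dir / fraction
        stage_classify(d / "reads.R1.fastq", d / "reads.R2.fastq",
                       d / "classify", ProtocolProfile.scm6a_c2t(),
                       d / "sample_sheet.tsv")
        class_map = readclass.read_class_log(
            d / "classify" / "reads.classes.tsv")
        reads = list(capcall.read_alignments(d / "truth.sam", class_map))
        lib_sizes[fraction] = len(reads)
        cap_reads_by_fraction[fraction] = [
            r for r in reads if r.subset in ("cap3G", "cap4G")]
    merged = [r for frac in ("input", "IP", "supernatant")
              for r in cap_reads_by_fraction[frac]]
    sites = capcall.filter_cap_sites(capcall.pile_cap_sites(merged), policy)
    clusters = capcall.cluster_cap_sites(sites, paraclu_params)
    genome = _load_genome(out_dir / "input" / "genome.fa")
    capcall.annotate_first_base(clusters, genome)
    counts = capcall.m7gpppa_counts(merged, clusters, genome)
    calls = capcall.call_m6am(clusters, counts, lib_sizes, cutoff)
    capcall.write_m6am_tsv(calls, out_dir / "m6am_calls.tsv")
    return {"calls": calls, "clusters": clusters,
            "library_sizes": lib_sizes,
            "truth_genes": out_dir / "input" / "truth_genes.tsv"}


def evaluate_m6am(calls, truth_genes_tsv: str | Path,
                  window: int = 5) -> dict:
    """Match m6Am calls to truth genes by cluster position vs true TSS and
    compute precision/recall over the truth m6Am gene set.

    When maximal-density clustering splits one 5' end into a dominant
    cluster and a low-count splinter, only the dominant (highest-count)
    cluster carries the gene's call: sub-clusters of the same cap peak are
    not independent evidence."""
    import pandas as pd

    truth = pd.read_csv(truth_genes_tsv, sep="\t")
    per_gene: dict[str, tuple[int, bool]] = {}
    for c in calls:
        chrom, strand = c.cluster.chrom, c.cluster.strand
        pos = c.cluster.mode_site.pos
        match = truth[(truth.chrom == chrom) & (truth.strand == strand)
                      & ((truth.tss - pos).abs() <= window)]
        for gid in match.gene_id:
            best = per_gene.get(gid)
            if best is None or c.cluster.total_count > best[0]:
                per_gene[gid] = (c.cluster.total_count, c.is_m6am)
    candidate_genes = set(per_gene)
    m6am_genes = {g for g, (_, flag) in per_gene.items() if flag}
    true_set = set(truth.loc[truth.m6am == 1, "gene_id"])
    tp = len(m6am_genes & true_set)
    fp = len(m6am_genes - true_set)
    fn = len(true_set - m6am_genes)
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    call_rate = len(m6am_genes) / max(len(candidate_genes), 1)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision,
            "recall": recall, "n_called": len(m6am_genes),
            "n_candidates": len(candidate_genes), "call_rate": call_rate}


def _params_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [convert(x) for x in obj]
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if hasattr(obj, "value"):
            return obj.value
        return obj

    return {f.name: convert(getattr(config, f.name))
            for f in dataclasses.fields(config)
            if f.name not in ("r1", "r2")}
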