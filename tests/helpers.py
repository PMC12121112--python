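"""Shared test utilities: running the classifier on a simulated experiment
and joining tail measurements against ground truth."""

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from c2t import capcall, readclass, tailcall
from c2t.pipeline import stage_classify
from c2t.readclass import ProtocolProfile
from c2t.sim import SimConfig, simulate_experiment


def classify_experiment(out_dir: Path, dedup: bool = True) -> dict:
    """Run the read classifier on a simulated experiment directory."""
    stage_classify(out_dir / "reads.R1.fastq", out_dir / "reads.R2.fastq",
                   out_dir / "classify", ProtocolProfile.scm6a_c2t(),
                   out_dir / "sample_sheet.tsv", dedup=dedup)
    return readclass.read_class_log(out_dir / "classify" / "reads.classes.tsv")


def load_tail_r2(out_dir: Path) -> dict:
    path = out_dir / "classify" / "reads.tail.R2.fastq"
    lookup = {}
    if path.exists():
        with open(path) as fh:
            for rid, seq, qual in FastqGeneralIterator(fh):
                lookup[rid.split()[0]] = (seq.upper(), qual)
    return lookup


def collect_tails(out_dir: Path, class_map: dict) -> list:
    """Tail reads joined from truth alignments and classified R2 mates,
    using the true per-cell adaptor lengths from the sample sheet."""
    adaptor_lens = {cell: len(adaptor) for adaptor, cell in
                    readclass.read_sample_sheet(out_dir / "sample_sheet.tsv").items()}
    alignments = capcall.read_alignments(out_dir / "truth.sam", class_map,
                                         subsets={"tail"})
    return tailcall.collect_tail_reads(alignments, class_map,
                                       load_tail_r2(out_dir), adaptor_lens)


def chrom_lengths(out_dir: Path) -> dict:
    return {rec.id: len(rec.seq)
            for rec in SeqIO.parse(str(out_dir / "genome.fa"), "fasta")}


def simulate_and_classify(config: SimConfig, out_dir: Path,
                          dedup: bool = True) -> dict:
    simulate_experiment(config, out_dir)
    return classify_experiment(out_dir, dedup=dedup)


def truth_reads(out_dir: Path) -> pd.DataFrame:
    return pd.read_csv(out_dir / "truth_reads.tsv", sep="\t")


def truth_genes(out_dir: Path) -> pd.DataFrame:
    return pd.read_csv(out_dir / "truth_genes.tsv", sep="\t")
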