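"""Multi-layer gene expression: cap, gene-body, tail, and m6Am count
matrices, plus cap-level and translation-efficiency scores.

The same library yields several independent quantifications of each gene:
reads whose 5' end carries the cap signature and falls in a called cap peak
(cap), aligned reads without that signature (gene body), tail reads assigned
via their poly(A) anchor (tail), and m7GpppA reads in called m6Am clusters
(m6am).  Each feature class is kept as its own genes x cells integer matrix
and normalised to counts per million within the class.  Per-gene scores:

* cap level = log2[(CPM_cap + 1) / (CPM_genebody + 1)]
* translation efficiency = log2[(CPM_translation + 1) / (CPM_genebody + 1)]
  (requires external translatome counts)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("cap", "genebody", "tail", "m6am")


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """1-based transcription start site."""
        return self.start + 1 if self.strand == "+" else self.end

    @property
    def three_prime_end(self) -> int:
        """1-based annotated 3' end."""
        return self.end if self.strand == "+" else self.start + 1


def read_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Load gene models (exon unions) from a GTF file."""
    import gffutils

    db = gffutils.create_db(str(gtf_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="merge",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, GeneModel] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        name = exon.attributes.get("gene_name", [gid])[0]
        model = genes.get(gid)
        if model is None:
            model = genes[gid] = GeneModel(gid, name, exon.seqid, exon.strand, [])
        model.exons.append((exon.start - 1, exon.end))
    for model in genes.values():
        model.exons.sort()
    return sorted(genes.values(), key=lambda g: g.gene_id)


class GeneIndex:
    """Strand-aware interval index for maximal-exon-overlap assignment."""

    def __init__(self, genes: Sequence[GeneModel]):
        from intervaltree import IntervalTree

        self.genes = list(genes)
        self._trees: dict[tuple[str, str], "IntervalTree"] = {}
        for g in self.genes:
            tree = self._trees.setdefault((g.chrom, g.strand), IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e, g.gene_id)

    def assign(self, chrom: str, strand: str, start: int, end: int
               ) -> Optional[str]:
        """Gene with the largest exonic overlap of [start, end) on the same
        strand; ties broken by longest overlap then lexicographic gene_id;
        no overlap returns None."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None
        overlap: dict[str, int] = {}
        for iv in tree.overlap(start, end):
            ov = min(end, iv.end) - max(start, iv.begin)
            if ov > 0:
                overlap[iv.data] = overlap.get(iv.data, 0) + ov
        if not overlap:
            return None
        return min(overlap.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def assign_gene(read, index: GeneIndex) -> Optional[str]:
    """Assign an :class:`c2t.capcall.AlignedRead` to a gene by maximal
    exon overlap on its strand."""
    return index.assign(read.chrom, read.strand, read.pos,
                        read.pos + read.ref_span)


@dataclass
class FeatureCountMatrix:
    """Integer genes x cells counts for one feature class."""

    feature_class: str
    counts: pd.DataFrame  # index: gene_id, columns: cell_id

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_matrix(records: Iterable[tuple[str, str]], feature_class: str,
                 genes: Sequence[str], cells: Sequence[str]
                 ) -> FeatureCountMatrix:
    """Count (gene_id, cell_id) assignment records into a dense matrix.

    Records with genes or cells outside the provided indices are dropped.
    Every counted read contributes to exactly one feature-class matrix; the
    caller is responsible for the disjoint partition of reads into classes."""
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(cells)}
    mat = np.zeros((len(genes), len(cells)), dtype=np.int64)
    for gene, cell in records:
        i, j = gi.get(gene), ci.get(cell)
        if i is not None and j is not None:
            mat[i, j] += 1
    return FeatureCountMatrix(
        feature_class,
        pd.DataFrame(mat, index=list(genes), columns=list(cells)))


def cpm(matrix: FeatureCountMatrix,
        library_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million within the feature class.

    By default each cell is normalised by its own column sum; zero-size cells
    are excluded with a warning.  Pass ``library_sizes`` for a global
    (cross-class) denominator."""
    import warnings

    sizes = matrix.library_sizes if library_sizes is None else library_sizes
    nonzero = sizes[sizes > 0].index
    dropped = [c for c in matrix.counts.columns if c not in set(nonzero)]
    if dropped:
        warnings.warn(f"excluding zero-library cells: {dropped}")
    sub = matrix.counts[nonzero]
    return sub * 1e6 / sizes[nonzero]


def pseudobulk(matrix: FeatureCountMatrix,
               groups: Optional[Mapping[str, str]] = None) -> FeatureCountMatrix:
    """Sum counts across cells (optionally within groups, e.g. stages)."""
    if groups is None:
        summed = matrix.counts.sum(axis=1).to_frame("bulk")
    else:
        summed = matrix.counts.T.groupby(
            matrix.counts.columns.map(groups)).sum().T
    return FeatureCountMatrix(matrix.feature_class, summed)


@dataclass
class GeneScore:
    gene_id: str
    cap_level: float
    te: Optional[float] = None


def gene_scores(cap_cpm: pd.Series, noncap_cpm: pd.Series,
                translation_cpm: Optional[pd.Series] = None
                ) -> list[GeneScore]:
    """Cap-level (and optionally translation-efficiency) log-ratios per gene
    with a pseudocount of 1 on numerator and denominator."""
    genes = cap_cpm.index.union(noncap_cpm.index)
    cap = cap_cpm.reindex(genes, fill_value=0.0)
    non = noncap_cpm.reindex(genes, fill_value=0.0)
    level = np.log2(cap + 1.0) - np.log2(non + 1.0)
    te = None
    if translation_cpm is not None:
        tr = translation_cpm.reindex(genes, fill_value=0.0)
        te = np.log2(tr + 1.0) - np.log2(non + 1.0)
    return [GeneScore(g, float(level[g]), None if te is None else float(te[g]))
            for g in genes]


def write_matrix(matrix: FeatureCountMatrix, out_dir: str | Path,
                 prefix: Optional[str] = None) -> None:
    """Write a feature-class matrix as MatrixMarket plus gene/cell indices."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or matrix.feature_class
    mmwrite(str(out_dir / f"{prefix}.mtx"),
            csr_matrix(matrix.counts.to_numpy()))
    (out_dir / f"{prefix}.genes.txt").write_text(
        "".join(f"{g}\n" for g in matrix.counts.index))
    (out_dir / f"{prefix}.cells.txt").write_text(
        "".join(f"{c}\n" for c in matrix.counts.columns))


def write_gene_scores(scores: Sequence[GeneScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcap_level\tte\n")
        for s in scores:
            te = "" if s.te is None else f"{s.te:.6g}"
            fh.write(f"{s.gene_id}\t{s.cap_level:.6g}\t{te}\n")


def read_translatome(path: str | Path) -> pd.Series:
    """Translatome counts TSV (gene_id, count) as a CPM series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "count"],
                     comment="#")
    counts = df.set_index("gene_id")["count"].astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty translatome counts")
    return counts * 1e6 / total
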