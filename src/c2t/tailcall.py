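"""Poly(A) tail measurement, uridylation detection, and APA peak calling.

The tail-side mate (R2) of a tail read starts with the per-cell ligation
adaptor, optionally followed by a block of A (the complement of a 3'
uridylation tail), followed by a run of T whose length encodes the poly(A)
tail.  The tail-side R1 carries the genomic anchor: after poly(A) trimming its
alignment ends at (or upstream of) the last templated base before the tail.

Alternative-polyadenylation (APA) peaks are called from the genomic anchors
of all tail reads by symmetric extension followed by a per-base Poisson
enrichment scan against the larger of the genome-wide and local background
rates; candidate peaks shorter than a minimum width and peaks below an RPKM
threshold are removed.  Within a peak, the exact polyadenylation positions
contributed by tail-adjacent anchors form the peak's tail sites, and the
largest distance between them is the peak's APA window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import poisson


@dataclass
class TailParams:
    """Rules for reading the tail out of R2."""

    min_qual: int = 20          # 3' bases below this Phred are masked
    min_t_run: int = 5          # shorter T-runs are rejected
    max_interrupt: int = 2      # tolerated isolated non-T bases in the run
    interrupt_flank: int = 3    # required T on each side of an interruption
    min_u: int = 2              # minimum A-block length to call a U tail
    min_adjacent_a: int = 5     # trimmed-off A run marking an exact anchor


@dataclass
class TailMeasurement:
    polya_len: int
    censored: bool
    u_tail: bool
    u_len: int          # 0 unless u_tail
    t_run_start: int    # index in R2 where the T-run begins


@dataclass
class TailRead:
    read_id: str
    cell_id: str
    chrom: str
    strand: str
    anchor_pos: int         # 1-based last templated base before the tail
    polya_len: int
    censored: bool
    u_tail: bool
    u_len: int
    tail_adjacent: bool     # anchor known exact (poly(A) trimmed off R1)
    aln_start: int = 0      # 0-based half-open R1 alignment interval
    aln_end: int = 0
    apa_peak_id: Optional[str] = None
    gene_id: Optional[str] = None


@dataclass
class PeakCallerParams:
    extension: int = 100        # symmetric read extension, nt
    pvalue: float = 0.05
    min_peak_len: int = 500     # nt, shorter candidate peaks are ignored
    min_rpkm: float = 2.0
    local_bg_window: int = 10000

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue < 1.0):
            raise ValueError("pvalue must lie in (0, 1)")
        for name in ("extension", "min_peak_len", "local_bg_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class APAPeak:
    id: str
    chrom: str
    strand: str
    start: int              # 0-based half-open
    end: int
    read_count: int
    rpkm: float
    tail_sites: list[int] = field(default_factory=list)  # 1-based, multiset

    @property
    def apa_window(self) -> int:
        return apa_window(self)

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# per-read tail measurement
# ---------------------------------------------------------------------------

def usable_length(qual: str, min_qual: int = 20) -> int:
    """Read length after masking the 3'-terminal run of low-quality bases."""
    n = len(qual)
    while n > 0 and ord(qual[n - 1]) - 33 < min_qual:
        n -= 1
    return n


def detect_u_tail(seq: str, prefix_len: int,
                  min_u: int = 2) -> tuple[bool, int]:
    """Detect a uridylation block.

    In R2, 3'-terminal U on the transcript read as a block of A between the
    adaptor prefix and the poly(A) T-run.  Returns ``(True, run_length)`` when
    at least ``min_u`` consecutive A follow the prefix, else ``(False, 0)``."""
    run = 0
    for ch in seq[prefix_len:]:
        if ch != "A":
            break
        run += 1
    if run >= min_u:
        return True, run
    return False, 0


def _a_block(seq: str, prefix_len: int) -> int:
    run = 0
    for ch in seq[prefix_len:]:
        if ch != "A":
            break
        run += 1
    return run


def polya_length_from_r2(seq: str, qual: str, prefix_len: int,
                         params: Optional[TailParams] = None
                         ) -> Optional[TailMeasurement]:
    """Count the poly(A) tail as the T-run in R2 after the adaptor prefix.

    3' bases below ``min_qual`` are masked first.  Any A-block directly after
    the prefix (a candidate U tail) is skipped before counting.  Up to
    ``max_interrupt`` isolated non-T bases are tolerated inside the run when
    flanked by at least ``interrupt_flank`` T on both sides (sequencing
    errors); interruptions are excluded from the count.  The run terminates at
    the first disqualifying base; a run reaching the usable read end is
    flagged censored (the true tail may exceed the read capacity).  Runs
    shorter than ``min_t_run`` are rejected (``None``)."""
    params = params or TailParams()
    usable = usable_length(qual, params.min_qual)
    u_run = _a_block(seq[:usable], prefix_len)
    start = prefix_len + u_run
    count = 0
    interrupts = 0
    i = start
    censored = True
    flank = params.interrupt_flank
    while i < usable:
        ch = seq[i]
        if ch == "T":
            count += 1
            i += 1
            continue
        # candidate interruption: isolated, flanked by >= flank T each side
        left_ok = i - start >= flank and all(
            seq[j] == "T" for j in range(i - flank, i))
        right_ok = i + 1 + flank <= usable and all(
            seq[j] == "T" for j in range(i + 1, i + 1 + flank))
        if interrupts < params.max_interrupt and left_ok and right_ok:
            interrupts += 1
            i += 1
            continue
        censored = False
        break
    if count < params.min_t_run:
        return None
    u_tail = u_run >= params.min_u
    return TailMeasurement(polya_len=count, censored=censored,
                           u_tail=u_tail, u_len=u_run if u_tail else 0,
                           t_run_start=start)


# ---------------------------------------------------------------------------
# APA peak calling (Poisson enrichment scan)
# ---------------------------------------------------------------------------

def _coverage(starts: np.ndarray, ends: np.ndarray, ext: int,
              length: int) -> np.ndarray:
    """Per-base coverage of alignment records extended symmetrically by
    ``ext`` on both sides."""
    diff = np.zeros(length + 1, dtype=np.int64)
    lo = np.clip(starts - ext, 0, length)
    hi = np.clip(ends + ext, 0, length)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi, -1)
    return np.cumsum(diff[:-1])


def _local_rate(cov: np.ndarray, window: int) -> np.ndarray:
    """Mean coverage in a centred window (actual window size at the edges)."""
    n = len(cov)
    half = window // 2
    csum = np.concatenate([[0], np.cumsum(cov)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def call_apa_peaks(tail_reads: Sequence[TailRead],
                   chrom_lengths: Mapping[str, int],
                   params: Optional[PeakCallerParams] = None,
                   library_size: Optional[int] = None) -> list[APAPeak]:
    """Call APA peaks from tail-read anchors and assign reads to them.

    Each read's mapping record is extended by ``params.extension`` on both
    sides; bases whose extended coverage is Poisson-significant
    (p < ``params.pvalue``) against ``max(genome-wide rate, local-window
    rate)`` form candidate peaks.  Peaks
    shorter than ``min_peak_len`` are ignored, then peaks with
    RPKM <= ``min_rpkm`` are removed (RPKM = reads x 1e9 / (len x library)).
    Each read's ``apa_peak_id`` is set when its anchor falls inside a retained
    peak; tail-adjacent anchors become the peak's tail sites."""
    params = params or PeakCallerParams()
    if library_size is None:
        library_size = len(tail_reads)
    genome_len = sum(chrom_lengths.values())
    if not tail_reads or genome_len == 0:
        return []
    groups: dict[tuple[str, str], list[TailRead]] = {}
    for r in tail_reads:
        groups.setdefault((r.chrom, r.strand), []).append(r)
    # genome-wide expected per-base rate of extended coverage, per strand
    peaks: list[APAPeak] = []
    for (chrom, strand) in sorted(groups):
        members = groups[(chrom, strand)]
        length = chrom_lengths[chrom]
        starts = np.array([r.aln_start for r in members], dtype=np.int64)
        ends = np.array([max(r.aln_end, r.aln_start + 1) for r in members],
                        dtype=np.int64)
        strand_mass = sum(
            sum(max(x.aln_end - x.aln_start, 1) + 2 * params.extension
                for x in v)
            for (c, s), v in groups.items() if s == strand)
        bg_rate = strand_mass / genome_len
        cov = _coverage(starts, ends, params.extension, length)
        lam = np.maximum(bg_rate, _local_rate(cov, params.local_bg_window))
        lam = np.maximum(lam, 1e-12)
        with np.errstate(divide="ignore"):
            sig = (cov > 0) & (poisson.sf(cov - 1, lam) < params.pvalue)
        # maximal significant runs
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8), [0]])))
        for s0, e0 in zip(edges[::2], edges[1::2]):
            if e0 - s0 < params.min_peak_len:
                continue
            inside = [r for r in members if s0 <= r.anchor_pos - 1 < e0]
            count = len(inside)
            rpkm = count * 1e9 / ((e0 - s0) * library_size)
            if rpkm <= params.min_rpkm:
                continue
            pid = f"{chrom}:{s0}-{e0}:{strand}"
            peak = APAPeak(pid, chrom, strand, int(s0), int(e0), count, rpkm,
                           tail_sites=sorted(r.anchor_pos for r in inside
                                             if r.tail_adjacent))
            for r in inside:
                r.apa_peak_id = pid
            peaks.append(peak)
    return peaks


def apa_window(peak: APAPeak) -> int:
    """Largest distance between polyadenylation sites inside one peak."""
    if not peak.tail_sites:
        raise ValueError(f"peak {peak.id} has no tail sites")
    return max(peak.tail_sites) - min(peak.tail_sites)


def match_reference_apa(peaks: Sequence[APAPeak],
                        reference: Sequence[tuple[str, int, str]],
                        flank: int = 100) -> dict[str, bool]:
    """Label peaks known/novel against a reference of (chrom, pos, strand)
    polyadenylation sites: a peak is known iff any reference site lies within
    ``[site - flank, site + flank]`` of one of its tail sites."""
    by_group: dict[tuple[str, str], np.ndarray] = {}
    for chrom, pos, strand in reference:
        by_group.setdefault((chrom, strand), []).append(pos)  # type: ignore[attr-defined]
    by_group = {k: np.sort(np.asarray(v)) for k, v in by_group.items()}
    out: dict[str, bool] = {}
    for peak in peaks:
        ref = by_group.get((peak.chrom, peak.strand))
        known = False
        if ref is not None and len(ref):
            for site in peak.tail_sites:
                i = np.searchsorted(ref, site)
                for j in (i - 1, i):
                    if 0 <= j < len(ref) and abs(int(ref[j]) - site) <= flank:
                        known = True
                        break
                if known:
                    break
        out[peak.id] = known
    return out


def load_apa_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Known APA sites from BED (chrom, start, end, [name, score, strand]);
    the site position is taken as the interval end (1-based)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            sites.append((f[0], int(f[2]), strand))
    return sites


# ---------------------------------------------------------------------------
# summaries and plumbing
# ---------------------------------------------------------------------------

def summarize_tail_lengths(tail_reads: Sequence[TailRead]):
    """Per-APA-peak and per-gene poly(A) length summaries.

    Censored reads are counted but excluded from the median/mean; groups with
    only censored reads are flagged.  Gene-level summaries pool reads across
    the gene's peaks (read-weighted)."""
    import pandas as pd

    df = pd.DataFrame([{
        "read_id": r.read_id, "cell_id": r.cell_id, "peak_id": r.apa_peak_id,
        "gene_id": r.gene_id, "polya_len": r.polya_len, "censored": r.censored,
        "u_tail": r.u_tail, "u_len": r.u_len,
    } for r in tail_reads])
    if df.empty:
        empty = pd.DataFrame(columns=["n", "n_censored", "median", "mean",
                                      "censored_only"])
        return empty, empty

    def _summary(g: "pd.DataFrame") -> "pd.Series":
        usable = g.loc[~g["censored"], "polya_len"]
        return pd.Series({
            "n": len(g),
            "n_censored": int(g["censored"].sum()),
            "median": float(usable.median()) if len(usable) else float("nan"),
            "mean": float(usable.mean()) if len(usable) else float("nan"),
            "censored_only": len(usable) == 0,
        })

    per_peak = (df[df["peak_id"].notna()]
                .groupby("peak_id").apply(_summary, include_groups=False))
    per_gene = (df[df["gene_id"].notna()]
                .groupby("gene_id").apply(_summary, include_groups=False))
    return per_peak, per_gene


def collect_tail_reads(alignments, class_map: Mapping[str, Mapping],
                       r2_lookup: Mapping[str, tuple[str, str]],
                       adaptor_len_by_cell: Optional[Mapping[str, int]] = None,
                       params: Optional[TailParams] = None) -> list[TailRead]:
    """Join tail alignments with their R2 tail measurements.

    ``alignments`` yields :class:`c2t.capcall.AlignedRead` for the trimmed
    tail-side R1; ``r2_lookup`` maps read_id to the (seq, qual) of the raw R2.
    When the per-cell adaptor length is known it overrides the regex-detected
    prefix length, which may otherwise absorb a uridylation A-block."""
    params = params or TailParams()
    out: list[TailRead] = []
    for aln in alignments:
        rec = class_map.get(aln.read_id)
        if rec is None or rec["label"] != "TAIL":
            continue
        pair = r2_lookup.get(aln.read_id)
        if pair is None:
            continue
        seq, qual = pair
        cell = rec.get("cell_id", aln.cell_id)
        prefix_len = rec.get("tail_prefix_len")
        if adaptor_len_by_cell and cell in adaptor_len_by_cell:
            prefix_len = adaptor_len_by_cell[cell]
        if prefix_len is None:
            continue
        m = polya_length_from_r2(seq, qual, prefix_len, params)
        if m is None:
            continue
        if aln.strand == "+":
            anchor = aln.pos + aln.ref_span  # 1-based rightmost aligned base
        else:
            anchor = aln.pos + 1             # 1-based leftmost aligned base
        out.append(TailRead(
            read_id=aln.read_id, cell_id=cell, chrom=aln.chrom,
            strand=aln.strand, anchor_pos=anchor, polya_len=m.polya_len,
            censored=m.censored, u_tail=m.u_tail, u_len=m.u_len,
            tail_adjacent=rec.get("r1_trailing_a", 0) >= params.min_adjacent_a,
            aln_start=aln.pos, aln_end=aln.pos + aln.ref_span))
    return out


def write_tail_table(tail_reads: Sequence[TailRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcell_id\tchrom\tstrand\tanchor_pos\tpolya_len"
                 "\tcensored\tu_tail\tu_len\ttail_adjacent\tpeak_id\tgene_id\n")
        for r in tail_reads:
            fh.write(f"{r.read_id}\t{r.cell_id}\t{r.chrom}\t{r.strand}"
                     f"\t{r.anchor_pos}\t{r.polya_len}\t{int(r.censored)}"
                     f"\t{int(r.u_tail)}\t{r.u_len}\t{int(r.tail_adjacent)}"
                     f"\t{r.apa_peak_id or ''}\t{r.gene_id or ''}\n")


def write_peaks(peaks: Sequence[APAPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tstrand\tstart\tend\tread_count\trpkm"
                 "\tn_tail_sites\tapa_window\n")
        for p in peaks:
            window = apa_window(p) if p.tail_sites else ""
            fh.write(f"{p.id}\t{p.chrom}\t{p.strand}\t{p.start}\t{p.end}"
                     f"\t{p.read_count}\t{p.rpkm:.6g}\t{len(p.tail_sites)}"
                     f"\t{window}\n")
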