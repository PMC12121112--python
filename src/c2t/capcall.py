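"""m7G cap-site detection, maximal-density clustering, and m6Am calling.

Capped 5' termini are recovered from alignments by their template-switching
signature: the non-templated G bases do not match the reference and appear as
a terminal soft clip on the transcript-5' end of the alignment, consisting
exclusively of G (or N) in transcript orientation -- equivalently C/N when the
read is stored reverse-complemented.  Single-base cap sites are piled up from
the 5'-most templated base of each qualifying read, filtered by 3G/4G support
policy, and clustered into cap peaks with a Paraclu-style maximal-density
clustering over (position, count) tags.

m6Am (N6,2'-O-dimethyladenosine at the first transcribed nucleotide) is
restricted to caps whose first templated base is A (m7GpppA).  It is called
per cap cluster from an anti-m6A immunoprecipitation experiment by comparing
the m7GpppA read level between the IP and input fractions:
``log2(CPM_IP + 1) - log2(CPM_input + 1) > cutoff`` (default 0.5).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

_GN = frozenset("GN")
_CN = frozenset("CN")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSETS = ("cap3G", "cap4G", "tail", "genebody")
FRACTIONS = ("input", "IP", "supernatant", "none")

_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class AlignedRead:
    """A single-end alignment of the cap- or tail-side mate.

    ``strand`` is the transcript strand of the alignment; ``pos`` is the
    0-based leftmost reference coordinate; ``cigar`` is a list of
    ``(length, op)`` pairs; ``seq`` is the stored (reference-strand) sequence.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    cigar: list[tuple[int, str]]
    seq: str
    subset: str = "genebody"
    fraction: str = "none"
    cell_id: str = "cell0"

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MDN=X")

    @classmethod
    def from_pysam(cls, aln, subset: str = "genebody",
                   fraction: Optional[str] = None,
                   cell_id: Optional[str] = None) -> "AlignedRead":
        cig = [(length, _CIGAR_OPS[op]) for op, length in aln.cigartuples or []]
        if fraction is None:
            fraction = aln.get_tag("XF") if aln.has_tag("XF") else "none"
        if cell_id is None:
            cell_id = aln.get_tag("CB") if aln.has_tag("CB") else "cell0"
        return cls(aln.query_name, aln.reference_name, aln.reference_start,
                   "-" if aln.is_reverse else "+", cig,
                   (aln.query_sequence or "").upper(), subset, fraction, cell_id)


@dataclass
class CapSite:
    """Single-base cap position with counts split by read subset x fraction.

    ``pos`` is 1-based and denotes the 5'-most templated base of the reads
    piling here (for '-' strand alignments this is the rightmost aligned
    base)."""

    chrom: str
    strand: str
    pos: int
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    first_base: str = "N"

    def add(self, subset: str, fraction: str, n: int = 1) -> None:
        key = (subset, fraction)
        self.counts[key] = self.counts.get(key, 0) + n

    def subset_total(self, subset: str) -> int:
        return sum(v for (s, _), v in self.counts.items() if s == subset)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CapCluster:
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    total_count: int
    min_density: float
    max_density: float
    member_sites: list[CapSite] = field(default_factory=list)
    first_base: str = "N"

    @property
    def mode_site(self) -> CapSite:
        return max(self.member_sites, key=lambda s: (s.total, -s.pos))

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class M6AmCall:
    cluster: CapCluster
    am_ip: float
    am_input: float
    delta: float
    is_m6am: bool


class CapSupportPolicy(str, enum.Enum):
    DROP_4G_ONLY = "drop_4g_only"
    REQUIRE_BOTH = "require_both"
    ANY = "any"


# ---------------------------------------------------------------------------
# cap-read extraction and pileup
# ---------------------------------------------------------------------------

def is_cap_alignment(read: AlignedRead, min_match: int = 10) -> tuple[bool, int]:
    """Test the template-switching soft-clip signature.

    True iff the transcript-5' end of the alignment carries a soft clip whose
    bases are exclusively G/N in transcript orientation (C/N as stored for
    reverse-strand alignments) and the adjacent matched block spans at least
    ``min_match`` bases.  Returns the clip length as the number of
    non-templated G.  Hard-clip-only ends never qualify."""
    if not read.cigar:
        return False, 0
    if read.strand == "+":
        n_clip, op = read.cigar[0]
        if op != "S":
            return False, 0
        nxt = read.cigar[1] if len(read.cigar) > 1 else None
        if nxt is None or nxt[1] != "M" or nxt[0] < min_match:
            return False, 0
        clipped = read.seq[:n_clip]
        ok = bool(clipped) and set(clipped) <= _GN
    else:
        n_clip, op = read.cigar[-1]
        if op != "S":
            return False, 0
        nxt = read.cigar[-2] if len(read.cigar) > 1 else None
        if nxt is None or nxt[1] != "M" or nxt[0] < min_match:
            return False, 0
        clipped = read.seq[len(read.seq) - n_clip:]
        ok = bool(clipped) and set(clipped) <= _CN
    return (True, n_clip) if ok else (False, 0)


def cap_site_position(read: AlignedRead) -> int:
    """1-based position of the 5'-most templated base of an alignment."""
    if read.strand == "+":
        return read.pos + 1
    return read.pos + read.ref_span


def pile_cap_sites(reads: Iterable[AlignedRead],
                   min_match: int = 10) -> list[CapSite]:
    """Aggregate cap-signature reads into single-base cap sites.

    Reads failing :func:`is_cap_alignment` are ignored.  Sites are returned
    sorted by (chrom, strand, pos)."""
    sites: dict[tuple[str, str, int], CapSite] = {}
    for read in reads:
        ok, _ = is_cap_alignment(read, min_match)
        if not ok:
            continue
        pos = cap_site_position(read)
        key = (read.chrom, read.strand, pos)
        site = sites.get(key)
        if site is None:
            site = sites[key] = CapSite(read.chrom, read.strand, pos)
        site.add(read.subset, read.fraction)
    return [sites[k] for k in sorted(sites)]


def filter_cap_sites(sites: Sequence[CapSite],
                     policy: CapSupportPolicy = CapSupportPolicy.DROP_4G_ONLY
                     ) -> list[CapSite]:
    """Apply the 3G/4G support policy.

    ``drop_4g_only`` removes sites supported exclusively by the 4G subset;
    ``require_both`` keeps sites with both 3G and 4G support; ``any`` keeps
    everything.  ``require_both`` output is a subset of ``drop_4g_only``
    output, which is a subset of ``any``."""
    policy = CapSupportPolicy(policy)
    out = []
    for s in sites:
        n3, n4 = s.subset_total("cap3G"), s.subset_total("cap4G")
        if policy is CapSupportPolicy.DROP_4G_ONLY:
            if n3 == 0 and n4 > 0:
                continue
        elif policy is CapSupportPolicy.REQUIRE_BOTH:
            if not (n3 > 0 and n4 > 0):
                continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# maximal-density (Paraclu-style) clustering
# ---------------------------------------------------------------------------

def _weakest_break(pos: Sequence[int], cnt: Sequence[int], lo: int, hi: int
                   ) -> tuple[int, Fraction]:
    """Weakest terminal piece of sites[lo:hi] (hi - lo >= 2).

    A prefix (or suffix) piece becomes worth dropping once the density
    parameter exceeds (piece total) / (span freed by dropping it); the span
    runs to the nearest retained site, i.e. it includes the gap.  Returns
    (mid, density) for the piece with the smallest such critical density;
    prefix candidates win ties, shorter pieces first."""
    best: Optional[Fraction] = None
    mid = lo + 1
    tot = 0
    for i in range(lo, hi - 1):
        tot += cnt[i]
        d = Fraction(tot, pos[i + 1] - pos[lo])
        if best is None or d < best:
            best, mid = d, i + 1
    tot = 0
    for i in range(hi - 1, lo, -1):
        tot += cnt[i]
        d = Fraction(tot, pos[hi - 1] - pos[i - 1])
        if best is None or d < best:
            best, mid = d, i
    assert best is not None
    return mid, best


def paraclu(sites: Sequence[tuple[int, int]]) -> list[dict]:
    """Maximal-density clustering of sorted single-base tags.

    ``sites`` is a list of (position, count) with strictly increasing
    positions and positive counts.  Returns the full laminar family of
    clusters, each a dict with ``start``, ``end`` (inclusive positions),
    ``lo``/``hi`` site-index range, ``total``, ``min_density`` and
    ``max_density``.  A cluster is reported for the density range over which
    it is the maximal segment whose every prefix and suffix meets the density;
    ``max_density`` is ``None`` (infinite) for single-site clusters and
    ``min_density`` is 0 for the root.  Densities are exact rationals."""
    if not sites:
        return []
    pos = [p for p, _ in sites]
    cnt = [c for _, c in sites]
    if any(c <= 0 for c in cnt):
        raise ValueError("site counts must be positive")
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("site positions must be strictly increasing")
    prefix = [0]
    for c in cnt:
        prefix.append(prefix[-1] + c)
    out: list[dict] = []
    # explicit stack: (lo, hi, inherited minimum density)
    stack: list[tuple[int, int, Fraction]] = [(0, len(sites), Fraction(0))]
    while stack:
        lo, hi, min_den = stack.pop()
        if hi - lo == 1:
            out.append({"lo": lo, "hi": hi, "start": pos[lo], "end": pos[lo],
                        "total": cnt[lo], "min_density": min_den,
                        "max_density": None})
            continue
        mid, break_den = _weakest_break(pos, cnt, lo, hi)
        if break_den > min_den:
            out.append({"lo": lo, "hi": hi, "start": pos[lo],
                        "end": pos[hi - 1], "total": prefix[hi] - prefix[lo],
                        "min_density": min_den, "max_density": break_den})
            child_min = break_den
        else:
            child_min = min_den
        stack.append((mid, hi, child_min))
        stack.append((lo, mid, child_min))
    out.sort(key=lambda c: (c["start"], -(c["end"])))
    return out


def paraclu_cluster(sites: Sequence[tuple[int, int]], min_count: int = 10,
                    max_length: int = 200, min_density_fold: float = 2.0
                    ) -> list[dict]:
    """Paraclu clustering with the canonical post-filters: minimum total tag
    count, maximum cluster length, and minimum max/min density fold."""
    out = []
    for c in paraclu(sites):
        if c["total"] < min_count:
            continue
        if c["end"] - c["start"] + 1 > max_length:
            continue
        dmin = float(c["min_density"])
        dmax = float("inf") if c["max_density"] is None else float(c["max_density"])
        fold = float("inf") if dmin == 0 else dmax / dmin
        if fold < min_density_fold:
            continue
        out.append(c)
    return out


@dataclass
class ParacluParams:
    min_count: int = 10
    max_length: int = 200
    min_density_fold: float = 2.0
    simplify: bool = True   # drop clusters nested inside a retained cluster


def cluster_cap_sites(sites: Sequence[CapSite],
                      params: Optional[ParacluParams] = None) -> list[CapCluster]:
    """Cluster filtered cap sites into cap peaks per (chrom, strand).

    With ``simplify`` (the canonical post-processing) only the outermost
    cluster of each nested chain that survives the count/length/fold filters
    is kept, so peaks are disjoint."""
    params = params or ParacluParams()
    groups: dict[tuple[str, str], list[CapSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.strand), []).append(s)
    clusters: list[CapCluster] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda s: s.pos)
        tags = [(s.pos, s.total) for s in members]
        passed = paraclu_cluster(tags, params.min_count, params.max_length,
                                 params.min_density_fold)
        if params.simplify:
            kept: list[dict] = []
            for c in sorted(passed, key=lambda c: c["lo"] - c["hi"]):
                if not any(k["lo"] <= c["lo"] and c["hi"] <= k["hi"]
                           for k in kept):
                    kept.append(c)
            passed = sorted(kept, key=lambda c: c["start"])
        for c in passed:
            dmax = float("inf") if c["max_density"] is None else float(c["max_density"])
            clusters.append(CapCluster(
                chrom, strand, c["start"], c["end"], c["total"],
                float(c["min_density"]), dmax,
                member_sites=members[c["lo"]:c["hi"]]))
    return clusters


# ---------------------------------------------------------------------------
# first templated base and m6Am calling
# ---------------------------------------------------------------------------

def reference_base(genome: Mapping[str, str], chrom: str, pos: int,
                   strand: str) -> str:
    """Strand-corrected reference base at a 1-based position.

    ``genome`` maps chromosome name to sequence (a dict or a pyfaidx.Fasta
    both work)."""
    seq = genome[chrom]
    if pos < 1 or pos > len(seq):
        raise IndexError(f"{chrom}:{pos} outside reference")
    base = str(seq[pos - 1]).upper()
    return _COMP[base] if strand == "-" else base


def first_templated_base(read: AlignedRead, genome: Mapping[str, str]) -> str:
    """Reference base, strand-corrected, at the 5'-most templated position of
    a cap alignment.  N excludes the read from the m7GpppA set."""
    return reference_base(genome, read.chrom, cap_site_position(read),
                          read.strand)


def annotate_first_base(clusters: Iterable[CapCluster],
                        genome: Mapping[str, str]) -> None:
    """Set each cluster's (and member sites') first templated base; the
    cluster takes the base of its dominant (highest-count) site."""
    for cl in clusters:
        for s in cl.member_sites:
            s.first_base = reference_base(genome, s.chrom, s.pos, s.strand)
        cl.first_base = cl.mode_site.first_base


def m7gpppa_counts(reads: Iterable[AlignedRead], clusters: Sequence[CapCluster],
                   genome: Mapping[str, str], min_match: int = 10
                   ) -> dict[int, dict[str, int]]:
    """Per-cluster, per-fraction counts of m7GpppA reads (cap-signature reads
    whose first templated base is A).  Keys are cluster indices."""
    index: dict[tuple[str, str, int], int] = {}
    for i, cl in enumerate(clusters):
        for s in cl.member_sites:
            index[(s.chrom, s.strand, s.pos)] = i
    counts: dict[int, dict[str, int]] = {i: {} for i in range(len(clusters))}
    for read in reads:
        ok, _ = is_cap_alignment(read, min_match)
        if not ok:
            continue
        pos = cap_site_position(read)
        i = index.get((read.chrom, read.strand, pos))
        if i is None:
            continue
        if first_templated_base(read, genome) != "A":
            continue
        frac = counts[i]
        frac[read.fraction] = frac.get(read.fraction, 0) + 1
    return counts


def am_level(count: int, library_size: int) -> float:
    """Am metric for one fraction: log2(CPM + 1)."""
    import math
    if library_size <= 0:
        raise ValueError("zero library size")
    return math.log2(count * 1e6 / library_size + 1.0)


def call_m6am(clusters: Sequence[CapCluster],
              capa_counts: Mapping[int, Mapping[str, int]],
              library_sizes: Mapping[str, int],
              cutoff: float = 0.5) -> list[M6AmCall]:
    """Call m6Am per cap cluster from IP vs input m7GpppA levels.

    Only clusters whose dominant cap site has first templated base A are
    considered (annotate first bases beforehand).  The supernatant fraction is
    carried for QC but does not enter the decision."""
    for frac in ("IP", "input"):
        if library_sizes.get(frac, 0) <= 0:
            raise ValueError(f"zero or missing library size for fraction {frac!r}")
    calls: list[M6AmCall] = []
    for i, cl in enumerate(clusters):
        if cl.first_base != "A":
            continue
        counts = capa_counts.get(i, {})
        ip = am_level(counts.get("IP", 0), library_sizes["IP"])
        inp = am_level(counts.get("input", 0), library_sizes["input"])
        delta = ip - inp
        calls.append(M6AmCall(cl, ip, inp, delta, delta > cutoff))
    return calls


# ---------------------------------------------------------------------------
# SAM plumbing
# ---------------------------------------------------------------------------

_LABEL_TO_SUBSET = {"CAP_4G": "cap4G", "CAP_3G": "cap3G", "TAIL": "tail"}


def read_alignments(sam_path: str | Path,
                    class_map: Optional[Mapping[str, Mapping]] = None,
                    subsets: Optional[set[str]] = None
                    ) -> Iterator[AlignedRead]:
    """Stream alignments from a SAM/BAM file as :class:`AlignedRead`.

    When a classification map (``read_id -> {label, ...}``) is given, the
    subset is derived from the classification label and unclassified or
    discarded reads are skipped.  ``subsets`` restricts the output."""
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            subset = "genebody"
            if class_map is not None:
                rec = class_map.get(aln.query_name)
                if rec is None:
                    continue
                subset = _LABEL_TO_SUBSET.get(rec["label"])
                if subset is None:
                    continue
            if subsets is not None and subset not in subsets:
                continue
            yield AlignedRead.from_pysam(aln, subset=subset)


def write_sites_bed(sites: Sequence[CapSite], path: str | Path) -> None:
    """Cap sites as BED6+ with per-subset count columns."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\ttotal\tstrand\t" +
                 "\t".join(SUBSETS) + "\n")
        for s in sites:
            row = [s.chrom, str(s.pos - 1), str(s.pos),
                   f"{s.chrom}:{s.pos}:{s.strand}", str(s.total), s.strand]
            row += [str(s.subset_total(sub)) for sub in SUBSETS]
            fh.write("\t".join(row) + "\n")


def write_clusters_tsv(clusters: Sequence[CapCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tstart\tend\ttotal\tmin_density\tmax_density"
                 "\tn_sites\tmode_pos\tfirst_base\n")
        for cl in clusters:
            dmax = "inf" if cl.max_density == float("inf") else f"{cl.max_density:.6g}"
            fh.write(f"{cl.chrom}\t{cl.strand}\t{cl.start}\t{cl.end}\t"
                     f"{cl.total_count}\t{cl.min_density:.6g}\t{dmax}\t"
                     f"{len(cl.member_sites)}\t{cl.mode_site.pos}\t{cl.first_base}\n")


def write_m6am_tsv(calls: Sequence[M6AmCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tstart\tend\tam_ip\tam_input\tdelta\tis_m6am\n")
        for c in calls:
            fh.write(f"{c.cluster.chrom}\t{c.cluster.strand}\t{c.cluster.start}"
                     f"\t{c.cluster.end}\t{c.am_ip:.6g}\t{c.am_input:.6g}"
                     f"\t{c.delta:.6g}\t{int(c.is_m6am)}\n")
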