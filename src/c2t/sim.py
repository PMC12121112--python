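"""Synthetic cap-to-tail library generator with full ground truth.

The generator emulates a ligation-based single-cell library: RNA molecules
are fragmented; every fragment receives a cell-indexed adaptor at its 3' end
and non-templated G bases at its 5' end from the template-switching reaction.
Capped molecule 5' ends draw their G count from a cap-biased distribution
(>20% of capped molecules receive more than three G), while hydroxyl 5' ends
(uncapped termini and all internal fragment ends) receive almost strictly
three G.  Tail fragments span the poly(A) tail: their R2 starts with the
adaptor, an optional A-block (the complement of a 3' uridylation tail), and a
T-run encoding the tail length.

Reads are emitted as paired FASTQ plus a truth SAM holding the exact
alignment of every genomic read portion (leading G and trailing tail bases as
soft clips), so the downstream pipeline can run without an external aligner.
Truth tables record the per-molecule ground truth (cap status, G count, tail
length, uridylation, cleavage site, fraction) and per-gene parameters.

Simplifications relative to real data (see the package methods note): only
substitution sequencing errors; A-runs in transcript bodies are capped below
the tail-detection threshold and cleavage-proximal bases are A-free, so true
tail lengths and anchors are identifiable; transcripts start with a non-G
base; adaptors contain no T.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .readclass import (CapPrefixClass, ProtocolProfile, classify_cap_prefix,
                        detect_tail_prefix, revcomp)

_BASES = np.array(list("ACGT"))


@dataclass
class ApaSite:
    t_pos: int        # transcript index (0-based) of the canonical last base
    genome_pos: int   # 1-based genome coordinate of that base
    weight: float
    window: int       # jitter width W: cleavage uniform on [t_pos - W, t_pos]


@dataclass
class SimTranscript:
    gene_id: str
    chrom: str
    strand: str
    g_start: int                 # 0-based genome start of the gene span
    length: int
    sequence: str                # transcript-sense sequence of the full span
    tss_genome: int              # 1-based
    first_base: str
    apa_sites: list[ApaSite]
    cap_prob: float
    m6am: bool
    polya_minus: bool
    u_tail_prob: float
    expression: float            # expected molecules per cell

    @property
    def g_end(self) -> int:
        return self.g_start + self.length


@dataclass
class SimConfig:
    """Generation parameters; the defaults define the reference experiment:
    300 genes x 4 cells at ~50k read pairs, PE250."""

    n_genes: int = 300
    n_cells: int = 4
    n_chroms: int = 4
    molecules_per_gene_cell: float = 14.0
    read_len: int = 250
    # fragment geometry (nt)
    frag_len_mean: float = 200.0
    frag_len_sd: float = 50.0
    frag_len_min: int = 120
    frag_len_max: int = 350
    tail_genomic_min: int = 200
    tail_genomic_max: int = 420
    internal_rate: float = 1.0          # Poisson mean internal fragments/molecule
    # terminal structure
    error_rate: float = 0.005
    g_count_dist_capped: dict[int, float] = field(
        default_factory=lambda: {3: 0.75, 4: 0.15, 5: 0.07, 6: 0.03})
    g_count_dist_uncapped: dict[int, float] = field(
        default_factory=lambda: {3: 0.98, 4: 0.02})
    cap_prob: float = 0.85
    cap_minus_fraction: float = 0.1
    cap_minus_cap_prob: float = 0.05
    # 5'-end micro-heterogeneity (positional noise <= 1 nt): probability of
    # a molecule starting 0/1 nt downstream of the canonical TSS
    tss_shift_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.8, 1: 0.2})
    polya_minus_fraction: float = 0.1
    m6am_fraction: float = 0.15
    # poly(A) tail
    polya_mean: float = 65.0
    polya_sd: float = 15.0
    polya_min: int = 20
    polya_max: int = 143
    u_tail_prob: float = 0.1
    u_geom_p: float = 0.5
    u_tail_len_factor: float = 0.6      # uridylated tails are shorter
    # gene structure
    transcript_len_min: int = 1600
    transcript_len_max: int = 2600
    intergenic_gap: int = 5000
    second_apa_prob: float = 0.3
    apa_offset_min: int = 800
    apa_offset_max: int = 1100
    apa_window_max: int = 10
    apa_window_fixed: Optional[int] = None  # overrides the per-gene draw
    # expression variation across genes (uniform multiplicative range)
    expression_jitter: float = 0.25
    # IP experiment
    ip_enrichment_fold: float = 4.0
    seed: int = 42

    def __post_init__(self) -> None:
        for dist in (self.g_count_dist_capped, self.g_count_dist_uncapped,
                     self.tss_shift_probs):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("probability table must sum to 1")
        lo, hi = ProtocolProfile().tail_prefix_range
        if self.read_len < hi + ProtocolProfile().min_t_run:
            raise ValueError("read_len shorter than tail prefix + minimum T run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("g_count_dist_capped", "g_count_dist_uncapped",
                    "tss_shift_probs"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        return cls(**data)


@dataclass
class SimReference:
    genome: dict[str, str]
    transcripts: list[SimTranscript]
    config: SimConfig

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _cap_a_runs(seq: np.ndarray, rng: np.random.Generator, max_run: int = 4
                ) -> None:
    """Break A-runs longer than ``max_run`` in place (prevents internal
    oligo(dT)-like T-runs in reverse-complemented reads)."""
    run = 0
    for i in range(len(seq)):
        if seq[i] == "A":
            run += 1
            if run > max_run:
                seq[i] = rng.choice(np.array(list("CGT")))
                run = 0
        else:
            run = 0


def simulate_transcriptome(config: SimConfig) -> SimReference:
    """Random genome with non-overlapping single-exon genes on both strands.

    Deterministic under ``config.seed``.  A configurable fraction of genes is
    poly(A)-minus and a fraction cap-minus (histone-like); a fraction of
    A-starting genes carries m6Am.  Cleavage-window bases are drawn A-free so
    that simulated tail lengths are identifiable from reads."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = config.n_genes
    polya_minus = np.zeros(n, dtype=bool)
    polya_minus[: int(round(n * config.polya_minus_fraction))] = True
    cap_minus = np.zeros(n, dtype=bool)
    k = int(round(n * config.cap_minus_fraction))
    cap_minus[n - k:] = True  # disjoint from the poly(A)-minus block when possible
    m6am = np.zeros(n, dtype=bool)
    candidates = np.flatnonzero(~cap_minus & ~polya_minus)
    n_m6am = min(int(round(n * config.m6am_fraction)), len(candidates))
    m6am[candidates[:n_m6am]] = True

    transcripts: list[SimTranscript] = []
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chroms)}
    chrom_cursor: dict[str, int] = {c: 0 for c in chrom_parts}

    for gi in range(n):
        gene_id = f"g{gi + 1:04d}"
        chrom = f"chr{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        L = int(rng.integers(config.transcript_len_min,
                             config.transcript_len_max + 1))
        seq = rng.choice(_BASES, size=L)
        _cap_a_runs(seq, rng)
        # first transcribed base: A for m6Am genes, otherwise non-G
        if m6am[gi]:
            seq[0] = "A"
        else:
            seq[0] = rng.choice(np.array(list("ACT")))
        # APA sites: canonical 3' end, optionally one upstream site
        def draw_window() -> int:
            if config.apa_window_fixed is not None:
                return config.apa_window_fixed
            return int(rng.integers(0, config.apa_window_max + 1))

        sites: list[tuple[int, float, int]] = []
        w1 = draw_window()
        sites.append((L - 1, 0.7, w1))
        if rng.random() < config.second_apa_prob:
            delta = int(rng.integers(config.apa_offset_min,
                                     config.apa_offset_max + 1))
            sites.append((L - 1 - delta, 0.3, draw_window()))
        else:
            sites = [(L - 1, 1.0, w1)]
        # cleavage-window bases (plus a 2 nt margin) must not be A
        nonA = np.array(list("CGT"))
        for t_pos, _, w in sites:
            lo = max(0, t_pos - w - 2)
            for i in range(lo, t_pos + 1):
                if seq[i] == "A":
                    seq[i] = rng.choice(nonA)
        tseq = "".join(seq)

        gap = "".join(rng.choice(_BASES, size=config.intergenic_gap))
        g_start = chrom_cursor[chrom] + config.intergenic_gap
        chrom_parts[chrom].append(gap)
        chrom_parts[chrom].append(tseq if strand == "+" else revcomp(tseq))
        chrom_cursor[chrom] = g_start + L

        tss = g_start + 1 if strand == "+" else g_start + L
        apa = []
        total_w = sum(w for _, w, _ in sites)
        for t_pos, w, win in sites:
            gpos = g_start + t_pos + 1 if strand == "+" else g_start + L - t_pos
            apa.append(ApaSite(t_pos, gpos, w / total_w, win))
        expr = config.molecules_per_gene_cell * float(
            rng.uniform(1 - config.expression_jitter,
                        1 + config.expression_jitter))
        cap_p = config.cap_minus_cap_prob if cap_minus[gi] else config.cap_prob
        transcripts.append(SimTranscript(
            gene_id=gene_id, chrom=chrom, strand=strand, g_start=g_start,
            length=L, sequence=tseq, tss_genome=tss, first_base=tseq[0],
            apa_sites=apa, cap_prob=cap_p, m6am=bool(m6am[gi]),
            polya_minus=bool(polya_minus[gi]),
            u_tail_prob=config.u_tail_prob, expression=expr))

    genome = {c: "".join(parts) + "".join(
        rng.choice(_BASES, size=config.intergenic_gap))
        for c, parts in chrom_parts.items()}
    return SimReference(genome=genome, transcripts=transcripts, config=config)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    read_id: str
    cell_id: str
    gene_id: str
    kind: str            # five_prime | internal | tail
    r1: str
    r2: str
    # truth alignment of the R1 genomic portion
    chrom: str = ""
    strand: str = "+"
    aln_start: int = 0   # 0-based genome start of the aligned block
    aln_len: int = 0
    n_clip5: int = 0     # leading soft clip (non-template G) in transcript sense
    n_clip3: int = 0     # trailing soft clip (adaptor / tail bases)
    sam_seq: str = ""    # stored (reference-strand) sequence
    # per-molecule truth
    capped: bool = False
    n_g: int = 0
    polya_len: int = 0
    u_len: int = 0
    censored: bool = False
    cleavage_genome: int = 0
    tail_adjacent: bool = False
    insert_len: int = 0
    expected_label: str = ""
    fraction: str = "none"
    t5_base: str = ""    # transcript base at the fragment's first templated position


def _make_cells(config: SimConfig, rng: np.random.Generator
                ) -> list[tuple[str, str]]:
    """(cell_id, observed R2 adaptor prefix) pairs; adaptors are T-free and
    unique in their first 7 bases."""
    cells = []
    seen: set[str] = set()
    alphabet = np.array(list("ACG"))
    for i in range(config.n_cells):
        length = 7 + (i % 2)
        while True:
            adaptor = "".join(rng.choice(alphabet, size=length))
            if adaptor[:7] not in seen:
                seen.add(adaptor[:7])
                break
        cells.append((f"cell{i:02d}", adaptor))
    return cells


def _categorical(dist: dict[int, float]):
    values = np.array(sorted(dist))
    probs = np.array([dist[v] for v in values])
    cum = np.cumsum(probs)
    cum[-1] = 1.0

    def draw(rng: np.random.Generator) -> int:
        return int(values[np.searchsorted(cum, rng.random(), side="right")])

    return draw


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    arr = list(seq)
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _draw_polya(config: SimConfig, rng: np.random.Generator,
                uridylated: bool) -> int:
    mean = config.polya_mean * (config.u_tail_len_factor if uridylated else 1.0)
    for _ in range(100):
        x = int(round(rng.normal(mean, config.polya_sd)))
        if config.polya_min <= x <= config.polya_max:
            return x
    return int(np.clip(x, config.polya_min, config.polya_max))


def simulate_library(ref: SimReference, fraction: str = "none",
                     enrichment: Optional[Mapping[str, float]] = None,
                     rng_tag: int = 0) -> tuple[list[SimRead], list[tuple[str, str]]]:
    """Generate the read set of one library (one fraction).

    ``enrichment`` maps gene_id to a capped-molecule sampling factor (the
    anti-m6A immunoprecipitation model); uncapped molecules are never
    enriched.  Returns the reads and the (cell_id, adaptor) table."""
    config = ref.config
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 23, rng_tag]))
    cells = _make_cells(config, np.random.default_rng(
        np.random.SeedSequence([config.seed, 7])))
    draw_g_capped = _categorical(config.g_count_dist_capped)
    draw_g_uncapped = _categorical(config.g_count_dist_uncapped)
    profile = ProtocolProfile.scm6a_c2t()
    reads: list[SimRead] = []
    counter = 0

    for tr in ref.transcripts:
        site_cum = np.cumsum([s.weight for s in tr.apa_sites])
        site_cum[-1] = 1.0
        for cell_id, adaptor in cells:
            adapt_sense = revcomp(adaptor)
            for capped in (True, False):
                p = tr.cap_prob if capped else 1.0 - tr.cap_prob
                factor = 1.0
                if capped and enrichment is not None:
                    factor = enrichment.get(tr.gene_id, 1.0)
                n_mol = rng.poisson(tr.expression * p * factor)
                for _ in range(n_mol):
                    counter += 1
                    mol_id = f"{tr.gene_id}:{cell_id}:m{counter:07d}"
                    site = tr.apa_sites[int(np.searchsorted(
                        site_cum, rng.random(), side="right"))]
                    jitter = int(rng.integers(0, site.window + 1))
                    c = site.t_pos - jitter  # last templated base, 0-based
                    if tr.polya_minus:
                        polya, u_len = 0, 0
                    else:
                        uridylated = rng.random() < tr.u_tail_prob
                        u_len = int(rng.geometric(config.u_geom_p)) if uridylated else 0
                        polya = _draw_polya(config, rng, uridylated)
                    n_g5 = draw_g_capped(rng) if capped else draw_g_uncapped(rng)
                    reads.extend(_emit_molecule(
                        tr, cell_id, adaptor, adapt_sense, mol_id, c, polya,
                        u_len, capped, n_g5, draw_g_uncapped, config, rng,
                        profile))
    for r in reads:
        r.fraction = fraction
    return reads, cells


def _emit_molecule(tr: SimTranscript, cell_id: str, adaptor: str,
                   adapt_sense: str, mol_id: str, c: int, polya: int,
                   u_len: int, capped: bool, n_g5: int, draw_g_uncapped,
                   config: SimConfig, rng: np.random.Generator,
                   profile: ProtocolProfile) -> list[SimRead]:
    rl = config.read_len
    seq = tr.sequence
    L_c = c + 1
    out: list[SimRead] = []

    def genome_interval(t_lo: int, t_hi: int) -> int:
        """0-based genome start of transcript slice [t_lo, t_hi)."""
        if tr.strand == "+":
            return tr.g_start + t_lo
        return tr.g_start + tr.length - t_hi

    def build(kind: str, n_g: int, t_lo: int, t_hi: int, tail: str,
              polya_rec: int, u_rec: int) -> SimRead:
        frag = seq[t_lo:t_hi]
        insert = "G" * n_g + frag + tail + adapt_sense
        r1 = insert[:rl]
        r2 = revcomp(insert)[:rl]
        aln_len = min(t_hi - t_lo, max(0, len(r1) - n_g))
        clip3 = len(r1) - n_g - aln_len
        if tr.strand == "+":
            aln_start = genome_interval(t_lo, t_hi)
            sam_seq_clean = r1
        else:
            aln_start = genome_interval(t_lo, t_lo + aln_len)
            sam_seq_clean = revcomp(r1)
        read = SimRead(
            read_id=f"{mol_id}:{kind[0]}{len(out)}", cell_id=cell_id,
            gene_id=tr.gene_id, kind=kind, r1=r1, r2=r2, chrom=tr.chrom,
            strand=tr.strand, aln_start=aln_start, aln_len=aln_len,
            n_clip5=n_g, n_clip3=clip3, sam_seq=sam_seq_clean,
            capped=capped if kind == "five_prime" else False, n_g=n_g,
            polya_len=polya_rec, u_len=u_rec, insert_len=len(insert),
            t5_base=seq[t_lo])
        # apply sequencing errors consistently to reads and stored alignment
        read.r1 = _mutate(read.r1, rng, config.error_rate)
        read.r2 = _mutate(read.r2, rng, config.error_rate)
        if tr.strand == "+":
            read.sam_seq = read.r1
        else:
            read.sam_seq = revcomp(read.r1)
        return read

    # 5'-terminal fragment (cap side), with TSS micro-heterogeneity
    shifts = sorted(config.tss_shift_probs)
    shift_cum = np.cumsum([config.tss_shift_probs[s] for s in shifts])
    shift_cum[-1] = 1.0
    shift = shifts[int(np.searchsorted(shift_cum, rng.random(), side="right"))]
    f = int(np.clip(round(rng.normal(config.frag_len_mean, config.frag_len_sd)),
                    config.frag_len_min, config.frag_len_max))
    f = min(f, L_c - shift)
    out.append(build("five_prime", n_g5, shift, shift + f, "", 0, 0))

    # internal fragments
    for _ in range(rng.poisson(config.internal_rate)):
        if L_c < 160:
            break
        s = int(rng.integers(1, L_c - 100))
        fi = int(np.clip(round(rng.normal(config.frag_len_mean,
                                          config.frag_len_sd)),
                         config.frag_len_min, config.frag_len_max))
        e = min(s + fi, L_c)
        out.append(build("internal", draw_g_uncapped(rng), s, e, "", 0, 0))

    # 3'-terminal (tail) fragment
    if polya > 0:
        g_len = int(rng.integers(config.tail_genomic_min,
                                 config.tail_genomic_max + 1))
        g_len = min(g_len, L_c - 1)
        tail = "A" * polya + "T" * u_len
        n_gt = draw_g_uncapped(rng)
        read = build("tail", n_gt, c + 1 - g_len, c + 1, tail, polya, u_len)
        read.cleavage_genome = (tr.g_start + c + 1 if tr.strand == "+"
                                else tr.g_start + tr.length - c)
        # R1 reaches the tail iff the genomic part fits before the read end
        read.tail_adjacent = g_len <= rl - n_gt - 1
        # tail SAM record: poly(A)-trimmed R1; restrict to the genomic part
        aln_len = min(g_len, rl - n_gt)
        read.aln_len = aln_len
        read.n_clip3 = 0
        r1_clean_prefix = read.r1[: n_gt + aln_len]
        # the alignment covers the first aln_len genomic bases of the
        # fragment (R1 may not reach the tail when g_len > read capacity)
        read.aln_start = genome_interval(c + 1 - g_len,
                                         c + 1 - g_len + aln_len)
        if tr.strand == "+":
            read.sam_seq = r1_clean_prefix
        else:
            read.sam_seq = revcomp(r1_clean_prefix)
        # censoring truth: the T-run reaches the usable R2 end
        read.censored = len(adaptor) + u_len + polya >= rl
        out.append(read)
    return out


def annotate_expected_labels(reads: Sequence[SimRead],
                             config: SimConfig) -> None:
    """Set each read's expected terminal class from its clean construction:
    tail fragments are read-through discards when the full insert is shorter
    than the minimum; other fragments follow the cap-prefix rule.  Exact for
    error-free reads."""
    profile = ProtocolProfile.scm6a_c2t()
    for r in reads:
        tail_match = detect_tail_prefix(r.r2, profile)
        if tail_match is not None:
            overlap = len(r.r1) + len(r.r2) - r.insert_len
            if (r.insert_len < profile.min_merged_insert
                    and overlap >= profile.merge_min_overlap):
                r.expected_label = "READTHROUGH_DISCARD"
            else:
                r.expected_label = "TAIL"
            continue
        cls, _ = classify_cap_prefix(r.r1)
        r.expected_label = {CapPrefixClass.FOUR_G: "CAP_4G",
                            CapPrefixClass.THREE_G: "CAP_3G",
                            CapPrefixClass.OTHER: "OTHER"}[cls]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(transcripts: Sequence[SimTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tr in transcripts:
            attrs = (f'gene_id "{tr.gene_id}"; transcript_id "{tr.gene_id}.1"; '
                     f'gene_name "{tr.gene_id}";')
            for feature in ("gene", "transcript", "exon"):
                fh.write(f"{tr.chrom}\tsim\t{feature}\t{tr.g_start + 1}\t"
                         f"{tr.g_end}\t.\t{tr.strand}\t.\t{attrs}\n")


def write_sample_sheet(cells: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("adaptor\tcell_id\n")
        for cell_id, adaptor in cells:
            fh.write(f"{adaptor}\t{cell_id}\n")


def write_fastq(reads: Sequence[SimRead], r1_path: str | Path,
                r2_path: str | Path, qual_char: str = "F") -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}\n{r.r1}\n+\n{qual_char * len(r.r1)}\n")
            f2.write(f"@{r.read_id}\n{r.r2}\n+\n{qual_char * len(r.r2)}\n")


def write_truth_sam(reads: Sequence[SimRead], chrom_lengths: Mapping[str, int],
                    path: str | Path, fraction: str = "none") -> None:
    """Truth alignments of the R1 genomic portions (tail reads poly(A)-trimmed)."""
    import pysam

    chroms = sorted(chrom_lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms]}
    tid = {c: i for i, c in enumerate(chroms)}
    records = []
    for r in reads:
        if r.aln_len <= 0:
            continue
        a = pysam.AlignedSegment()
        a.query_name = r.read_id
        a.reference_id = tid[r.chrom]
        a.reference_start = r.aln_start
        a.mapping_quality = 60
        a.is_reverse = r.strand == "-"
        if r.strand == "+":
            cig = []
            if r.n_clip5:
                cig.append((4, r.n_clip5))
            cig.append((0, r.aln_len))
            if r.n_clip3:
                cig.append((4, r.n_clip3))
        else:
            cig = []
            if r.n_clip3:
                cig.append((4, r.n_clip3))
            cig.append((0, r.aln_len))
            if r.n_clip5:
                cig.append((4, r.n_clip5))
        a.cigartuples = cig
        a.query_sequence = r.sam_seq
        a.query_qualities = pysam.qualitystring_to_array("F" * len(r.sam_seq))
        a.set_tag("CB", r.cell_id)
        a.set_tag("XF", fraction)
        records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in records:
            fh.write(a)


def write_truth_reads(reads: Sequence[SimRead], path: str | Path,
                      fraction: str = "none") -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\tcell_id\tfraction\tkind\tcapped\tn_g"
                 "\tpolya_len\tu_len\tcensored\tcleavage_genome"
                 "\ttail_adjacent\tinsert_len\texpected_label\tfirst_base\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.gene_id}\t{r.cell_id}\t{fraction}"
                     f"\t{r.kind}\t{int(r.capped)}\t{r.n_g}\t{r.polya_len}"
                     f"\t{r.u_len}\t{int(r.censored)}\t{r.cleavage_genome}"
                     f"\t{int(r.tail_adjacent)}\t{r.insert_len}"
                     f"\t{r.expected_label}\t{r.t5_base}\n")


def write_truth_genes(transcripts: Sequence[SimTranscript],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tg_start\tg_end\ttss\tfirst_base"
                 "\tcap_prob\tm6am\tpolya_minus\texpression\tapa_genome"
                 "\tapa_windows\tapa_weights\n")
        for tr in transcripts:
            sites = ";".join(str(s.genome_pos) for s in tr.apa_sites)
            wins = ";".join(str(s.window) for s in tr.apa_sites)
            wts = ";".join(f"{s.weight:.4g}" for s in tr.apa_sites)
            fh.write(f"{tr.gene_id}\t{tr.chrom}\t{tr.strand}\t{tr.g_start}"
                     f"\t{tr.g_end}\t{tr.tss_genome}\t{tr.first_base}"
                     f"\t{tr.cap_prob:.4g}\t{int(tr.m6am)}"
                     f"\t{int(tr.polya_minus)}\t{tr.expression:.6g}"
                     f"\t{sites}\t{wins}\t{wts}\n")


def write_known_apa_bed(transcripts: Sequence[SimTranscript],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for tr in transcripts:
            for s in tr.apa_sites:
                fh.write(f"{tr.chrom}\t{s.genome_pos - 1}\t{s.genome_pos}"
                         f"\t{tr.gene_id}\t0\t{tr.strand}\n")


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig, out_dir: str | Path,
                        ref: Optional[SimReference] = None,
                        fraction: str = "none",
                        enrichment: Optional[Mapping[str, float]] = None,
                        rng_tag: int = 0) -> dict:
    """Write one full library (reference files + FASTQ + truth) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ref is None:
        ref = simulate_transcriptome(config)
    reads, cells = simulate_library(ref, fraction=fraction,
                                    enrichment=enrichment, rng_tag=rng_tag)
    annotate_expected_labels(reads, config)
    write_fasta(ref.genome, out_dir / "genome.fa")
    write_gtf(ref.transcripts, out_dir / "genes.gtf")
    write_sample_sheet(cells, out_dir / "sample_sheet.tsv")
    write_fastq(reads, out_dir / "reads.R1.fastq", out_dir / "reads.R2.fastq")
    write_truth_sam(reads, ref.chrom_lengths, out_dir / "truth.sam",
                    fraction=fraction)
    write_truth_reads(reads, out_dir / "truth_reads.tsv", fraction=fraction)
    write_truth_genes(ref.transcripts, out_dir / "truth_genes.tsv")
    write_known_apa_bed(ref.transcripts, out_dir / "known_apa.bed")
    return {"n_reads": len(reads), "n_genes": len(ref.transcripts),
            "n_cells": len(cells), "out_dir": str(out_dir)}


def simulate_ip_experiment(config: SimConfig, out_dir: str | Path,
                           ref: Optional[SimReference] = None,
                           fold: Optional[float] = None) -> dict:
    """Input / IP / supernatant libraries with capped-molecule enrichment of
    m6Am genes in the IP and matching depletion in the supernatant."""
    out_dir = Path(out_dir)
    if ref is None:
        ref = simulate_transcriptome(config)
    fold = config.ip_enrichment_fold if fold is None else fold
    enrich = {tr.gene_id: fold for tr in ref.transcripts if tr.m6am}
    deplete = {tr.gene_id: 1.0 / fold for tr in ref.transcripts if tr.m6am}
    plans = [("input", None, 1), ("IP", enrich, 2), ("supernatant", deplete, 3)]
    manifest = {}
    for fraction, weights, tag in plans:
        manifest[fraction] = simulate_experiment(
            config, out_dir / fraction, ref=ref, fraction=fraction,
            enrichment=weights, rng_tag=tag)
    return manifest
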