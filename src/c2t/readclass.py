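"""Terminal classification of read pairs from cap-to-tail (C2T) libraries.

A C2T library is built by fragmenting RNA, ligating a cell-indexed adaptor to
every fragment 3' end, and reverse-transcribing with a template-switching
oligo (TSO).  The TSO step appends non-templated G bases to the cDNA 5' end:
hydroxyl/phosphate 5' ends receive almost strictly three G, whereas m7G-capped
5' ends frequently receive four or more.  Fragments that span a poly(A) tail
produce mate-2 reads that begin with the (7-12 nt) adaptor followed by a run
of T.  This module partitions every read pair into exactly one terminal class
before alignment:

* ``CAP_4G`` / ``CAP_3G`` -- the cap-side mate starts with >=4 / exactly 3
  G-or-N bases (candidate capped / uncapped 5' termini);
* ``TAIL`` -- the tail-side mate matches ``[ACGT]{7,12}TTTTT``;
* ``READTHROUGH_DISCARD`` -- a tail candidate whose mates merge into an
  insert shorter than the minimum (fragmentation may have occurred inside the
  poly(A) tail, so the T count is unreliable);
* ``SHORT_DISCARD`` -- a tail candidate whose genomic anchor is too short
  after poly(A)/adapter trimming;
* ``OTHER`` -- everything else (discarded for the single-cell protocol).
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_GN = frozenset("GN")
_ATC = frozenset("ATC")
_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CapPrefixClass(enum.Enum):
    """Outcome of the 5'-prefix test on the cap-side mate."""

    FOUR_G = "4G"
    THREE_G = "3G"
    OTHER = "other"


class ReadClassLabel(str, enum.Enum):
    CAP_4G = "CAP_4G"
    CAP_3G = "CAP_3G"
    TAIL = "TAIL"
    READTHROUGH_DISCARD = "READTHROUGH_DISCARD"
    SHORT_DISCARD = "SHORT_DISCARD"
    OTHER = "OTHER"


class Protocol(str, enum.Enum):
    SCM6A_C2T = "scm6a_c2t"
    SMARTER_TOTAL = "smarter_total"


@dataclass
class ReadPair:
    """One paired-end record with per-base Phred-33 quality strings."""

    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str
    cell_id: str = "cell0"

    def validate(self) -> None:
        for mate, (seq, qual) in (("R1", (self.r1_seq, self.r1_qual)),
                                  ("R2", (self.r2_seq, self.r2_qual))):
            if not seq:
                raise ValueError(f"{self.read_id}: empty {mate} sequence")
            if len(seq) != len(qual):
                raise ValueError(f"{self.read_id}: {mate} seq/qual length mismatch")
            if not set(seq) <= _VALID:
                raise ValueError(f"{self.read_id}: {mate} has non-ACGTN characters")


@dataclass
class ProtocolProfile:
    """Library-layout parameters: which mate carries which signal, and the
    thresholds of the classification rules."""

    protocol: Protocol = Protocol.SCM6A_C2T
    cap_prefix_mate: str = "R1"
    tail_mate: str = "R2"
    min_merged_insert: int = 300
    min_trimmed_len: int = 18
    tail_prefix_range: tuple[int, int] = (7, 12)
    min_t_run: int = 5
    # merge criterion for "perfectly merged" (read-through) pairs
    merge_min_overlap: int = 20
    merge_max_mismatch_rate: float = 0.05
    # cutadapt-style poly(A) adapter: a run of >= this many A marks the tail
    polya_adapter_min_run: int = 9
    # optional hard clip of TSO-derived bases before output (0 = keep)
    five_prime_hard_trim: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.protocol, str):
            self.protocol = Protocol(self.protocol)
        if self.min_merged_insert <= self.min_trimmed_len:
            raise ValueError("min_merged_insert must exceed min_trimmed_len")
        lo, hi = self.tail_prefix_range
        if not (1 <= lo <= hi <= 30):
            raise ValueError("tail_prefix_range must lie within [1, 30]")

    @classmethod
    def scm6a_c2t(cls, **kw) -> "ProtocolProfile":
        return cls(protocol=Protocol.SCM6A_C2T, cap_prefix_mate="R1",
                   tail_mate="R2", **kw)

    @classmethod
    def smarter_total(cls, **kw) -> "ProtocolProfile":
        return cls(protocol=Protocol.SMARTER_TOTAL, cap_prefix_mate="R2",
                   tail_mate="R2", **kw)


@dataclass
class ClassifiedRead:
    pair: ReadPair
    label: ReadClassLabel
    n_leading_g: int = 0
    tail_prefix_len: Optional[int] = None
    trimmed_r1: str = ""
    trimmed_r2: str = ""
    # number of consecutive A immediately downstream of the trimmed R1 part;
    # a large run marks the R1 alignment end as abutting the poly(A) tail
    r1_trailing_a: int = 0


def classify_cap_prefix(seq: str) -> tuple[CapPrefixClass, int]:
    """Classify the 5' prefix of the cap-side mate.

    Returns ``(FOUR_G, run)`` when the read begins with >=4 consecutive bases
    from {G, N}; ``(THREE_G, 3)`` when it begins with exactly three such bases
    followed by at least one base from {A, T, C}; ``(OTHER, run)`` otherwise.
    N counts as G here because template-switch bases are read with degenerate
    quality; it never counts toward the tail T-run.
    """
    if not seq:
        raise ValueError("empty sequence")
    run = 0
    for ch in seq:
        if ch in _GN:
            run += 1
        else:
            break
    if run >= 4:
        return CapPrefixClass.FOUR_G, run
    if run == 3 and len(seq) > 3 and seq[3] in _ATC:
        return CapPrefixClass.THREE_G, run
    return CapPrefixClass.OTHER, run


def detect_tail_prefix(seq: str, profile: ProtocolProfile) -> Optional[int]:
    """Smallest admissible adaptor-prefix length such that a run of
    ``min_t_run`` T starts right after it; ``None`` if no length qualifies.

    The prefix itself is unconstrained (it may contain T), so the rule is
    ambiguous for T-rich prefixes; the smallest length wins deterministically.
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = profile.tail_prefix_range
    t_run = "T" * profile.min_t_run
    for p in range(lo, hi + 1):
        if len(seq) >= p + profile.min_t_run and seq[p:p + profile.min_t_run] == t_run:
            return p
    return None


def merge_pair(r1: str, r2: str, min_overlap: int = 20,
               max_mismatch_rate: float = 0.05) -> Optional[int]:
    """Attempt to merge a pair via reverse-complement overlap.

    Scans candidate insert lengths from ``max(len(r1), len(r2))`` upward and
    returns the first (i.e. maximum-overlap) length whose overlap of at least
    ``min_overlap`` bases matches at >= ``1 - max_mismatch_rate`` identity.
    Returns ``None`` when the mates do not detectably overlap, which callers
    interpret as an insert longer than the combined read span.
    """
    if not r1 or not r2:
        raise ValueError("empty mate sequence")
    rc2 = revcomp(r2)
    n1, n2 = len(r1), len(rc2)
    for insert in range(max(n1, n2), n1 + n2 - min_overlap + 1):
        # r1 occupies [0, n1); rc2 occupies [insert - n2, insert)
        start = insert - n2
        ov = n1 - start
        if ov < min_overlap:
            break
        budget = int(max_mismatch_rate * ov)
        mism = 0
        ok = True
        for x, y in zip(r1[start:], rc2):
            if x != y:
                mism += 1
                if mism > budget:
                    ok = False
                    break
        if ok:
            return insert
    return None


def trim_polya_from_r1(seq: str, min_trimmed_len: int = 18,
                       adapter_min_run: int = 9) -> Optional[str]:
    """Trim the poly(A) stretch (and anything 3' of it) from a tail-side R1.

    Mirrors a cutadapt ``-a AAAAAAAAAA -O9 -n10`` pass followed by terminal
    A-trimming: the leftmost A-run of length >= ``adapter_min_run`` and all
    bases downstream are removed; otherwise the maximal terminal A-run is
    removed.  Returns ``None`` (a short discard) when fewer than
    ``min_trimmed_len`` bases remain.  Idempotent.
    """
    if not seq:
        raise ValueError("empty sequence")
    cut = len(seq)
    run = 0
    for i, ch in enumerate(seq):
        if ch == "A":
            run += 1
            if run >= adapter_min_run:
                cut = i - run + 1
                break
        else:
            run = 0
    trimmed = seq[:cut]
    trimmed = trimmed.rstrip("A")
    if len(trimmed) < min_trimmed_len:
        return None
    return trimmed


def deduplicate(pairs: Iterable[ReadPair], k: int = 30) -> Iterator[ReadPair]:
    """Drop presumed PCR duplicates: at most one pair is retained per
    ``(cell_id, r1[:k], r2[:k])`` key, first occurrence winning.  The protocol
    has no UMIs, so identical sequence starts within a cell are treated as
    amplification copies."""
    seen: set[tuple[str, str, str]] = set()
    for pair in pairs:
        key = (pair.cell_id, pair.r1_seq[:k], pair.r2_seq[:k])
        if key in seen:
            continue
        seen.add(key)
        yield pair


def classify_pair(pair: ReadPair, profile: ProtocolProfile) -> ClassifiedRead:
    """Assign exactly one terminal class to a read pair.

    Order of precedence: tail detection on the tail mate, then read-through
    filtering and R1 poly(A) trimming for tail candidates, then cap-prefix
    classification on the cap mate.  Under the single-cell protocol every
    non-tail pair is either a 3G/4G cap-class read or discarded."""
    pair.validate()
    tail_seq = pair.r2_seq if profile.tail_mate == "R2" else pair.r1_seq
    prefix_len = detect_tail_prefix(tail_seq, profile)
    if prefix_len is not None:
        merged = merge_pair(pair.r1_seq, pair.r2_seq,
                            profile.merge_min_overlap,
                            profile.merge_max_mismatch_rate)
        if merged is not None and merged < profile.min_merged_insert:
            return ClassifiedRead(pair, ReadClassLabel.READTHROUGH_DISCARD,
                                  tail_prefix_len=prefix_len)
        trimmed = trim_polya_from_r1(pair.r1_seq, profile.min_trimmed_len,
                                     profile.polya_adapter_min_run)
        if trimmed is None:
            return ClassifiedRead(pair, ReadClassLabel.SHORT_DISCARD,
                                  tail_prefix_len=prefix_len)
        trailing_a = 0
        for ch in pair.r1_seq[len(trimmed):]:
            if ch != "A":
                break
            trailing_a += 1
        return ClassifiedRead(pair, ReadClassLabel.TAIL,
                              tail_prefix_len=prefix_len,
                              trimmed_r1=trimmed, trimmed_r2=tail_seq,
                              r1_trailing_a=trailing_a)
    cap_seq = pair.r1_seq if profile.cap_prefix_mate == "R1" else pair.r2_seq
    cls, run = classify_cap_prefix(cap_seq)
    trim = profile.five_prime_hard_trim
    trimmed_cap = cap_seq[trim:] if trim else cap_seq
    if cls is CapPrefixClass.FOUR_G:
        return ClassifiedRead(pair, ReadClassLabel.CAP_4G, n_leading_g=run,
                              trimmed_r1=trimmed_cap)
    if cls is CapPrefixClass.THREE_G:
        return ClassifiedRead(pair, ReadClassLabel.CAP_3G, n_leading_g=run,
                              trimmed_r1=trimmed_cap)
    return ClassifiedRead(pair, ReadClassLabel.OTHER, n_leading_g=run)


def classify_stream(pairs: Iterable[ReadPair], profile: ProtocolProfile,
                    dedup: bool = True, dedup_k: int = 30) -> Iterator[ClassifiedRead]:
    stream: Iterable[ReadPair] = deduplicate(pairs, dedup_k) if dedup else pairs
    for pair in stream:
        yield classify_pair(pair, profile)


# ---------------------------------------------------------------------------
# FASTQ / sample-sheet plumbing
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """TSV with columns ``adaptor`` (observed R2 prefix) and ``cell_id``."""
    table: dict[str, str] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            ia, ic = header.index("adaptor"), header.index("cell_id")
        except ValueError as exc:
            raise ValueError("sample sheet needs 'adaptor' and 'cell_id' columns") from exc
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) > max(ia, ic):
                table[fields[ia]] = fields[ic]
    return table


def assign_cell(r2_seq: str, adaptors: dict[str, str]) -> Optional[str]:
    """Demultiplex by matching the recorded per-cell adaptor at the R2 start."""
    for adaptor, cell in adaptors.items():
        if r2_seq.startswith(adaptor):
            return cell
    return None


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path,
                      adaptors: Optional[dict[str, str]] = None) -> Iterator[ReadPair]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(FastqGeneralIterator(f1),
                                                FastqGeneralIterator(f2)):
            rid = id1.split()[0]
            if rid != id2.split()[0]:
                raise ValueError(f"unsynchronised FASTQ mates: {id1} vs {id2}")
            cell = "cell0"
            if adaptors is not None:
                cell = assign_cell(s2.upper(), adaptors) or "unassigned"
            yield ReadPair(rid, s1.upper(), s2.upper(), q1, q2, cell)


def write_classified(classified: Iterable[ClassifiedRead], out_dir: str | Path,
                     prefix: str = "reads") -> dict[str, int]:
    """Write one FASTQ pair per retained class plus a classification log.

    Returns per-label counts.  Suffixes: ``.cap4G``, ``.cap3G``, ``.tail``,
    ``.other`` (discards are logged but not written as FASTQ)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = {ReadClassLabel.CAP_4G: "cap4G", ReadClassLabel.CAP_3G: "cap3G",
              ReadClassLabel.TAIL: "tail", ReadClassLabel.OTHER: "other"}
    handles: dict[str, tuple[TextIO, TextIO]] = {}
    counts: dict[str, int] = {label.value: 0 for label in ReadClassLabel}
    log_path = out_dir / f"{prefix}.classes.tsv"
    try:
        with open(log_path, "w") as log:
            log.write("read_id\tcell_id\tlabel\tn_leading_g\ttail_prefix_len"
                      "\tr1_trailing_a\n")
            for rec in classified:
                counts[rec.label.value] += 1
                pl = "" if rec.tail_prefix_len is None else str(rec.tail_prefix_len)
                log.write(f"{rec.pair.read_id}\t{rec.pair.cell_id}\t{rec.label.value}"
                          f"\t{rec.n_leading_g}\t{pl}\t{rec.r1_trailing_a}\n")
                sfx = suffix.get(rec.label)
                if sfx is None:
                    continue
                if sfx not in handles:
                    handles[sfx] = (open(out_dir / f"{prefix}.{sfx}.R1.fastq", "w"),
                                    open(out_dir / f"{prefix}.{sfx}.R2.fastq", "w"))
                h1, h2 = handles[sfx]
                p = rec.pair
                h1.write(f"@{p.read_id}\n{p.r1_seq}\n+\n{p.r1_qual}\n")
                h2.write(f"@{p.read_id}\n{p.r2_seq}\n+\n{p.r2_qual}\n")
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()
    return counts


def read_class_log(path: str | Path) -> dict[str, dict]:
    """Load a classification log as ``read_id -> record`` (label, cell,
    n_leading_g, tail_prefix_len)."""
    out: dict[str, dict] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[f[idx["read_id"]]] = {
                "cell_id": f[idx["cell_id"]],
                "label": f[idx["label"]],
                "n_leading_g": int(f[idx["n_leading_g"]]),
                "tail_prefix_len": int(f[idx["tail_prefix_len"]])
                if f[idx["tail_prefix_len"]] else None,
                "r1_trailing_a": int(f[idx["r1_trailing_a"]])
                if "r1_trailing_a" in idx and f[idx["r1_trailing_a"]] else 0,
            }
    return out
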