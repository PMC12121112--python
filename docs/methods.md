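# Methods

This note documents the models and conventions behind `c2t`: what each
stage computes, why the defaults are what they are, what the synthetic
generator does and does not emulate, and the numerical choices a user or
reviewer would want stated explicitly.

## Library model

The library design assumed throughout: RNA is fragmented (~200 nt), a
cell-indexed DNA adaptor is ligated to every fragment 3′ end, and reverse
transcription with a template-switching oligo (TSO) appends non-templated G
to every cDNA 5′ end. Consequences the pipeline relies on:

* every read-1 begins with a run of G — strictly three for hydroxyl 5′ ends
  (uncapped termini and all fragment-internal ends), four or more for a
  substantial fraction of m7G-capped ends;
* every read-2 begins with the observed (reverse-complement) adaptor of its
  cell, 7–12 nt;
* fragments spanning the poly(A) tail put the tail on read-2 as
  `adaptor + A-block (uridylation) + T-run (poly(A))`, and on read-1 as a
  trailing A run after the genomic anchor.

## Read classification (`c2t.readclass`)

Order of precedence: tail detection on the tail mate, read-through and
length filters for tail candidates, then the cap-prefix rule. The rules:

* cap prefix: `[GN]{4,}` → `CAP_4G`; `[GN]{3}[ATC]` → `CAP_3G`; anything
  else is discarded under the single-cell protocol. N counts as G (the
  template-switch bases are read with degenerate quality) but never as T in
  the tail run.
* tail prefix: the smallest `p ∈ [7, 12]` with five consecutive T at
  position `p`. The regex is ambiguous for T-rich prefixes; smallest-p is
  the deterministic tie-break. When the per-cell adaptor is known (sample
  sheet), its true length overrides the regex-detected prefix downstream,
  because the regex absorbs any uridylation A-block into the prefix.
* read-through: mates are merged by reverse-complement overlap (≥ 20 nt at
  ≥ 95 % identity; the mismatch budget is checked with early exit). A tail
  candidate whose merged insert is < 300 bp is discarded — fragmentation may
  have occurred inside the poly(A), making the T count unreliable. Note
  that A-dominated pairs (fragments broken inside the tail) merge at a
  spuriously short insert through poly(A) self-similarity; this is the
  artifact the filter is designed to catch, not a defect of the merger.
* poly(A) trimming of tail read-1: cut at the leftmost A-run ≥ 9 nt
  (cutadapt-style adapter semantics) or else strip the maximal terminal A
  run; discard when < 18 nt remain. The trim is idempotent. The count of A
  immediately after the trimmed part is logged: a run ≥ 5 marks the
  alignment end as *tail-adjacent* (abutting the poly(A)), which later
  gates exact polyadenylation positions.
* deduplication: the protocol has no UMIs, so presumed PCR duplicates are
  collapsed per `(cell, read-1 30-mer prefix, read-2 30-mer prefix)`, first
  occurrence winning. This is a heuristic: distinct molecules can share the
  key (e.g. tail reads of one gene in a narrow fragment-length regime).
  Synthetic libraries contain no PCR duplicates, so truth-level evaluations
  run with deduplication off; the default pipeline keeps it on, as real
  data requires.

Mate orientation is configurable (`ProtocolProfile`): the single-cell
protocol reads the cap prefix on R1 and the tail on R2; the total-RNA kit
variant reads the cap prefix on R2. A configurable 5′ hard trim is exposed
(default 0) for aligners that do not soft-clip the TSO G run.

## Cap calling (`c2t.capcall`)

A cap-signature alignment carries a terminal soft clip on its transcript-5′
end whose bases are exclusively G/N in transcript orientation (equivalently
C/N at the stored-sequence end of reverse-strand alignments), adjacent to a
matched block of ≥ 10 nt. The cap site is the 5′-most templated base
(strand-aware). Sites keep counts split by read subset (3G/4G) and
IP fraction.

Site-support policy: the default `drop_4g_only` removes sites seen only in
the 4G subset; `require_both` and `any` are provided. The default follows
the stated filtering rule of the upstream protocol literally even though
4G support is the cap-specific signal; the policy is a parameter precisely
because the choice is debatable.

### Maximal-density clustering

Cap peaks are the laminar cluster family produced by recursive
weakest-edge splitting of the single-base site list (per chrom/strand),
the construction underlying Paraclu-style tag clustering. For a segment of
sites, each terminal piece (proper prefix or suffix) has a *critical
density* `total(piece) / span`, where the span runs to the nearest
retained site — gap-inclusive, which is what makes dropping an isolated
distant site cheaper than cutting inside a dense pile. The segment is
reported as a cluster over the density interval between the density at
which it formed (its parent's break) and its own weakest critical density;
recursion continues on both sides of the break. Ties are broken
deterministically: prefix pieces before suffix pieces, shorter pieces
first. All density comparisons use exact rationals; the test suite checks
the family against an independent naive recomputation and verifies
laminarity.

Post-filters (the canonical ones, since the upstream description names no
values): total count ≥ 10, length ≤ 200 nt, max/min density fold ≥ 2, and
a simplification step that keeps only the outermost surviving cluster of
each nested chain, so reported peaks are disjoint.

### m6Am

For an IP experiment, cap reads of input, IP, and supernatant are merged
for peak identification; the supernatant is carried for QC only. A peak is
an m6Am candidate when its dominant (highest-count) site has first
templated base A. The Am level per fraction is `log2(CPM + 1)` of the
peak's m7GpppA reads (cap-signature reads whose first templated base is A),
normalised by the fraction's total aligned reads; the call is
`Am(IP) − Am(input) > 0.5`. The metric is a package choice — the upstream
description gives the cutoff but not the units — and the pseudocount keeps
empty peaks finite. At gene level, each 5′ end is represented by its
dominant cluster: when clustering strands a low-count splinter one
nucleotide from a dominant peak, the splinter is not independent evidence;
genuinely distinct peaks (alternative TSSs) still count separately.

## Tail and APA calling (`c2t.tailcall`)

Poly(A) length per read: after masking the 3′-terminal run of bases below
Q20, skip the adaptor prefix and any A-block, then count the T-run. Up to
two isolated non-T bases are tolerated when flanked by ≥ 3 T on both sides
(isolated substitution errors); interruptions are excluded from the count,
and the run ends at the first disqualifying base. Runs shorter than 5 are
rejected; runs reaching the usable read end are censored (the true tail
may exceed the read capacity — the motivation for sequencing poly(A)
libraries at PE150/PE250). The interruption rule is a package choice: the
"base content" criterion it implements is not specified upstream.
Uridylation is an A-block of ≥ 2 nt between adaptor and T-run; a 1 nt
block is skipped for length purposes but not called.

APA peaks: each tail read-1 mapping record is extended ±100 nt (the
extension size is a package default; the upstream description extends
records symmetrically without giving a size) and per-base coverage is
tested against `Poisson(max(genome-wide rate, local 10 kb rate))` at
p < 0.05, standing in for a MACS2 `--nomodel -p 0.05` run without the
external binary. Maximal significant runs shorter than 500 bp are ignored,
then peaks with RPKM ≤ 2 are removed, RPKM = reads × 10⁹ / (length ×
library size) with the library size equal to the number of measured tail
reads (the normalising denominator is unspecified upstream). The 500 bp
rule is interpreted as peak *width*; both thresholds are parameters.

Reads are assigned to peaks by their genomic anchor — the alignment end
adjacent to the tail — replacing a multiple-sequence-realignment step with
a deterministic rule that is exact for reads whose read-1 actually reaches
the tail (the tail-adjacent flag). Only tail-adjacent anchors become a
peak's polyadenylation positions; the APA window is their max − min, so
anchors of reads that stop short of the tail contribute coverage but never
window. Length summaries report n, median, and mean per peak and per gene
(read-weighted), with censored reads counted but excluded from the
statistics and censored-only groups flagged.

## Quantification (`c2t.quant`)

Reads are assigned to genes by strand-aware maximal exon overlap
(ties: longest overlap, then lexicographic gene id). The cap matrix counts
cap-signature reads whose site falls inside a called cap peak; gene-body
counts the remaining aligned non-tail reads; the tail matrix counts
measured tail reads via their anchor's gene. Restricting the cap class to
called peaks (rather than any soft-clipped read) reflects that in this
protocol every fragment end carries a G run, so the soft-clip alone does
not distinguish a capped 5′ terminus from an internal fragment end.

CPM is computed within each feature class per cell (the classes are
compared as separate data sets); a global-denominator mode and pseudo-bulk
aggregation (summing cells before CPM) are provided. Scores use a
pseudocount of 1 on both numerator and denominator — the bare ratios are
undefined at zero. Only primary alignments are counted.

## Synthetic experiments (`c2t.sim`)

The generator emulates the library model above with full per-molecule
truth. Defaults define the reference experiment: 300 genes × 4 cells,
~14 molecules per gene per cell (≈50 k read pairs), PE250, 0.5 %
substitution errors, seed 42. Per gene: single-exon transcripts of
1.6–2.6 kb on 4 chromosomes with 5 kb intergenic spacing (so the 10 kb
local background of the peak caller is not dominated by neighbouring
genes); cap probability 0.85, with 10 % cap-poor genes (cap probability
0.05) and 10 % poly(A)-minus genes emulating histone-like transcripts;
15 % m6Am genes (forced to start with A); 30 % of genes carry a second
polyadenylation site 800–1,100 nt upstream at 0.3 weight; cleavage jitter
uniform on a per-gene window of 0–10 nt; poly(A) lengths normal(65, 15)
truncated to [20, 143] nt, 10 % uridylated transcripts with geometric
(p = 0.5) U-tails and 0.6× shorter poly(A); TSS micro-heterogeneity of
≤ 1 nt (80 % canonical, 20 % +1). G counts: capped
{3: 0.75, 4: 0.15, 5: 0.07, ≥6: 0.03} — so > 20 % of capped molecules gain
more than three G — and uncapped {3: 0.98, 4: 0.02}. The m6Am experiment
simulates input/IP/supernatant with capped molecules of m6Am genes
enriched ×4 in the IP and depleted ×4 in the supernatant, at a depth
giving ≥ 100 cap-A reads per gene per fraction (comfortably above the
50-read regime where the 0.5 cutoff is statistically marginal under the
null).

Deliberate identifiability constraints, so that ground truth is
recoverable exactly: transcript bodies never contain A-runs ≥ 5 (no
internal oligo(dT)-like T-runs in reverse-complemented reads), cleavage
windows and their 2 nt margin are A-free (the estimator cannot distinguish
templated terminal A from the tail — real data has this ambiguity; the
generator removes it so exactness is testable), transcripts never start
with G, and cell adaptors are T-free and unique in their first 7 nt.
Errors are substitutions only (truth alignments stay exact); PCR
amplification, base-quality profiles, indels, and internal priming are not
modelled. Passing tests therefore demonstrate correctness of the
algorithms under the stated library model, not robustness to artifacts the
generator excludes.

The generator writes a truth SAM (leading G and trailing tail bases as
soft clips, poly(A)-trimmed tail read-1 records) so the pipeline runs
without an aligner; FASTQ output allows end-to-end runs with a real
aligner. All randomness derives from a single seed through named
SeedSequence streams; outputs are byte-reproducible.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on simulation:
the reference experiment (~50 k pairs) twice for determinism, the IP pair
of experiments (~75 k molecules each), the tail-recovery runs (~15 k tail
reads), a window sweep over jitter widths {0, 5, 10, 40} (the W = 40 sweep
uses ~8 reads per candidate position so both extremes are sampled), 200
random clustering instances against the exact oracle, and the exhaustive
5⁶ prefix enumeration. The window sweep relaxes the peak-width floor to
300 bp because its narrow fragment geometry (chosen so nearly every read
is tail-adjacent) cannot produce 500 bp footprints; the width filter
itself is tested separately at its default.

## Known limitations

* The cap/non-cap split leans on called cap peaks; genes whose TSS peak
  fails the count filter have their 5′ reads counted as gene body.
* Tail lengths are right-censored by read length; summaries exclude
  censored reads rather than modelling the censoring.
* The read-through filter discards short-insert tail fragments, biasing
  retained tail reads toward longer inserts (and, weakly, longer tails) —
  a property of the protocol's own filter, visible in the simulation.
* The deduplication key can collapse distinct molecules at high per-gene
  depth; with UMI-free chemistry this is unavoidable.
* m6Am calling assumes the IP fraction's composition shift is captured by
  total-read normalisation; strong global enrichment would call for spike-in
  normalisation, which is out of scope.
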