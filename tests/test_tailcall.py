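"""Tests for poly(A) tail measurement, uridylation, and APA peak calling."""

import numpy as np
import pytest
from scipy.stats import poisson

from c2t.tailcall import (APAPeak, PeakCallerParams, TailParams, TailRead,
                          apa_window, call_apa_peaks, detect_u_tail,
                          match_reference_apa, polya_length_from_r2,
                          summarize_tail_lengths, usable_length)

Q = "I"  # Phred 40


def _measure(seq, prefix_len=8, qual=None, **kw):
    qual = qual if qual is not None else Q * len(seq)
    return polya_length_from_r2(seq, qual, prefix_len, TailParams(**kw))


class TestPolyALength:
    prefix = "ACGTACGA"  # 8 nt

    def test_clean_run(self):
        m = _measure(self.prefix + "T" * 30 + "GCGCGCGC")
        assert m.polya_len == 30 and not m.censored and not m.u_tail

    def test_single_interruption_tolerated_and_excluded(self):
        m = _measure(self.prefix + "T" * 12 + "C" + "T" * 12 + "GCGC")
        assert m.polya_len == 24 and not m.censored

    def test_run_to_read_end_is_censored(self):
        m = _measure(self.prefix + "T" * 40)
        assert m.polya_len == 40 and m.censored

    def test_low_quality_tail_is_masked(self):
        seq = self.prefix + "T" * 30 + "GCGC"
        qual = Q * (8 + 20) + "#" * (len(seq) - 28)  # 3' end below Q20
        assert usable_length(qual) == 28
        m = polya_length_from_r2(seq, qual, 8, TailParams())
        assert m.polya_len == 20 and m.censored

    def test_short_run_rejected(self):
        assert _measure(self.prefix + "TTT" + "GCGC") is None

    def test_interruption_budget_is_finite(self):
        seq = self.prefix + ("T" * 6 + "C") * 3 + "T" * 6 + "GC"
        m = _measure(seq)
        # two interruptions allowed, the third terminates the run
        assert m.polya_len == 18 and not m.censored

    def test_unflanked_interruption_terminates(self):
        m = _measure(self.prefix + "T" * 10 + "CA" + "T" * 10)
        assert m.polya_len == 10


class TestUTail:
    def test_u_block_detected_and_skipped(self):
        seq = "ACGTACGA" + "AA" + "T" * 25 + "GCGC"
        assert detect_u_tail(seq, 8) == (True, 2)
        m = _measure(seq)
        assert m.u_tail and m.u_len == 2 and m.polya_len == 25
        assert m.t_run_start == 10

    def test_single_a_below_threshold(self):
        seq = "ACGTACGA" + "A" + "T" * 25 + "GCGC"
        assert detect_u_tail(seq, 8) == (False, 0)
        m = _measure(seq)
        assert not m.u_tail and m.u_len == 0 and m.polya_len == 25

    def test_no_a_block(self):
        assert detect_u_tail("ACGTACGA" + "T" * 25, 8) == (False, 0)


class TestApaWindow:
    def _peak(self, sites):
        return APAPeak("p", "chr1", "+", 0, 1000, len(sites), 10.0,
                       tail_sites=list(sites))

    def test_spread(self):
        assert apa_window(self._peak([1000, 1003, 1009])) == 9

    def test_single_site(self):
        assert apa_window(self._peak([1000])) == 0

    def test_upper_range(self):
        assert apa_window(self._peak([2000, 2040])) == 40

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            apa_window(self._peak([]))


def _tail_read(chrom, strand, anchor, aln_len=200, adjacent=True, rid=None):
    return TailRead(read_id=rid or f"t{anchor}", cell_id="cell0", chrom=chrom,
                    strand=strand, anchor_pos=anchor, polya_len=60,
                    censored=False, u_tail=False, u_len=0,
                    tail_adjacent=adjacent, aln_start=anchor - aln_len,
                    aln_end=anchor)


class TestPeakCaller:
    lengths = {"chr1": 20000}

    def test_focal_pileup_forms_one_peak(self):
        rng = np.random.default_rng(0)
        reads = [_tail_read("chr1", "+", int(a), aln_len=300, rid=f"r{i}")
                 for i, a in enumerate(10000 + rng.integers(0, 50, size=50))]
        peaks = call_apa_peaks(reads, self.lengths, PeakCallerParams())
        assert len(peaks) == 1
        peak = peaks[0]
        assert len(peak) >= 500 and peak.read_count == 50
        assert all(r.apa_peak_id == peak.id for r in reads)

    def test_uniform_scatter_yields_no_peaks(self):
        rng = np.random.default_rng(1)
        reads = [_tail_read("chr1", "+", int(a), aln_len=50, rid=f"r{i}")
                 for i, a in enumerate(
                     np.sort(rng.choice(np.arange(100, 19900), 60,
                                        replace=False)))]
        peaks = call_apa_peaks(reads, self.lengths,
                               PeakCallerParams(local_bg_window=19000))
        assert peaks == []

    def test_narrow_enrichment_removed_by_length_filter(self):
        reads = [_tail_read("chr1", "+", 10000, aln_len=40, rid=f"r{i}")
                 for i in range(50)]
        # footprint = 40 + 2 x 100 = 240 < 500
        assert call_apa_peaks(reads, self.lengths, PeakCallerParams()) == []
        relaxed = PeakCallerParams(min_peak_len=200)
        assert len(call_apa_peaks(reads, self.lengths, relaxed)) == 1

    def test_rpkm_filter(self):
        rng = np.random.default_rng(2)
        reads = [_tail_read("chr1", "+", int(a), aln_len=300, rid=f"r{i}")
                 for i, a in enumerate(10000 + rng.integers(0, 50, size=50))]
        kept = call_apa_peaks(reads, self.lengths, PeakCallerParams(),
                              library_size=50)
        assert len(kept) == 1
        # rpkm = 50e9 / (len x lib): make the library huge so rpkm <= 2
        gone = call_apa_peaks(reads, self.lengths, PeakCallerParams(),
                              library_size=4 * 10 ** 10)
        assert gone == []

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(3)
        reads = []
        for j, centre in enumerate((3000, 8000, 15000)):
            for i in range(20 + 10 * j):
                reads.append(_tail_read("chr1", "+",
                                        centre + int(rng.integers(0, 60)),
                                        rid=f"r{j}_{i}"))
        base = PeakCallerParams(min_peak_len=100, min_rpkm=0.1)
        n0 = len(call_apa_peaks(reads, self.lengths, base))
        for mpl in (200, 400, 600, 800):
            n = len(call_apa_peaks(reads, self.lengths,
                                   PeakCallerParams(min_peak_len=mpl,
                                                    min_rpkm=0.1)))
            assert n <= n0
            n0 = n
        n0 = len(call_apa_peaks(reads, self.lengths, base))
        for rpkm in (1.0, 10.0, 100.0, 10 ** 5):
            n = len(call_apa_peaks(reads, self.lengths,
                                   PeakCallerParams(min_peak_len=100,
                                                    min_rpkm=rpkm)))
            assert n <= n0
            n0 = n

    def test_matches_naive_per_base_scan(self):
        """Peak intervals equal an independent per-base Poisson threshold
        scan on small instances."""
        params = PeakCallerParams(extension=20, pvalue=0.05, min_peak_len=30,
                                  min_rpkm=0.5, local_bg_window=400)
        rng = np.random.default_rng(4)
        for trial in range(15):
            L = int(rng.integers(1000, 5000))
            lengths = {"c": L}
            n = int(rng.integers(5, 60))
            reads = []
            for i in range(n):
                a = int(rng.integers(100, L - 100))
                reads.append(_tail_read("c", "+", a,
                                        aln_len=int(rng.integers(20, 80)),
                                        rid=f"r{trial}_{i}"))
            got = [(p.start, p.end) for p in
                   call_apa_peaks(reads, lengths, params, library_size=n)]
            exp = self._naive(reads, L, params, n)
            assert got == exp

    @staticmethod
    def _naive(reads, L, params, library_size):
        cov = [0] * L
        for r in reads:
            for b in range(max(0, r.aln_start - params.extension),
                           min(L, r.aln_end + params.extension)):
                cov[b] += 1
        mass = sum((r.aln_end - r.aln_start) + 2 * params.extension
                   for r in reads)
        bg = mass / L
        half = params.local_bg_window // 2
        sig = []
        for b in range(L):
            lo, hi = max(0, b - half), min(L, b + half + 1)
            lam = max(bg, sum(cov[lo:hi]) / (hi - lo), 1e-12)
            sig.append(cov[b] > 0
                       and poisson.sf(cov[b] - 1, lam) < params.pvalue)
        peaks, b = [], 0
        while b < L:
            if sig[b]:
                e = b
                while e < L and sig[e]:
                    e += 1
                if e - b >= params.min_peak_len:
                    count = sum(1 for r in reads
                                if b <= r.anchor_pos - 1 < e)
                    rpkm = count * 1e9 / ((e - b) * library_size)
                    if rpkm > params.min_rpkm:
                        peaks.append((b, e))
                b = e
            else:
                b += 1
        return peaks

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(ValueError):
            PeakCallerParams(pvalue=1.5)


class TestSummaries:
    def _reads(self, lens, censored=None, peak="p1", gene="g1"):
        censored = censored or [False] * len(lens)
        return [TailRead(read_id=f"r{i}", cell_id="c", chrom="chr1",
                         strand="+", anchor_pos=100, polya_len=ln,
                         censored=cs, u_tail=False, u_len=0,
                         tail_adjacent=True, apa_peak_id=peak, gene_id=gene)
                for i, (ln, cs) in enumerate(zip(lens, censored))]

    def test_median_and_mean(self):
        per_peak, per_gene = summarize_tail_lengths(self._reads([10, 20, 30]))
        assert per_peak.loc["p1", "median"] == 20
        assert per_peak.loc["p1", "mean"] == 20
        assert per_gene.loc["g1", "n"] == 3

    def test_skewed_lengths(self):
        per_peak, _ = summarize_tail_lengths(self._reads([10, 20, 30, 100]))
        assert per_peak.loc["p1", "median"] == 25
        assert per_peak.loc["p1", "mean"] == 40

    def test_censored_counted_but_excluded(self):
        per_peak, _ = summarize_tail_lengths(
            self._reads([10, 20, 99], censored=[False, False, True]))
        assert per_peak.loc["p1", "n"] == 3
        assert per_peak.loc["p1", "n_censored"] == 1
        assert per_peak.loc["p1", "median"] == 15

    def test_censored_only_group_flagged(self):
        per_peak, _ = summarize_tail_lengths(
            self._reads([99, 99], censored=[True, True]))
        assert bool(per_peak.loc["p1", "censored_only"])
        assert np.isnan(per_peak.loc["p1", "median"])


class TestReferenceMatch:
    def _peak(self, site, pid="p1"):
        return APAPeak(pid, "chr1", "+", site - 600, site + 10, 30, 10.0,
                       tail_sites=[site])

    def test_within_flank_is_known(self):
        out = match_reference_apa([self._peak(10050)],
                                  [("chr1", 10000, "+")], flank=100)
        assert out == {"p1": True}

    def test_distant_reference_is_novel(self):
        out = match_reference_apa([self._peak(10500)],
                                  [("chr1", 10000, "+")], flank=100)
        assert out == {"p1": False}

    def test_zero_flank_exact_match(self):
        out = match_reference_apa([self._peak(10000)],
                                  [("chr1", 10000, "+")], flank=0)
        assert out == {"p1": True}

    def test_strand_must_agree(self):
        out = match_reference_apa([self._peak(10000)],
                                  [("chr1", 10000, "-")], flank=100)
        assert out == {"p1": False}
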