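"""Tests for cap-read extraction, cap-site pileup, maximal-density
clustering, and m6Am calling."""

import math

import numpy as np
import pytest

from c2t.capcall import (AlignedRead, CapCluster, CapSite, CapSupportPolicy,
                         ParacluParams, call_m6am, cap_site_position,
                         cluster_cap_sites, filter_cap_sites,
                         first_templated_base, is_cap_alignment,
                         m7gpppa_counts, paraclu, paraclu_cluster,
                         pile_cap_sites, reference_base)


def _read(pos, cigar, seq, strand="+", chrom="chr1", subset="cap3G",
          fraction="none", read_id="r"):
    return AlignedRead(read_id, chrom, pos, strand, cigar, seq,
                       subset, fraction)


class TestCapAlignment:
    def test_forward_g_clip_qualifies(self):
        r = _read(100, [(4, "S"), (96, "M")], "GGGG" + "A" * 96)
        assert is_cap_alignment(r) == (True, 4)

    def test_reverse_stored_c_clip_qualifies(self):
        r = _read(100, [(96, "M"), (4, "S")], "A" * 96 + "CCCC", strand="-")
        assert is_cap_alignment(r) == (True, 4)

    def test_no_soft_clip(self):
        r = _read(100, [(100, "M")], "A" * 100)
        assert is_cap_alignment(r) == (False, 0)

    def test_mixed_clip_bases_rejected(self):
        r = _read(100, [(4, "S"), (96, "M")], "GAGG" + "A" * 96)
        assert is_cap_alignment(r) == (False, 0)
        rev = _read(100, [(96, "M"), (4, "S")], "A" * 96 + "CACC", strand="-")
        assert is_cap_alignment(rev) == (False, 0)

    def test_n_allowed_in_clip(self):
        r = _read(100, [(3, "S"), (50, "M")], "GNG" + "A" * 50)
        assert is_cap_alignment(r) == (True, 3)

    def test_hard_clip_and_short_match_rejected(self):
        r = _read(100, [(4, "H"), (96, "M")], "A" * 96)
        assert is_cap_alignment(r) == (False, 0)
        short = _read(100, [(4, "S"), (5, "M")], "GGGG" + "A" * 5)
        assert is_cap_alignment(short) == (False, 0)

    def test_wrong_end_clip_rejected(self):
        """A 3'-end clip is not a cap signature."""
        r = _read(100, [(96, "M"), (4, "S")], "A" * 96 + "GGGG")
        assert is_cap_alignment(r) == (False, 0)


class TestPileCapSites:
    def test_aggregation_and_strand_keys(self):
        reads = [_read(999, [(3, "S"), (50, "M")], "GGG" + "A" * 50,
                       read_id=f"r{i}") for i in range(3)]
        reads.append(_read(999, [(50, "M"), (3, "S")], "A" * 50 + "CCC",
                           strand="-", read_id="m"))
        sites = pile_cap_sites(reads)
        assert len(sites) == 2
        plus = next(s for s in sites if s.strand == "+")
        minus = next(s for s in sites if s.strand == "-")
        assert plus.pos == 1000 and plus.total == 3
        assert minus.pos == 999 + 50 and minus.total == 1

    def test_reverse_strand_coordinate_arithmetic(self):
        # 0-based pos 500, 46 aligned bases: 5'-most templated base at 1-based 546
        r = _read(500, [(46, "M"), (4, "S")], "A" * 46 + "CCCC", strand="-")
        assert cap_site_position(r) == 546
        [site] = pile_cap_sites([r])
        assert site.pos == 546

    def test_counts_split_by_subset_and_fraction(self):
        reads = [_read(10, [(3, "S"), (30, "M")], "GGG" + "A" * 30,
                       subset="cap3G", fraction="input", read_id="a"),
                 _read(10, [(4, "S"), (30, "M")], "GGGG" + "A" * 30,
                       subset="cap4G", fraction="IP", read_id="b")]
        [site] = pile_cap_sites(reads)
        assert site.counts == {("cap3G", "input"): 1, ("cap4G", "IP"): 1}


class TestFilterPolicies:
    @staticmethod
    def _site(n3, n4):
        s = CapSite("chr1", "+", 100)
        if n3:
            s.add("cap3G", "none", n3)
        if n4:
            s.add("cap4G", "none", n4)
        return s

    @pytest.mark.parametrize("n3,n4,policy,kept", [
        (5, 2, "drop_4g_only", True),
        (5, 2, "require_both", True),
        (5, 2, "any", True),
        (0, 7, "drop_4g_only", False),
        (0, 7, "any", True),
        (4, 0, "drop_4g_only", True),
        (4, 0, "require_both", False),
    ])
    def test_policy_table(self, n3, n4, policy, kept):
        out = filter_cap_sites([self._site(n3, n4)], CapSupportPolicy(policy))
        assert bool(out) is kept

    def test_policy_monotonicity(self):
        rng = np.random.default_rng(5)
        sites = [self._site(int(rng.integers(0, 4)), int(rng.integers(0, 4)))
                 for _ in range(50)]
        both = {id(s) for s in filter_cap_sites(sites, CapSupportPolicy.REQUIRE_BOTH)}
        drop = {id(s) for s in filter_cap_sites(sites, CapSupportPolicy.DROP_4G_ONLY)}
        anyp = {id(s) for s in filter_cap_sites(sites, CapSupportPolicy.ANY)}
        assert both <= drop <= anyp


class TestParaclu:
    def test_singleton(self):
        [c] = paraclu([(1000, 10)])
        assert (c["start"], c["end"], c["total"]) == (1000, 1000, 10)
        assert c["max_density"] is None

    def test_dense_pair_separates_from_isolated_site(self):
        out = paraclu_cluster([(10, 5), (11, 5), (500, 1)], min_count=2,
                              max_length=100, min_density_fold=1.0)
        spans = {(c["start"], c["end"]) for c in out}
        assert (10, 11) in spans
        assert all(not (s <= 500 <= e) or (s, e) == (500, 500)
                   for s, e in spans)

    def test_uniform_run_forms_single_cluster(self):
        sites = [(i, 1) for i in range(1, 21)]
        out = paraclu_cluster(sites, min_count=1, max_length=100,
                              min_density_fold=0.0)
        assert any(c["start"] == 1 and c["end"] == 20 for c in out)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            paraclu([(5, 1), (5, 2)])
        with pytest.raises(ValueError):
            paraclu([(5, 0)])
        assert paraclu([]) == []

    def test_count_conservation_with_filters_disabled(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 500), 40, replace=False))
        sites = [CapSite("chr1", "+", int(p)) for p in pos]
        for s in sites:
            s.add("cap3G", "none", int(rng.integers(1, 5)))
        total = sum(s.total for s in sites)
        free = ParacluParams(min_count=1, max_length=10 ** 9,
                             min_density_fold=0.0, simplify=True)
        clusters = cluster_cap_sites(sites, free)
        assert sum(c.total_count for c in clusters) == total
        strict = ParacluParams(min_count=3, max_length=100,
                               min_density_fold=2.0, simplify=True)
        assert sum(c.total_count for c in cluster_cap_sites(sites, strict)) <= total

    def test_laminarity_of_full_family(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(1, 25))
            pos = np.sort(rng.choice(np.arange(1, 150), n, replace=False))
            cnt = rng.integers(1, 4, size=n)
            fam = [(c["lo"], c["hi"]) for c in
                   paraclu([(int(p), int(c)) for p, c in zip(pos, cnt)])]
            for a in fam:
                for b in fam:
                    assert not (a[0] < b[0] < a[1] < b[1])

    def test_simplified_clusters_are_disjoint(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 300), 60, replace=False))
        sites = [CapSite("chr1", "+", int(p)) for p in pos]
        for s in sites:
            s.add("cap3G", "none", int(rng.integers(1, 6)))
        clusters = cluster_cap_sites(sites, ParacluParams(
            min_count=1, max_length=10 ** 9, min_density_fold=0.0))
        spans = sorted((c.start, c.end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestFirstBase:
    genome = {"chr1": "TTAGC"}

    def test_forward_lookup(self):
        assert reference_base(self.genome, "chr1", 3, "+") == "A"

    def test_reverse_complement_lookup(self):
        assert reference_base(self.genome, "chr1", 1, "-") == "A"

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            reference_base(self.genome, "chr1", 6, "+")

    def test_read_level_extraction(self):
        r = _read(2, [(3, "S"), (10, "M")], "GGG" + "A" * 10)
        genome = {"chr1": "TTAGC" + "G" * 10}
        assert first_templated_base(r, genome) == "A"

    def test_n_reference_excluded_from_m7gpppa(self):
        genome = {"chr1": "TTN" + "G" * 20}
        r = _read(2, [(3, "S"), (10, "M")], "GGG" + "A" * 10)
        cl = CapCluster("chr1", "+", 3, 3, 1, 0.0, 1.0,
                        member_sites=[CapSite("chr1", "+", 3)])
        counts = m7gpppa_counts([r], [cl], genome)
        assert counts[0] == {}


class TestM6AmCalling:
    @staticmethod
    def _cluster(first_base="A"):
        site = CapSite("chr1", "+", 100)
        site.add("cap3G", "input", 5)
        site.first_base = first_base
        cl = CapCluster("chr1", "+", 100, 100, 5, 0.0, 1.0,
                        member_sites=[site])
        cl.first_base = first_base
        return cl

    def test_enriched_cluster_called(self):
        cl = self._cluster()
        libs = {"IP": 10 ** 6, "input": 10 ** 6}
        calls = call_m6am([cl], {0: {"IP": 40, "input": 10}}, libs)
        [call] = calls
        assert math.isclose(call.am_ip, math.log2(41))
        assert math.isclose(call.am_input, math.log2(11))
        assert call.is_m6am and call.delta > 0.5

    def test_balanced_cluster_not_called(self):
        cl = self._cluster()
        libs = {"IP": 10 ** 6, "input": 10 ** 6}
        [call] = call_m6am([cl], {0: {"IP": 20, "input": 20}}, libs)
        assert call.delta == 0.0 and not call.is_m6am

    def test_non_a_first_base_excluded(self):
        cl = self._cluster(first_base="G")
        libs = {"IP": 10 ** 6, "input": 10 ** 6}
        assert call_m6am([cl], {0: {"IP": 100, "input": 0}}, libs) == []

    def test_zero_library_size_is_an_error(self):
        cl = self._cluster()
        with pytest.raises(ValueError):
            call_m6am([cl], {0: {}}, {"IP": 0, "input": 10})

    def test_library_normalisation_enters_delta(self):
        """Same counts, four-fold larger IP library: enrichment vanishes."""
        cl = self._cluster()
        calls = call_m6am([cl], {0: {"IP": 40, "input": 10}},
                          {"IP": 4 * 10 ** 6, "input": 10 ** 6})
        assert math.isclose(calls[0].delta, 0.0, abs_tol=1e-12)
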