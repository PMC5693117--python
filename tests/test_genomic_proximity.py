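"""Interval procedures vs brute-force oracles and worked examples."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from samdyn import (closest_motif_distance, distance_histogram_compare,
                    hypergeometric_enrichment, intersect_replicates,
                    shared_binding, summit_regions, upstream_fraction)
from samdyn.genomic import gap_distance, merge_intervals


def _df(rows, columns=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(columns))


def _random_intervals(rng, n, length_hi=60, span=10_000, chroms=("chr1",)):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span, size=n)
    length = rng.integers(1, length_hi, size=n)
    return _df(list(zip(chrom, start, start + length)))


class TestSummitRegions:
    def test_direct_construction(self):
        peaks = _df([("chr1", 400, 700, 500)],
                    columns=("chrom", "start", "end", "summit"))
        out = summit_regions(peaks)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (400, 600)

    def test_clipping_at_chromosome_start(self):
        peaks = _df([("chr1", 0, 200, 40)],
                    columns=("chrom", "start", "end", "summit"))
        out = summit_regions(peaks)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 140)

    def test_width_200_when_unclipped(self, rng):
        s = rng.integers(150, 9000, size=50)
        peaks = _df(list(zip(["chr1"] * 50, s - 20, s + 20, s)),
                    columns=("chrom", "start", "end", "summit"))
        out = summit_regions(peaks)
        assert ((out["end"] - out["start"]) == 200).all()

    def test_missing_summit_is_an_error(self):
        with pytest.raises(ValueError, match="summit"):
            summit_regions(_df([("chr1", 0, 100)]))


class TestIntersectReplicates:
    def test_basic_overlap(self):
        out = intersect_replicates(_df([("chr1", 100, 300)]),
                                   _df([("chr1", 200, 400)]))
        assert out.values.tolist() == [["chr1", 200, 300]]

    def test_disjoint_sets_empty(self):
        out = intersect_replicates(_df([("chr1", 0, 100)]),
                                   _df([("chr1", 500, 600)]))
        assert len(out) == 0

    def test_matches_bruteforce_all_pairs(self, rng):
        a = _random_intervals(rng, 100, chroms=("chr1", "chr2"))
        b = _random_intervals(rng, 100, chroms=("chr1", "chr2"))
        got = intersect_replicates(a, b)
        # oracle: every base covered by both sets, merged per locus
        covered = set()
        for _, ra in a.iterrows():
            for _, rb in b.iterrows():
                if ra["chrom"] != rb["chrom"]:
                    continue
                lo = max(ra["start"], rb["start"])
                hi = min(ra["end"], rb["end"])
                covered.update((ra["chrom"], x) for x in range(lo, hi))
        got_bases = set()
        for _, r in got.iterrows():
            got_bases.update((r["chrom"], x)
                             for x in range(r["start"], r["end"]))
        assert got_bases == covered
        # merged: no adjacent/overlapping output intervals per chromosome
        for _, grp in got.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert np.all(starts[1:] > ends[:-1])


class TestSharedBinding:
    def _summits(self, positions):
        return _df([("chr1", p - 25, p + 25, p) for p in positions],
                   columns=("chrom", "start", "end", "summit"))

    @pytest.mark.parametrize("dist,expected", [
        (0, True),     # identical summits: full overlap
        (5, True),     # 45/50 bp overlap
        (10, True),    # 40/50 bp = exactly 80%
        (11, False),   # 39/50 bp
    ])
    def test_overlap_rule(self, dist, expected):
        a = self._summits([1000])
        b = self._summits([1000 + dist])
        assert shared_binding(a, b).iloc[0] == expected

    def test_symmetric_on_random_fixtures(self, rng):
        pa = rng.integers(100, 5000, size=60)
        pb = rng.integers(100, 5000, size=60)
        a, b = self._summits(pa), self._summits(pb)
        ab = shared_binding(a, b)
        ba = shared_binding(b, a)
        # flags need not match element-wise, but existence of a shared
        # partner is symmetric: A has any shared region iff B does
        assert ab.any() == ba.any()
        # brute-force oracle for the A-side flags
        for i, p in enumerate(pa):
            assert ab.iloc[i] == (np.abs(pb - p) <= 10).any()


class TestClosestMotifDistance:
    OPEN_ALL = _df([("chr1", 0, 10_000_000), ("chr2", 0, 10_000_000)])

    def test_gap_example(self):
        g = _df([("chr1", 100, 106)])
        a = _df([("chr1", 150, 156)])
        d = closest_motif_distance(g, a, self.OPEN_ALL)
        assert d.iloc[0] == 44

    def test_overlap_is_zero(self):
        g = _df([("chr1", 100, 106)])
        a = _df([("chr1", 103, 109)])
        assert closest_motif_distance(g, a, self.OPEN_ALL).iloc[0] == 0

    def test_no_are_on_chromosome_missing(self):
        g = _df([("chr1", 100, 106)])
        a = _df([("chr2", 100, 106)])
        assert closest_motif_distance(g, a, self.OPEN_ALL).isna().iloc[0]

    def test_closed_chromatin_filters_motifs(self):
        open_chrom = _df([("chr1", 0, 200)])
        g = _df([("chr1", 100, 106), ("chr1", 300, 306)])
        a = _df([("chr1", 150, 156), ("chr1", 310, 316)])
        d = closest_motif_distance(g, a, open_chrom)
        assert d.iloc[0] == 44          # the closed ARE at 310 is discarded
        assert d.isna().iloc[1]         # closed G-box is discarded

    def test_matches_bruteforce_scan(self, rng):
        g = _random_intervals(rng, 500, length_hi=8, span=50_000,
                              chroms=("chr1", "chr2"))
        a = _random_intervals(rng, 500, length_hi=8, span=50_000,
                              chroms=("chr1", "chr2"))
        got = closest_motif_distance(g, a, self.OPEN_ALL)
        for i, rg in g.iterrows():
            best = math.inf
            for _, ra in a.iterrows():
                if ra["chrom"] != rg["chrom"]:
                    continue
                best = min(best, gap_distance(rg["start"], rg["end"],
                                              ra["start"], ra["end"]))
            if math.isinf(best):
                assert got.isna().iloc[i]
            else:
                assert got.iloc[i] == best

    def test_translation_and_renaming_invariance(self, rng):
        g = _random_intervals(rng, 80, length_hi=8, span=20_000)
        a = _random_intervals(rng, 80, length_hi=8, span=20_000)
        d1 = closest_motif_distance(g, a, self.OPEN_ALL)
        shift = 1_000
        g2 = g.assign(chrom="chrX", start=g["start"] + shift,
                      end=g["end"] + shift)
        a2 = a.assign(chrom="chrX", start=a["start"] + shift,
                      end=a["end"] + shift)
        open2 = _df([("chrX", 0, 10_000_000)])
        d2 = closest_motif_distance(g2, a2, open2)
        assert np.array_equal(d1.to_numpy(float), d2.to_numpy(float),
                              equal_nan=True)


class TestDistanceHistogram:
    def test_frequencies_sum_to_one_and_modal_bins(self, rng):
        near = rng.integers(0, 50, size=200)
        far = rng.integers(400, 450, size=200)
        out = distance_histogram_compare(near, far)
        assert out["freq_peaks"].sum() == pytest.approx(1.0)
        assert out["freq_background"].sum() == pytest.approx(1.0)
        assert out["modal_bin_peaks"] == (0, 50)
        assert out["modal_bin_background"] == (400, 450)

    def test_identical_inputs_identical_histograms(self, rng):
        d = rng.integers(0, 300, size=100)
        out = distance_histogram_compare(d, d)
        assert np.array_equal(out["freq_peaks"], out["freq_background"])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            distance_histogram_compare([], [1.0])


class TestUpstreamFraction:
    GENES = pd.DataFrame({"chrom": ["chr1", "chr1"], "tss": [2000, 9000],
                          "strand": ["+", "-"]})

    def test_region_in_upstream_window(self):
        regions = _df([("chr1", 900, 1100)])
        assert upstream_fraction(regions, self.GENES) == 1.0

    def test_gene_body_not_counted(self):
        # region right of the + strand TSS (inside the gene), far from the
        # - strand gene's upstream window
        regions = _df([("chr1", 2100, 2300)])
        assert upstream_fraction(regions, self.GENES) == 0.0

    def test_minus_strand_window_is_right_of_tss(self):
        regions = _df([("chr1", 9500, 9600)])
        assert upstream_fraction(regions, self.GENES) == 1.0

    def test_max_dist_zero(self):
        regions = _df([("chr1", 1990, 2010)])
        assert upstream_fraction(regions, self.GENES, max_dist=0) == 0.0

    def test_monotone_in_max_dist(self, rng):
        regions = _random_intervals(rng, 120, length_hi=200, span=40_000)
        genes = pd.DataFrame({
            "chrom": ["chr1"] * 10,
            "tss": rng.integers(0, 40_000, size=10),
            "strand": rng.choice(["+", "-"], size=10),
        })
        fracs = [upstream_fraction(regions, genes, max_dist=d)
                 for d in (0, 500, 1000, 3000, 10_000)]
        assert all(0.0 <= f <= 1.0 for f in fracs)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_matches_bruteforce(self, rng):
        regions = _random_intervals(rng, 200, length_hi=300, span=30_000)
        genes = pd.DataFrame({
            "chrom": ["chr1"] * 8,
            "tss": rng.integers(0, 30_000, size=8),
            "strand": rng.choice(["+", "-"], size=8),
        })
        got = upstream_fraction(regions, genes, max_dist=3000)
        count = 0
        for _, r in regions.iterrows():
            hit = False
            for _, gene in genes.iterrows():
                if gene["strand"] == "+":
                    lo, hi = max(0, gene["tss"] - 3000), gene["tss"]
                else:
                    lo, hi = gene["tss"] + 1, gene["tss"] + 3001
                if r["start"] < hi and r["end"] > lo:
                    hit = True
            count += hit
        assert got == pytest.approx(count / len(regions))


def _hypergeom_tail_comb(k, n, K, N):
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / total


class TestHypergeometricEnrichment:
    def test_exact_enumeration_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeometric_enrichment(4, 4, 5, 10) == \
            pytest.approx(5 / 210, rel=1e-12)

    def test_k_zero_certain(self):
        assert hypergeometric_enrichment(0, 7, 3, 20) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 4, 11, 10)

    def test_all_small_cases_match_comb_formula(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        got = hypergeometric_enrichment(k, n, K, N)
                        assert got == pytest.approx(
                            _hypergeom_tail_comb(k, n, K, N), abs=1e-12)

    def test_subset_enumeration_oracle(self):
        # literal enumeration of all draws for a handful of N <= 10 cases
        for (N, K, n, k) in [(8, 3, 4, 2), (10, 5, 4, 3), (9, 4, 5, 1)]:
            marked = set(range(K))
            hits = sum(1 for draw in itertools.combinations(range(N), n)
                       if len(marked.intersection(draw)) >= k)
            expected = hits / math.comb(N, n)
            assert hypergeometric_enrichment(k, n, K, N) == \
                pytest.approx(expected, rel=1e-12)


class TestMergeIntervals:
    def test_bookended_fragments_joined(self):
        out = merge_intervals(_df([("chr1", 0, 100), ("chr1", 100, 200)]))
        assert out.values.tolist() == [["chr1", 0, 200]]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals(_df([("chr1", 50, 50)]))
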