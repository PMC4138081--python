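import numpy as np
import pytest
from scipy.stats import chi2_contingency

from mirforge import context as ctx
from mirforge.discovery import CandidatePrecursor
from mirforge.models import GeneModel


def _pre(pid, scaffold, start, end, strand="+"):
    n = end - start
    return CandidatePrecursor(pid, scaffold, (start, end), strand, "A" * n,
                              "." * n, -30.0, {}, 1)


GENES = [GeneModel("g1", "s1", "+", ((1000, 1500), (3000, 3500)))]


class TestClassifyLocation:
    def test_intronic_sense(self):
        ap = ctx.classify_location(_pre("p", "s1", 2000, 2079, "+"), GENES)
        assert ap.location_class == "intronic_sense"
        assert ap.host_gene_id == "g1"

    def test_intronic_antisense(self):
        ap = ctx.classify_location(_pre("p", "s1", 2000, 2079, "-"), GENES)
        assert ap.location_class == "intronic_antisense"

    def test_exonic(self):
        ap = ctx.classify_location(_pre("p", "s1", 1200, 1279, "+"), GENES)
        assert ap.location_class == "exonic"

    def test_intergenic_distance(self):
        ap = ctx.classify_location(_pre("p", "s1", 8500, 8579, "+"), GENES)
        assert ap.location_class == "intergenic"
        assert ap.distance_to_nearest_gene == 5000

    def test_boundary_spanning_flagged(self):
        ap = ctx.classify_location(_pre("p", "s1", 3450, 3529, "+"), GENES)
        assert ap.boundary_flag


def brute_window_null(genome, genes, window, flank, sense=None):
    n = hits = 0
    for sc, seq in genome.items():
        gsp = [g.span for g in genes
               if g.biotype == "protein_coding" and g.scaffold_id == sc
               and (sense is None or g.strand == sense)]
        pos = 0
        while pos < len(seq):
            wend = min(len(seq), pos + window)
            if wend - pos < window and (wend - pos) * 2 < window:
                break
            n += 1
            fs, fe = max(0, pos - flank), min(len(seq), wend + flank)
            if any(a < fe and fs < b for a, b in gsp):
                hits += 1
            pos += window
    return n, hits


class TestWindowNull:
    def test_all_gene_genome_fraction_one(self):
        genome = {"s1": "A" * 790}
        genes = [GeneModel("g", "s1", "+", ((0, 790),))]
        assert ctx.window_null(genome, genes, 79).fraction == 1.0

    def test_gene_free_genome_fraction_zero(self):
        assert ctx.window_null({"s1": "A" * 790}, [], 79).fraction == 0.0

    def test_matches_per_window_brute_force(self, rng):
        for _ in range(15):
            genome = {f"s{i}": "A" * int(rng.integers(500, 6000))
                      for i in range(int(rng.integers(1, 4)))}
            genes = []
            for sc, seq in genome.items():
                pos = int(rng.integers(0, 200))
                while pos + 300 < len(seq):
                    end = pos + int(rng.integers(150, 400))
                    genes.append(GeneModel(f"g{sc}{pos}", sc,
                                           "+" if rng.random() < 0.5 else "-",
                                           ((pos, min(end, len(seq))),)))
                    pos = end + int(rng.integers(100, 800))
            for flank in (0, 100):
                res = ctx.window_null(genome, genes, 79, flank)
                n, hits = brute_window_null(genome, genes, 79, flank)
                assert (res.n_windows, res.n_overlapping_gene) == (n, hits)

    def test_sense_strand_restriction(self):
        genome = {"s1": "A" * 1000}
        genes = [GeneModel("g", "s1", "-", ((0, 1000),))]
        assert ctx.window_null(genome, genes, 100,
                               sense_strand="+").fraction == 0.0
        assert ctx.window_null(genome, genes, 100,
                               sense_strand="-").fraction == 1.0


class TestCompareProportions:
    def test_identical_proportions_are_null(self):
        stat, p, _ = ctx.compare_proportions(50, 100, 50, 100)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        stat, p, _ = ctx.compare_proportions(10, 100, 30, 100)
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(4.07e-4, rel=1e-2)

    def test_strong_contrast_is_significant(self):
        _stat, p, _ = ctx.compare_proportions(49, 100, 20, 100)
        assert p < 0.01

    def test_matches_scipy_to_1e10(self, rng):
        for _ in range(200):
            n1, n2 = int(rng.integers(10, 500)), int(rng.integers(10, 500))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            stat, p, _ = ctx.compare_proportions(k1, n1, k2, n2)
            ref = chi2_contingency([[k1, n1 - k1], [k2, n2 - k2]],
                                   correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            ctx.compare_proportions(0, 100, 0, 100)

    def test_low_expected_count_flagged(self):
        *_, low = ctx.compare_proportions(1, 10, 2, 10)
        assert low


def brute_force_clusters(intervals, max_gap):
    """Transitive closure over the pairwise 'gap <= max_gap on the same
    scaffold' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (sc1, s1, e1), (sc2, s2, e2) = intervals[i], intervals[j]
            if sc1 != sc2:
                continue
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestFindClusters:
    def _annotated(self, intervals):
        return [
            ctx.AnnotatedPrecursor(_pre(f"p{i}", sc, s, e), "intergenic",
                                   None, 0)
            for i, (sc, s, e) in enumerate(intervals)
        ]

    def test_boundary_gap_10000_clusters(self):
        aps = self._annotated([("s1", 0, 79), ("s1", 10079, 10158)])
        ctx.find_clusters(aps)
        assert aps[0].cluster_id is not None
        assert aps[0].cluster_id == aps[1].cluster_id

    def test_gap_10001_does_not_cluster(self):
        aps = self._annotated([("s1", 0, 79), ("s1", 10080, 10159)])
        ctx.find_clusters(aps)
        assert aps[0].cluster_id is None and aps[1].cluster_id is None

    def test_different_scaffolds_never_cluster(self):
        aps = self._annotated([("s1", 0, 79), ("s2", 100, 179)])
        ctx.find_clusters(aps)
        assert all(a.cluster_id is None for a in aps)

    def test_chain_of_three(self):
        aps = self._annotated([("s1", 0, 79), ("s1", 4079, 4158),
                               ("s1", 14157, 14236)])
        ctx.find_clusters(aps)
        assert len({a.cluster_id for a in aps}) == 1

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(40):
            intervals = []
            for _ in range(int(rng.integers(2, 25))):
                sc = f"s{int(rng.integers(2))}"
                start = int(rng.integers(0, 60_000))
                intervals.append((sc, start, start + 79))
            aps = self._annotated(intervals)
            ordered = ctx.find_clusters(aps, 10_000)
            got = {}
            for i, ap in enumerate(aps):
                key = ap.cluster_id if ap.cluster_id else f"single{i}"
                got.setdefault(key, []).append(
                    intervals.index((ap.precursor.scaffold_id,
                                     *ap.precursor.interval)))
            got_groups = sorted(sorted(v) for v in got.values())
            assert got_groups == brute_force_clusters(intervals, 10_000)


class TestFlankExtension:
    genome = {"s1": "A" * 20_000}
    genes = [GeneModel("g1", "s1", "+", ((5000, 6000),))]

    def test_flank_zero_matches_location_classing(self):
        aps = [ctx.classify_location(_pre("p", "s1", 5200, 5279), self.genes)]
        rows = ctx.flank_extension_profile(aps, self.genome, self.genes,
                                           (0, 500))
        assert rows[0]["precursor_fraction"] == 1.0

    def test_nearby_intergenic_joins_at_500(self):
        aps = [ctx.classify_location(_pre("p", "s1", 6400, 6479), self.genes)]
        rows = ctx.flank_extension_profile(aps, self.genome, self.genes,
                                           (0, 500, 1000, 2000))
        fr = [r["precursor_fraction"] for r in rows]
        assert fr == [0.0, 1.0, 1.0, 1.0]

    def test_fractions_monotone(self, rng):
        aps = [
            ctx.classify_location(
                _pre(f"p{i}", "s1", int(rng.integers(0, 19_900)),
                     int(rng.integers(0, 19_900)) + 79), self.genes)
            for i in range(15)
        ]
        # rebuild with valid intervals
        aps = [
            ctx.classify_location(_pre(f"p{i}", "s1", s, s + 79), self.genes)
            for i, s in enumerate(rng.integers(0, 19_900, size=15))
        ]
        rows = ctx.flank_extension_profile(aps, self.genome, self.genes)
        fr = [r["precursor_fraction"] for r in rows]
        assert fr == sorted(fr)
        nf = [r["null_fraction"] for r in rows]
        assert nf == sorted(nf)

    def test_unsorted_flanks_rejected(self):
        with pytest.raises(ValueError):
            ctx.flank_extension_profile([], self.genome, self.genes, (500, 0))
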