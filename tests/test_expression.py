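import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirforge import expression as expr
from mirforge.models import Sample, SampleSheet

CATALOG = [
    ("TGAGGTAGTAGGTTGTATAGTT", "let-7", 1),
    ("TATCACAGCCAGCTTTGATGAGC", "mir-2", 3),
    ("TCCCTGAGACCCTAACTTGTGA", "mir-10", 2),
]


def brute_force_assign(mature, catalog, novel_rank, min_identity=0.8):
    """All-offsets scoring oracle: slide the candidate over each entry;
    only the seed-aligned offset can qualify (seed positions must match
    positionally), score identity over the longer length."""
    best = None
    for ref, _fam, rank in catalog:
        for offset in range(-5, 6):
            # positions 2-8 of each sequence must coincide -> offset 0 only
            if offset != 0:
                continue
            if ref[1:8] != mature[1:8]:
                continue
            ident = sum(a == b for a, b in zip(mature, ref)) / max(
                len(mature), len(ref))
            if ident >= min_identity and (best is None or
                                          (-ident, rank) < best[:2]):
                best = (-ident, rank)
    return novel_rank if best is None else best[1]


class TestAssignPhylostratum:
    def test_identical_sequence_gets_catalog_rank(self):
        assert expr.assign_phylostratum(CATALOG[0][0], CATALOG, 9) == 1

    def test_seed_mismatch_is_novel(self):
        seq = list(CATALOG[0][0])
        seq[4] = "A" if seq[4] != "A" else "C"  # position 5 is in the seed
        assert expr.assign_phylostratum("".join(seq), CATALOG, 9) == 9

    def test_low_identity_is_novel(self):
        ref = CATALOG[0][0]
        seq = ref[:8] + "".join(
            "A" if b != "A" else "C" for b in ref[8:])  # seed kept, rest broken
        assert expr.assign_phylostratum(seq, CATALOG, 9) == 9

    def test_one_mismatch_outside_seed_keeps_rank(self):
        seq = list(CATALOG[1][0])
        seq[15] = "A" if seq[15] != "A" else "C"
        assert expr.assign_phylostratum("".join(seq), CATALOG, 9) == 3

    def test_short_mature_is_error(self):
        with pytest.raises(ValueError):
            expr.assign_phylostratum("ACGTACG", CATALOG, 9)

    def test_matches_brute_force_oracle(self, rng):
        bases = np.array(list("ACGT"))
        catalog = [("".join(bases[rng.integers(0, 4, 22)]), f"f{i}",
                    int(rng.integers(1, 7))) for i in range(50)]
        for _ in range(300):
            if rng.random() < 0.5:
                ref = catalog[int(rng.integers(len(catalog)))][0]
                seq = list(ref)
                for _m in range(int(rng.integers(0, 6))):
                    j = int(rng.integers(len(seq)))
                    seq[j] = bases[int(rng.integers(4))]
                seq = "".join(seq)
            else:
                seq = "".join(bases[rng.integers(0, 4, int(rng.integers(18,
                                                                        25)))])
            assert expr.assign_phylostratum(seq, catalog, 99) == \
                brute_force_assign(seq, catalog, 99)


class TestRPM:
    def test_fifty_reads_in_a_million(self):
        raw = pd.DataFrame({"a": [50, 0]}, index=["m1", "m2"])
        m = expr.compute_rpm(raw, {"a": 1_000_000})
        assert m.rpm.loc["m1", "a"] == 50.0
        assert m.rpm.loc["m2", "a"] == 0.0

    def test_doubling_library_halves_rpm(self):
        raw = pd.DataFrame({"a": [40], "b": [40]}, index=["m1"])
        m = expr.compute_rpm(raw, {"a": 1_000_000, "b": 2_000_000})
        assert m.rpm.loc["m1", "a"] == 2 * m.rpm.loc["m1", "b"]

    def test_zero_library_size_is_error(self):
        raw = pd.DataFrame({"a": [1]}, index=["m1"])
        with pytest.raises(ValueError):
            expr.compute_rpm(raw, {"a": 0})


class TestMiRPAI:
    def test_equal_ranks_collapse_to_that_rank(self):
        counts = pd.DataFrame(np.random.default_rng(0).integers(
            1, 100, (5, 4)), index=[f"m{i}" for i in range(5)],
            columns=list("abcd"))
        prof = expr.mirpai(counts, {f"m{i}": 3 for i in range(5)},
                           list("abcd"))
        assert all(v == pytest.approx(3.0) for v in prof.values.values())

    def test_weighted_mean_formula(self):
        counts = pd.DataFrame({"s": [100, 300]}, index=["m1", "m2"])
        prof = expr.mirpai(counts, {"m1": 1, "m2": 2}, ["s"])
        assert prof.values["s"] == pytest.approx(1.75)

    def test_bounded_by_rank_range_and_scale_invariant(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (20, 6)) + 1,
                              index=[f"m{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(6)])
        ranks = {f"m{i}": int(rng.integers(1, 8)) for i in range(20)}
        prof = expr.mirpai(counts, ranks, list(counts.columns))
        lo, hi = min(ranks.values()), max(ranks.values())
        for v in prof.values.values():
            assert lo <= v <= hi
        scaled = expr.mirpai(counts * 17, ranks, list(counts.columns))
        for s in counts.columns:
            assert prof.values[s] == pytest.approx(scaled.values[s])

    def test_zero_count_stage_is_error(self):
        counts = pd.DataFrame({"s": [0, 0]}, index=["m1", "m2"])
        with pytest.raises(ValueError):
            expr.mirpai(counts, {"m1": 1, "m2": 2}, ["s"])

    def test_missing_rank_is_error(self):
        counts = pd.DataFrame({"s": [1, 2]}, index=["m1", "m2"])
        with pytest.raises(ValueError):
            expr.mirpai(counts, {"m1": 1}, ["s"])


class TestCoexpression:
    def test_perfect_linear_relation(self):
        x = np.arange(16, dtype=float)
        res = expr.coexpression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.co_expressed

    def test_constant_host_is_degenerate(self):
        res = expr.coexpression(np.arange(16.0), np.ones(16))
        assert res.degenerate and not res.co_expressed

    def test_matches_scipy_pearsonr(self, rng):
        for _ in range(100):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            res = expr.coexpression(x, y)
            ref_r, ref_p = stats.pearsonr(x, y)
            assert res.r == pytest.approx(ref_r, abs=1e-12)
            assert res.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_negative_correlation_not_co_expressed(self):
        x = np.arange(16, dtype=float)
        res = expr.coexpression(x, -x)
        assert res.r == pytest.approx(-1.0) and not res.co_expressed


class TestCV:
    def test_two_point_example(self):
        assert expr.coefficient_of_variation([10, 30]) == pytest.approx(
            np.sqrt(200) / 20)

    def test_constant_vector_is_zero(self):
        assert expr.coefficient_of_variation([5, 5, 5]) == 0.0

    def test_scale_invariance(self, rng):
        v = rng.random(10) + 0.5
        assert expr.coefficient_of_variation(v) == pytest.approx(
            expr.coefficient_of_variation(7 * v))

    def test_zero_mean_is_error(self):
        with pytest.raises(ValueError):
            expr.coefficient_of_variation([0.0, 0.0])


def _sheet(n=3, merged=False):
    samples = [Sample(f"o{i}", "organ",
                      merge_group="m" if merged and i < 2 else None)
               for i in range(n)]
    return SampleSheet(samples)


class TestSpecificityScreen:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"mir{i}" for i in range(len(rows))],
                            columns=[f"o{i}" for i in range(len(rows[0]))])

    def test_fivefold_high_call(self):
        calls = expr.specificity_screen(self._frame([[100, 10, 10]]), _sheet())
        assert calls.loc["mir0", "call"] == "specific_high"
        assert calls.loc["mir0", "sample"] == "o0"

    def test_just_under_fivefold_is_none(self):
        calls = expr.specificity_screen(self._frame([[100, 21, 10]]), _sheet())
        assert calls.loc["mir0", "call"] == "none"

    def test_one_fifth_low_call(self):
        calls = expr.specificity_screen(self._frame([[1, 10, 10]]), _sheet())
        assert calls.loc["mir0", "call"] == "specific_low"

    def test_merge_group_averaged_before_screening(self):
        # the two mantle parts average to 55; 275 >= 5 x 55 passes only
        # because merging happens first
        rpm = pd.DataFrame([[100, 10, 275, 20]], index=["mir0"],
                           columns=["o0", "o1", "o2", "o3"])
        sheet = SampleSheet([
            Sample("o0", "organ", merge_group="mantle"),
            Sample("o1", "organ", merge_group="mantle"),
            Sample("o2", "organ"), Sample("o3", "organ"),
        ])
        calls = expr.specificity_screen(rpm, sheet)
        assert calls.loc["mir0", "call"] == "specific_high"
        assert calls.loc["mir0", "sample"] == "o2"

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            expr.specificity_screen(self._frame([[1, 2]]), _sheet(2))
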