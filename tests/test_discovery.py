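import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirforge import discovery as disc
from mirforge.folding import fold
from mirforge.models import ReadTag, TagAlignment
from mirforge.synthetic import build_hairpin


@pytest.fixture(scope="module")
def perfect():
    """A designed hairpin with its fold and intended matures."""
    hp, m5, m3 = build_hairpin(32, 15, seed=3)
    return fold(hp), m5, m3


class TestDuplexGeometry:
    def test_designed_duplex_has_two_nt_overhangs(self, perfect):
        fr, m5, m3 = perfect
        g = disc.duplex_geometry(fr, m5, m3)
        assert g.n_complementary == 20  # mature length 22, both ends offset 2
        assert (g.overhang_base_end, g.overhang_loop_end) == (2, 2)
        assert g.dicer_signature

    def test_shifted_star_breaks_the_overhang(self, perfect):
        fr, m5, (a3, e3) = perfect
        g = disc.duplex_geometry(fr, m5, (a3 + 2, e3 + 2))
        assert not g.dicer_signature
        assert g.overhang_base_end == 4 and g.overhang_loop_end == 4

    def test_no_pairing_between_matures(self, perfect):
        fr, m5, _ = perfect
        g = disc.duplex_geometry(fr, m5, (m5[0], m5[1]))  # same arm twice
        assert g.n_complementary == 0
        assert g.overhang_base_end is None


def _candidate(mfe=-40.0, n_loci=1, frac5=1.0, frac3=1.0, n5=400, n3=40,
               ncomp=20, over=(2, 2), conserved=False):
    prof5 = disc.ArmProfile("5p", [(2, 24, n5)], 2, 22, frac5, n5)
    prof3 = disc.ArmProfile("3p", [(57, 79, n3)], 57, 22, frac3, n3)
    arm_profiles = {}
    if n5 > 0:
        arm_profiles["5p"] = prof5
    if n3 > 0:
        arm_profiles["3p"] = prof3
    return disc.CandidatePrecursor(
        "c1", "s1", (0, 79), "+", "A" * 79, "." * 79, mfe, arm_profiles,
        n_loci, geometry=disc.DuplexGeometry(ncomp, *over), conserved=conserved,
    )


class TestApplyCriteria:
    def test_clean_candidate_accepted(self):
        assert disc.apply_criteria(_candidate()).accepted

    @pytest.mark.parametrize(
        "kwargs, failed",
        [
            ({"n_loci": 2}, {1}),
            ({"mfe": -20.0}, {2}),
            ({"mfe": -21.0}, {2}),  # strictly lower than -21 required
            ({"frac5": 0.79}, {3}),
            ({"n5": 49, "n3": 0}, {3, 4, 5, 6}),  # missing arm fails 3/4 and
            # leaves no duplex geometry
            ({"n5": 30, "n3": 19}, {4}),  # combined 49 < 50
            ({"ncomp": 15}, {5}),
            ({"over": (3, 1)}, {6}),
        ],
    )
    def test_single_rule_failures(self, kwargs, failed):
        cand = _candidate(**kwargs)
        if kwargs.get("n3") == 0:
            cand.geometry = None
        v = disc.apply_criteria(cand)
        assert v.failed == frozenset(failed)

    def test_mfe_just_below_threshold_passes(self):
        assert disc.apply_criteria(_candidate(mfe=-21.5)).per_criterion[2][0]

    def test_combined_fifty_reads_pass(self):
        v = disc.apply_criteria(_candidate(n5=30, n3=20))
        assert v.per_criterion[4][0]

    def test_conservation_rescues_broken_overhang(self):
        v = disc.apply_criteria(_candidate(over=(4, 4), conserved=True))
        assert v.per_criterion[6][0]

    def test_whitelist_rescues_multi_locus(self):
        t = disc.CriteriaThresholds(multi_locus_whitelist=frozenset({"A" * 79}))
        v = disc.apply_criteria(_candidate(n_loci=2), t)
        assert v.per_criterion[1][0]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n5=st.integers(1, 500), n3=st.integers(1, 500),
           extra=st.integers(0, 200))
    def test_criterion4_monotone_in_reads(self, n5, n3, extra):
        before = disc.apply_criteria(_candidate(n5=n5, n3=n3)).per_criterion[4][0]
        after = disc.apply_criteria(
            _candidate(n5=n5 + extra, n3=n3)).per_criterion[4][0]
        if before:
            assert after


class TestAssignRoles:
    def test_sixfold_difference_gives_guide_and_star(self):
        (m5, m3) = disc.assign_roles(_candidate(n5=600, n3=100))
        assert m5.role == "guide" and m3.role == "star"

    def test_comparable_arms_are_co_mature(self):
        roles = {m.arm: m.role for m in disc.assign_roles(_candidate(n5=300,
                                                                     n3=200))}
        assert roles == {"5p": "co_mature", "3p": "co_mature"}

    def test_exactly_fivefold_is_co_mature(self):
        roles = {m.arm: m.role for m in disc.assign_roles(_candidate(n5=500,
                                                                     n3=100))}
        assert roles == {"5p": "co_mature", "3p": "co_mature"}

    def test_low_read_star_dropped_from_expression_set(self):
        matures = disc.assign_roles(_candidate(n5=500, n3=49))
        by_arm = {m.arm: m for m in matures}
        assert by_arm["5p"].role == "guide"
        assert by_arm["3p"].role == "star"
        assert not by_arm["3p"].in_expression_set
        assert by_arm["5p"].in_expression_set

    def test_zero_star_reads_is_infinite_ratio(self):
        cand = _candidate(n5=100, n3=40)
        cand.arm_profiles["3p"].total_reads = 0
        matures = disc.assign_roles(cand)
        assert {m.arm: m.role for m in matures} == {"5p": "guide", "3p": "star"}


class TestExtraction:
    def _alignments(self, genome, start, count, length=22):
        tag = ReadTag(genome["s1"][start: start + length],
                      {"x": count})
        return [TagAlignment(tag, "s1", start, "+")]

    def test_small_stack_yields_no_window(self, rng):
        genome = {"s1": "".join(np.array(list("ACGT"))[rng.integers(0, 4,
                                                                    2000)])}
        alns = self._alignments(genome, 500, count=5)
        assert disc.extract_candidates(alns, genome,
                                       disc.ExtractionParams()) == []

    def test_qualifying_stack_yields_two_windows(self, rng):
        genome = {"s1": "".join(np.array(list("ACGT"))[rng.integers(0, 4,
                                                                    2000)])}
        alns = self._alignments(genome, 500, count=50)
        wins = disc.extract_candidates(alns, genome, disc.ExtractionParams())
        assert len(wins) == 2
        for _sc, strand, ws, we in wins:
            assert strand == "+" and we - ws == 100

    def test_windows_containing_n_discarded(self):
        # the A-island is too narrow for either window to avoid the Ns
        genome = {"s1": "N" * 100 + "A" * 60 + "N" * 100 + "A" * 400}
        tag = ReadTag("A" * 22, {"x": 50})
        wins = disc.extract_candidates([TagAlignment(tag, "s1", 120, "+")],
                                       genome, disc.ExtractionParams())
        assert wins == []


def test_count_genomic_loci_counts_both_strands():
    from mirforge.models import revcomp

    probe = "ACGGTTCAACGGATCCGTTGAACCGT"[:20]
    genome = {"s1": "T" * 50 + probe + "T" * 50 + revcomp(probe) + "T" * 50,
              "s2": probe + "T" * 30}
    assert disc.count_genomic_loci(probe, genome) == 3
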