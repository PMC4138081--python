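import numpy as np
import pytest

from mirforge import discovery as disc
from mirforge import synthetic as syn
from mirforge.folding import fold
from mirforge.models import revcomp


class TestBuildHairpin:
    def test_dimensions_and_mature_placement(self):
        hp, m5, m3 = syn.build_hairpin(30, 10, seed=0, gc_bias=0.8)
        assert len(hp) == 70
        assert m5 == (2, 24) and m3 == (48, 70)

    def test_strong_stem_folds_below_threshold(self):
        hp, _, _ = syn.build_hairpin(30, 10, seed=0, gc_bias=0.8)
        assert fold(hp).mfe <= -21.0

    def test_same_seed_is_identical(self):
        a = syn.build_hairpin(32, 15, seed=5)
        b = syn.build_hairpin(32, 15, seed=5)
        assert a == b

    def test_infeasible_geometry_is_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            syn.build_hairpin(16, 10, seed=0, mature_length=22)

    def test_intended_duplex_has_dicer_overhangs(self):
        hp, m5, m3 = syn.build_hairpin(32, 15, seed=1)
        g = disc.duplex_geometry(fold(hp), m5, m3)
        assert g.dicer_signature and g.n_complementary >= 16


class TestPlantGenome:
    def test_contexts_are_realised_as_labelled(self, small_truth):
        genes = {g.gene_id: g for g in small_truth.genes
                 if g.biotype == "protein_coding"}
        for plant in small_truth.plants:
            ctx = plant.spec.context
            host = None
            for g in genes.values():
                if g.scaffold_id != plant.scaffold_id:
                    continue
                for intron in g.introns:
                    if intron[0] <= plant.start and plant.end <= intron[1]:
                        host = g
            if ctx == "intergenic":
                assert host is None
                for g in genes.values():
                    if g.scaffold_id == plant.scaffold_id:
                        gs, ge = g.span
                        assert plant.end <= gs or ge <= plant.start
            else:
                assert host is not None
                if ctx == "intronic_sense":
                    assert plant.strand == host.strand
                else:
                    assert plant.strand != host.strand

    def test_cluster_members_gap_below_10kb(self, small_truth):
        by_cluster = {}
        for p in small_truth.plants:
            if p.spec.cluster_id:
                by_cluster.setdefault(p.spec.cluster_id, []).append(p)
        assert by_cluster
        for members in by_cluster.values():
            members.sort(key=lambda p: p.start)
            assert len({p.scaffold_id for p in members}) == 1
            for a, b in zip(members, members[1:]):
                assert 0 < b.start - a.end < 10_000

    def test_criterion1_decoy_duplicated_exactly_twice(self, small_truth):
        decoy = next(p for p in small_truth.plants
                     if p.spec.violated_criterion == 1)
        assert len(decoy.extra_loci) == 1
        assert disc.count_genomic_loci(decoy.hairpin if decoy.strand == "+"
                                       else revcomp(decoy.hairpin),
                                       small_truth.genome) == 2

    def test_genome_determinism(self, samples):
        specs = syn.study_plants(samples, n_true=4, n_decoys_per_criterion=0,
                                 seed=3, n_clusters=0)
        a = syn.plant_genome(2, 20_000, 0.35, specs, seed=4)
        b = syn.plant_genome(2, 20_000, 0.35, specs, seed=4)
        assert a.genome == b.genome
        assert [(p.start, p.end, p.strand) for p in a.plants] == \
            [(p.start, p.end, p.strand) for p in b.plants]

    def test_oversized_planting_is_error(self, samples):
        specs = syn.study_plants(samples, n_true=50, n_decoys_per_criterion=0,
                                 seed=0, n_clusters=0)
        with pytest.raises(syn.PlacementError):
            syn.plant_genome(1, 3000, 0.4, specs, seed=0)


class TestPlantability:
    """Every criterion has a constructible decoy that fails exactly that
    criterion under the actual engine (the generator validates at build
    time; this re-checks from scratch)."""

    def test_decoys_fail_exactly_their_criterion(self, small_truth):
        seen = set()
        for plant in small_truth.plants:
            want = plant.spec.violated_criterion
            ok, failed = syn.validate_plant(plant, small_truth.genome,
                                            small_truth.catalog)
            assert ok, (plant.precursor_id, want, sorted(failed))
            if want is not None:
                seen.add(want)
        assert seen == {1, 2, 3, 4, 5, 6}


class TestSimulateReads:
    def test_determinism_byte_identical(self, small_truth, samples):
        a = syn.simulate_reads(small_truth, samples, seed=21)
        b = syn.simulate_reads(small_truth, samples, seed=21)
        assert a == b

    def test_zero_jitter_reads_start_at_intended_matures(self, samples):
        specs = syn.study_plants(samples, n_true=4, n_decoys_per_criterion=0,
                                 seed=5, n_clusters=0)
        truth = syn.plant_genome(2, 20_000, 0.35, specs, seed=6)
        noise = syn.NoiseModel(five_prime_jitter_rate=0.0,
                               background_rate=0.0, qc_fail_rate=0.0)
        reads = syn.simulate_reads(truth, samples, noise, seed=7)
        intended = set()
        for p in truth.plants:
            for arm in ("5p", "3p"):
                rec = syn._arm_read(p, truth.genome, arm, 0, 0)
                intended.add(rec[0])
        for sid, rec_list in reads.items():
            for _rid, seq, _q in rec_list:
                assert seq in intended

    def test_count_conservation(self, small_truth, samples):
        reads = syn.simulate_reads(small_truth, samples, seed=22)
        for sid in samples.sample_ids:
            n_plant = sum(v for (pid, arm, s), v in small_truth.emitted.items()
                          if s == sid)
            expected = (n_plant + small_truth.background[sid]
                        + small_truth.qc_fail[sid])
            assert len(reads[sid]) == expected

    def test_criterion4_decoy_under_fifty_reads(self, small_truth, samples):
        syn.simulate_reads(small_truth, samples, seed=23)
        for p in small_truth.plants:
            total = sum(v for (pid, _a, _s), v in small_truth.emitted.items()
                        if pid == p.precursor_id)
            if p.spec.violated_criterion == 4:
                assert total < 50
            else:
                assert total >= 50

    def test_unknown_sample_id_is_error(self, small_truth, samples):
        bad = syn.PlantSpec("x", "intergenic", None, 1,
                            expression_profile={"nope": 5.0})
        truth = syn.SyntheticTruth([], small_truth.genome, [], [])
        truth.plants = [p for p in small_truth.plants]
        truth.plants[0].spec.expression_profile["not-a-sample"] = 1.0
        with pytest.raises(ValueError, match="unknown sample"):
            syn.simulate_reads(truth, samples, seed=1)
        del truth.plants[0].spec.expression_profile["not-a-sample"]


def test_stage_counts_simulator_shapes():
    counts, ranks, peak = syn.simulate_stage_counts(50, 8, seed=3)
    assert counts.shape == (50, 8)
    assert set(ranks) == set(counts.index)
    assert 0 <= peak < 8
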