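"""Ground-truthed synthetic data: toy genome, gene models, planted miRNA
precursors (true and per-criterion decoys) and multi-sample small RNA
reads.

The generator is the study-condition oracle for the whole pipeline: every
planted precursor is validated against the actual criteria engine at build
time (rejection sampling), so a "true" plant satisfies all six annotation
criteria given its intended read stack and a decoy for criterion c fails
exactly c.  Per-(plant, sample) arm counts are negative binomial; 5'-end
heterogeneity is a +-1 nt jitter; a configurable fraction of reads carries
low-quality bases so the QC rule has work to do; background reads come
from annotated intervals and random genome.

Hairpin geometry: a planted hairpin is  [2-nt lead][5p arm, L nt][loop]
[3p arm = revcomp(5p arm)] ; the 5p mature starts 2 nt into the sequence
and the 3p mature runs to the hairpin 3' end, which realises the exact
2-nt 3' overhang at both duplex ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import discovery as disc
from .models import GeneModel, ReadTag, SampleSheet, TagAlignment, revcomp

MATURE_LENGTH = 22
DEFAULT_STEM = 32  # with loop 15 -> 79 nt, the average precursor length
DEFAULT_LOOP = 15


class PlacementError(RuntimeError):
    pass


@dataclass
class PlantSpec:
    precursor_id: str
    context: str  # intronic_sense | intronic_antisense | intergenic
    cluster_id: str | None
    phylostratum: int
    stem_length: int = DEFAULT_STEM
    loop_length: int = DEFAULT_LOOP
    violated_criterion: int | None = None
    expression_profile: dict[str, float] = field(default_factory=dict)
    mature_length: int = MATURE_LENGTH
    guide_arm: str = "5p"
    co_mature: bool = False
    conserved: bool = False  # gets a catalog entry
    gc_bias: float = 0.55

    def __post_init__(self) -> None:
        if self.stem_length < 16:
            raise ValueError("stem_length must be >= 16")
        if self.loop_length < 3:
            raise ValueError("loop_length must be >= 3")
        if self.context not in ("intronic_sense", "intronic_antisense", "intergenic"):
            raise ValueError(f"bad context {self.context!r}")
        if self.violated_criterion is not None and not 1 <= self.violated_criterion <= 6:
            raise ValueError("violated_criterion must be 1..6 or None")


@dataclass
class RealizedPlant:
    spec: PlantSpec
    scaffold_id: str
    start: int  # hairpin start, forward coordinates
    end: int
    strand: str
    hairpin: str  # 5'->3' hairpin sequence
    mature_5p: tuple[int, int]  # hairpin-local
    mature_3p: tuple[int, int]
    extra_loci: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def precursor_id(self) -> str:
        return self.spec.precursor_id

    def mature_sequence(self, arm: str) -> str:
        s, e = self.mature_5p if arm == "5p" else self.mature_3p
        return self.hairpin[s:e]

    def mature_genomic(self, arm: str) -> tuple[int, int]:
        s, e = self.mature_5p if arm == "5p" else self.mature_3p
        if self.strand == "+":
            return (self.start + s, self.start + e)
        return (self.end - e, self.end - s)


@dataclass
class SyntheticTruth:
    plants: list[RealizedPlant]
    genome: dict[str, str]
    genes: list[GeneModel]
    catalog: list[tuple[str, str, int]]
    # (precursor_id, arm, sample) -> emitted read count; filled by simulate_reads
    emitted: dict[tuple[str, str, str], int] = field(default_factory=dict)
    background: dict[str, int] = field(default_factory=dict)
    qc_fail: dict[str, int] = field(default_factory=dict)

    def plant(self, precursor_id: str) -> RealizedPlant:
        for p in self.plants:
            if p.precursor_id == precursor_id:
                return p
        raise KeyError(precursor_id)


# ------------------------------------------------------------- hairpins

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def build_hairpin(
    stem_length: int,
    loop_length: int,
    seed: int | np.random.Generator,
    gc_bias: float = 0.55,
    mature_length: int = MATURE_LENGTH,
    arm_mode: str = "revcomp",
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """A stem-loop sequence with intended mature coordinates.

    Returns (hairpin, 5p mature interval, 3p mature interval), hairpin
    length = 2*stem + loop.  ``arm_mode`` controls arm complementarity:
    ``revcomp`` (Watson-Crick stem), ``wobble`` (G:T-only stem, for weak
    decoys) or ``mismatched`` (Watson-Crick with mismatches injected).
    """
    if stem_length < 16 or loop_length < 3:
        raise ValueError("need stem_length >= 16 and loop_length >= 3")
    if mature_length > stem_length:
        raise ValueError(
            f"infeasible geometry: mature {mature_length} nt exceeds "
            f"stem {stem_length} nt"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if arm_mode == "wobble":
        arm5 = "G" * stem_length
        arm3 = "T" * stem_length
    else:
        arm5 = _random_seq(rng, stem_length, gc_bias)
        arm3 = list(revcomp(arm5))
        # a few G:U wobble pairs, as real stems have; they also break the
        # perfect self-complementarity that would let arm reads map
        # antisense onto the opposite arm
        cand = [i for i in range(4, mature_length - 2) if arm5[i] in "GT"]
        rng.shuffle(cand)
        for i in cand[:3]:
            arm3[stem_length - 1 - i] = "T" if arm5[i] == "G" else "G"
        arm3 = "".join(arm3)
    loop = _random_seq(rng, loop_length, 0.3)
    hairpin = arm5 + loop + arm3
    total = len(hairpin)
    m = mature_length
    mature_5p = (2, 2 + m)
    mature_3p = (total - m, total)
    return hairpin, mature_5p, mature_3p


def _inject_mismatches(hairpin: str, stem_length: int, loop_length: int,
                       positions: list[int], rng: np.random.Generator) -> str:
    """Break Watson-Crick pairing at the given 5p-arm offsets by mutating
    the 3p-arm partner to the same base as the 5p side (never pairable
    with itself except G:T; G is avoided)."""
    seq = list(hairpin)
    total = len(hairpin)
    for i in positions:
        partner = total - 1 - i
        b = seq[i]
        repl = {"A": "A", "C": "C", "G": "A", "T": "C"}[b]
        seq[partner] = repl
    return "".join(seq)


# -------------------------------------------------------------- genomes


def _make_genes(
    rng: np.random.Generator, scaffold_id: str, length: int, gene_density: float,
    tag: str, forbidden: list[tuple[int, int]] | None = None,
) -> list[GeneModel]:
    """Walk the scaffold emitting genes with a target coverage density,
    skipping over ``forbidden`` intervals (reserved intergenic space)."""
    forbidden = sorted(forbidden or [])
    genes: list[GeneModel] = []
    mean_gene = 3000.0
    mean_gap = max(400.0, mean_gene * (1 - gene_density) / max(gene_density, 0.05))
    pos = int(rng.integers(200, int(mean_gap) + 200))
    k = 0
    while pos + 1200 < length:
        n_exons = int(rng.integers(2, 5))
        exons = []
        cursor = pos
        for i in range(n_exons):
            exon_len = int(rng.integers(150, 400))
            exons.append((cursor, cursor + exon_len))
            cursor += exon_len
            if i < n_exons - 1:
                cursor += int(rng.integers(400, 1400))  # intron
        if cursor >= length - 50:
            break
        clash = next((f for f in forbidden if f[0] < cursor and pos < f[1]), None)
        if clash is not None:
            pos = clash[1] + int(rng.integers(100, 400))
            continue
        k += 1
        genes.append(
            GeneModel(
                f"g_{tag}{k:03d}", scaffold_id,
                "+" if rng.random() < 0.5 else "-", tuple(exons),
            )
        )
        pos = cursor + int(rng.integers(int(mean_gap * 0.5), int(mean_gap * 1.5)))
    return genes


def _make_ncrna(
    rng: np.random.Generator, scaffold_id: str, length: int,
    occupied: list[tuple[int, int]], tag: str, n: int = 6,
) -> list[GeneModel]:
    out = []
    biotypes = ["rRNA", "tRNA", "snRNA", "repeat"]
    for i in range(n):
        for _ in range(50):
            size = int(rng.integers(80, 300))
            s = int(rng.integers(0, length - size))
            if all(s >= e + 50 or s + size <= b - 50 for b, e in occupied):
                occupied.append((s, s + size))
                out.append(
                    GeneModel(f"nc_{tag}{i:02d}", scaffold_id, "+",
                              ((s, s + size),), biotypes[i % 4])
                )
                break
    return out


# ---------------------------------------------------- intended read stacks


def _arm_read(
    plant: RealizedPlant, genome: dict[str, str], arm: str,
    shift5: int, shift3: int,
) -> tuple[str, int] | None:
    """Read (sequence, genomic start) for an arm mature shifted at its
    5'/3' ends; sequence is taken from the genome (strand-adjusted), so
    shifted reads may run past the hairpin proper."""
    ls, le = plant.mature_5p if arm == "5p" else plant.mature_3p
    ls, le = ls + shift5, le + shift3
    if le - ls < 18:
        return None
    if plant.strand == "+":
        gs, ge = plant.start + ls, plant.start + le
    else:
        gs, ge = plant.end - le, plant.end - ls
    scaffold = genome[plant.scaffold_id]
    if gs < 0 or ge > len(scaffold):
        return None
    seq = scaffold[gs:ge]
    if plant.strand == "-":
        seq = revcomp(seq)
    return seq, gs


def _intended_stack(
    plant: RealizedPlant, genome: dict[str, str],
    guide_total: int = 400, star_total: int = 40,
) -> list[TagAlignment]:
    """The idealised (jitter-free) alignments this plant should produce,
    used both for build-time validation and for tests."""
    spec = plant.spec
    if spec.co_mature:
        star_total = int(guide_total / 1.5)
    if spec.violated_criterion == 4:
        guide_total, star_total = 30, 5
    entries = []  # (arm, start_shift, end_shift, count)
    guide, star = (spec.guide_arm, "3p" if spec.guide_arm == "5p" else "5p")
    if spec.violated_criterion == 3:
        entries += [(guide, 0, 0, int(guide_total * 0.5)),
                    (guide, 1, 0, int(guide_total * 0.3)),
                    (guide, -1, 0, int(guide_total * 0.2))]
    else:
        entries.append((guide, 0, 0, guide_total))
    if spec.violated_criterion == 6:
        entries.append((star, 2, 2, star_total))  # whole star shifted +2
    else:
        entries.append((star, 0, 0, star_total))
    out = []
    for arm, s_shift, e_shift, count in entries:
        if count <= 0:
            continue
        rec = _arm_read(plant, genome, arm, s_shift, e_shift)
        if rec is None:
            continue
        seq, gs = rec
        tag = ReadTag(seq, {"_intended": count})
        out.append(TagAlignment(tag, plant.scaffold_id, gs, plant.strand))
    return out


def validate_plant(
    plant: RealizedPlant,
    genome: dict[str, str],
    catalog: list[tuple[str, str, int]],
    thresholds: disc.CriteriaThresholds | None = None,
    params: disc.ExtractionParams | None = None,
) -> tuple[bool, frozenset[int]]:
    """Run the actual extraction + criteria engine on the plant's intended
    read stack; returns (matches_intent, failed_criteria)."""
    alignments = _intended_stack(plant, genome)
    windows = disc.extract_candidates(alignments, genome, params)
    best = None
    for i, (scaffold, strand, ws, we) in enumerate(windows):
        cand = disc.evaluate_window(
            scaffold, strand, (ws, we), alignments, genome, thresholds,
            catalog, precursor_id=f"val{i}",
        )
        if cand is None:
            continue
        if best is None or len(cand.verdict.failed) < len(best.verdict.failed):
            best = cand
    if best is None:
        return False, frozenset({0})
    failed = best.verdict.failed
    want = plant.spec.violated_criterion
    ok = failed == (frozenset() if want is None else frozenset({want}))
    return ok, failed


# -------------------------------------------------------------- planting


def _design_hairpin(spec: PlantSpec, rng: np.random.Generator):
    """Draw a hairpin matching the spec's intent (before placement)."""
    c = spec.violated_criterion
    if c == 2:
        # All-wobble stem: every stem pair is G:T (-1 kcal/mol), so 20
        # pairs fold at -20, above the -21 threshold, while 17 pairs still
        # join the two matures (criterion 5 holds).  The whole hairpin is
        # drawn over {G,T} with loop and tail all-G, which caps the T
        # count at exactly the stem length -- no alternative structure can
        # score higher than the ladder.
        k, m = 20, 19
        arm5 = "GG" + "".join(rng.choice(["G", "T"], size=k - 2))
        arm3 = "".join("T" if b == "G" else "G" for b in reversed(arm5))
        hp = arm5 + "G" * spec.loop_length + arm3 + "GG"
        total = len(hp)
        return hp, (2, 2 + m), (total - 2 - m, total - 2)
    if c == 5:
        hp, m5, m3 = build_hairpin(spec.stem_length, spec.loop_length, rng,
                                   spec.gc_bias, spec.mature_length)
        # break pairing inside the duplex until < 16 pairs remain
        n_pairs = spec.mature_length - 2
        n_break = n_pairs - int(rng.integers(12, 15))
        offsets = rng.choice(np.arange(4, spec.mature_length - 3), size=n_break,
                             replace=False)
        hp = _inject_mismatches(hp, spec.stem_length, spec.loop_length,
                                sorted(int(o) for o in offsets), rng)
        return hp, m5, m3
    return build_hairpin(spec.stem_length, spec.loop_length, rng,
                         spec.gc_bias, spec.mature_length)


def _place_interval(
    rng: np.random.Generator,
    scaffolds: dict[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    size: int,
    margin: int,
    retries: int = 400,
    scaffold: str | None = None,
    lo: int | None = None,
    hi: int | None = None,
) -> tuple[str, int]:
    names = list(scaffolds)
    for _ in range(retries):
        sc = scaffold or names[int(rng.integers(len(names)))]
        a = lo if lo is not None else 50
        b = (hi if hi is not None else scaffolds[sc]) - size - 50
        if b <= a:
            continue
        s = int(rng.integers(a, b))
        if all(
            s >= e + margin or s + size <= b0 - margin
            for b0, e in occupied.get(sc, [])
        ):
            occupied.setdefault(sc, []).append((s, s + size))
            return sc, s
    raise PlacementError(f"cannot place interval of {size} bp after {retries} tries")


_PAD = "AA"  # strand-space 2-nt tail written after every hairpin; absorbs
# the precursor trim so the trimmed candidate never ends in arbitrary
# genomic sequence (at most one extra A:T pair per tail base can form)


def _write_plant(genome: dict[str, str], sc: str, pos: int, hairpin: str,
                 strand: str) -> tuple[int, int]:
    """Write hairpin + tail at ``pos``; returns the hairpin's genomic
    interval (the tail sits 3' of the hairpin in strand space)."""
    gplant = hairpin + _PAD
    seq = gplant if strand == "+" else revcomp(gplant)
    g = genome[sc]
    genome[sc] = g[:pos] + seq + g[pos + len(seq):]
    if strand == "+":
        return (pos, pos + len(hairpin))
    return (pos + len(_PAD), pos + len(_PAD) + len(hairpin))


def plant_genome(
    n_scaffolds: int,
    scaffold_length: int,
    gene_density: float,
    plants: list[PlantSpec],
    seed: int,
    intergenic_min_dist: int = 500,
    cluster_gap_range: tuple[int, int] = (300, 2000),
    unit_margin: int = 150,
    validate: bool = True,
) -> SyntheticTruth:
    """Build genome + genes and realize every plant at a context-consistent
    locus; cluster members are chained with gaps below 10 kb.  Each plant
    is validated against the criteria engine and redrawn until its verdict
    matches its label."""
    rng = np.random.default_rng(seed)
    total_plant = sum(2 * p.stem_length + p.loop_length for p in plants)
    if total_plant >= n_scaffolds * scaffold_length:
        raise PlacementError("total planted length exceeds genome length")
    genome = {
        f"scaffold{i + 1}": _random_seq(rng, scaffold_length, 0.4)
        for i in range(n_scaffolds)
    }
    scaffolds = {sc: len(seq) for sc, seq in genome.items()}
    pad_n = len(_PAD)

    # group plants into placement units (cluster chains or singletons)
    units: dict[str, list[PlantSpec]] = {}
    order: list[str] = []
    for p in plants:
        key = p.cluster_id or f"__single_{p.precursor_id}"
        if key not in units:
            units[key] = []
            order.append(key)
        units[key].append(p)

    # reserve intergenic space first, then grow genes around it: the
    # reservations double as the forbidden set for gene placement, which
    # guarantees the configurable gene distance by construction
    reserved: dict[str, list[tuple[int, int]]] = {sc: [] for sc in genome}
    reserved_true: dict[str, list[tuple[int, int]]] = {sc: [] for sc in genome}
    unit_slot: dict[str, tuple[str, int, list[int]]] = {}
    c1_slot: dict[str, tuple[str, int]] = {}
    # designed cluster chains claim an exclusion band: no other *true*
    # unit may come within 10 kb, so the designed clusters are the only
    # multi-precursor chains guaranteed among accepted precursors.
    # Decoys are rejected at discovery and may pack anywhere.
    chains_first = sorted(order, key=lambda k: -len(units[k]))
    for key in chains_first:
        members = units[key]
        if members[0].context.startswith("intronic"):
            continue
        is_true = members[0].violated_criterion is None
        sizes = [2 * p.stem_length + p.loop_length + pad_n for p in members]
        gaps = [int(rng.integers(*cluster_gap_range))
                for _ in range(len(members) - 1)]
        chain_len = sum(sizes) + sum(gaps)
        for _try in range(600):
            sc, s = _place_interval(rng, scaffolds, reserved, chain_len,
                                    margin=unit_margin)
            if not is_true or all(
                    s >= e + 10_500 or s + chain_len <= b - 10_500
                    for b, e in reserved_true[sc]):
                break
            reserved[sc].remove((s, s + chain_len))
        else:
            raise PlacementError(f"cannot keep unit {key} clear of clusters")
        if is_true and len(members) > 1:
            reserved_true[sc].append((s, s + chain_len))
        unit_slot[key] = (sc, s, gaps)
    for p in plants:  # second locus for criterion-1 decoys
        if p.violated_criterion == 1:
            size = 2 * p.stem_length + p.loop_length + pad_n + 8
            sc, s = _place_interval(rng, scaffolds, reserved, size,
                                    margin=unit_margin)
            c1_slot[p.precursor_id] = (sc, s)

    genes: list[GeneModel] = []
    for i, (sc, seq) in enumerate(genome.items()):
        forbidden = [(max(0, a - intergenic_min_dist), b + intergenic_min_dist)
                     for a, b in reserved[sc]]
        genes.extend(_make_genes(rng, sc, len(seq), gene_density,
                                 f"s{i + 1}", forbidden))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.scaffold_id, []).append(g.span)
    nc_occupied = {
        sc: gene_spans.get(sc, []) + reserved[sc] for sc in genome
    }
    for i, (sc, seq) in enumerate(genome.items()):
        genes.extend(
            _make_ncrna(rng, sc, len(seq), nc_occupied[sc], f"s{i + 1}")
        )

    realized: list[RealizedPlant] = []
    intronic_pool = [
        (g, iv) for g in genes if g.biotype == "protein_coding"
        for iv in g.introns if iv[1] - iv[0] >= 300
    ]
    rng.shuffle(intronic_pool)

    for key in order:
        members = units[key]
        ctx = members[0].context
        sizes = [2 * p.stem_length + p.loop_length + pad_n for p in members]
        if ctx.startswith("intronic"):
            placed = False
            for gi in range(len(intronic_pool)):
                g, (is_, ie_) = intronic_pool[gi]
                gaps = [int(rng.integers(30, 60)) for _ in range(len(members) - 1)]
                need = sum(sizes) + sum(gaps)
                if ie_ - is_ - 20 < need:
                    continue
                start0 = is_ + 10 + int(rng.integers(0, ie_ - is_ - 20 - need + 1))
                pos = start0
                strand = g.strand if ctx == "intronic_sense" else (
                    "-" if g.strand == "+" else "+")
                for p, size in zip(members, sizes):
                    hp, m5, m3 = _design_hairpin(p, rng)
                    hs, he = _write_plant(genome, g.scaffold_id, pos, hp, strand)
                    realized.append(
                        RealizedPlant(p, g.scaffold_id, hs, he, strand, hp, m5, m3)
                    )
                    pos += size + (gaps.pop(0) if gaps else 0)
                intronic_pool.pop(gi)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"no intron can host unit {key} ({len(members)} plants)"
                )
        else:
            sc, s, gaps = unit_slot[key]
            pos = s
            strand = "+" if rng.random() < 0.5 else "-"
            g2 = list(gaps)
            for p, size in zip(members, sizes):
                hp, m5, m3 = _design_hairpin(p, rng)
                hs, he = _write_plant(genome, sc, pos, hp, strand)
                realized.append(
                    RealizedPlant(p, sc, hs, he, strand, hp, m5, m3)
                )
                pos += size + (g2.pop(0) if g2 else 0)

    # criterion-1 decoys: copy hairpin (+pad each side) to a second locus
    for plant in realized:
        if plant.spec.violated_criterion != 1:
            continue
        pad = 4
        src_sc = plant.scaffold_id
        region = genome[src_sc][plant.start - pad: plant.end + pad]
        sc, s = c1_slot[plant.precursor_id]
        g = genome[sc]
        genome[sc] = g[:s] + region + g[s + len(region):]
        plant.extra_loci.append((sc, s + pad, s + pad + (plant.end - plant.start)))

    # build the reference catalog from conserved plants
    catalog: list[tuple[str, str, int]] = []
    for i, plant in enumerate(realized):
        if plant.spec.conserved and plant.spec.violated_criterion is None:
            catalog.append(
                (plant.mature_sequence(plant.spec.guide_arm),
                 f"fam{i + 1:03d}", plant.spec.phylostratum)
            )

    truth = SyntheticTruth(realized, genome, genes, catalog)
    if validate:
        _validate_all(truth, rng)
    return truth


def _tags_unique(plant: RealizedPlant, genome: dict[str, str]) -> bool:
    """Each intended mature tag must occur in the genome exactly once per
    planted locus; collisions (e.g. between the restricted-alphabet stems
    of weak-fold decoys) would smear read stacks across plants."""
    expected = 1 + len(plant.extra_loci)
    for arm in ("5p", "3p"):
        shift = (2, 2) if (plant.spec.violated_criterion == 6
                           and arm != plant.spec.guide_arm) else (0, 0)
        rec = _arm_read(plant, genome, arm, *shift)
        if rec is None:
            return False
        if disc.count_genomic_loci(rec[0], genome) != expected:
            return False
    return True


def _validate_all(truth: SyntheticTruth, rng: np.random.Generator,
                  max_redraws: int = 40) -> None:
    """Redraw any plant whose engine verdict does not match its label."""
    for plant in truth.plants:
        for attempt in range(max_redraws):
            ok, failed = validate_plant(plant, truth.genome, truth.catalog)
            if ok and _tags_unique(plant, truth.genome):
                break
            hp, m5, m3 = _design_hairpin(plant.spec, rng)
            gseq = hp if plant.strand == "+" else revcomp(hp)
            sc = plant.scaffold_id
            g = truth.genome[sc]
            truth.genome[sc] = g[:plant.start] + gseq + g[plant.end:]
            plant.hairpin, plant.mature_5p, plant.mature_3p = hp, m5, m3
            for (esc, es, ee) in plant.extra_loci:  # keep criterion-1 copies
                pad = 4
                region = truth.genome[sc][plant.start - pad: plant.end + pad]
                g2 = truth.genome[esc]
                truth.genome[esc] = g2[:es - pad] + region + g2[ee + pad:]
        else:
            raise PlacementError(
                f"{plant.precursor_id}: could not realise label "
                f"{plant.spec.violated_criterion} (last verdict {sorted(failed)})"
            )


# ------------------------------------------------------------ read model


@dataclass
class NoiseModel:
    five_prime_jitter_rate: float = 0.05
    background_rate: float = 0.05
    count_dispersion: float = 8.0  # NB size parameter; larger = closer to Poisson
    qc_fail_rate: float = 0.02
    guide_star_ratio: float = 10.0
    co_mature_ratio: float = 1.5


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))




def simulate_reads(
    truth: SyntheticTruth,
    samples: SampleSheet,
    noise: NoiseModel | None = None,
    seed: int = 0,
    depth: float | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-sample reads as (read_id, sequence, quality-string) lists.

    Counts per (plant, sample, arm) are NB draws around the plant's
    expression profile, with two generator guarantees that keep criterion-4
    labels exact: a criterion-4 decoy's all-sample total is clamped below
    50 and any other plant's total is floored at 60.  Decoy read geometry
    (5'-end splits, star offsets) follows the violated criterion.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    sample_ids = samples.sample_ids
    for p in truth.plants:
        unknown = set(p.spec.expression_profile) - set(sample_ids)
        if unknown:
            raise ValueError(f"unknown sample id(s) {sorted(unknown)}")

    counts: dict[tuple[str, str, str], int] = {}
    for plant in truth.plants:
        spec = plant.spec
        ratio = noise.co_mature_ratio if spec.co_mature else noise.guide_star_ratio
        star_arm = "3p" if spec.guide_arm == "5p" else "5p"
        scale = depth if depth is not None else 1.0
        totals = 0
        for sid in sample_ids:
            mean = spec.expression_profile.get(sid, 0.0) * scale
            cg = _nb_draw(rng, mean, noise.count_dispersion)
            cs = _nb_draw(rng, mean / ratio, noise.count_dispersion)
            counts[(plant.precursor_id, spec.guide_arm, sid)] = cg
            counts[(plant.precursor_id, star_arm, sid)] = cs
            totals += cg + cs
        if spec.violated_criterion == 4:
            # clamp below the 50-read criterion, both arms observed
            target = 35
            if totals > target:
                keys = [(plant.precursor_id, a, sid) for a in ("5p", "3p")
                        for sid in sample_ids]
                vals = np.array([counts[k] for k in keys], dtype=float)
                vals = np.floor(vals * target / totals).astype(int)
                for k, v in zip(keys, vals):
                    counts[k] = int(v)
            best = max(sample_ids,
                       key=lambda s: spec.expression_profile.get(s, 0.0))
            counts[(plant.precursor_id, spec.guide_arm, best)] = max(
                counts[(plant.precursor_id, spec.guide_arm, best)], 20)
            counts[(plant.precursor_id, star_arm, best)] = max(
                counts[(plant.precursor_id, star_arm, best)], 3)
        else:
            # floor: keep clear of the 50-read boundary
            best = max(sample_ids,
                       key=lambda s: spec.expression_profile.get(s, 0.0))
            if totals < 60:
                counts[(plant.precursor_id, spec.guide_arm, best)] += 60 - totals
            if all(counts[(plant.precursor_id, star_arm, s)] == 0
                   for s in sample_ids):
                counts[(plant.precursor_id, star_arm, best)] += max(
                    3, int(60 / ratio))

    truth.emitted = dict(counts)

    # excluded intervals for background draws
    bg_intervals: list[tuple[str, int, int]] = []
    for g in truth.genes:
        if g.biotype == "protein_coding":
            bg_intervals += [(g.scaffold_id, s, e) for s, e in g.exons]
        else:
            s, e = g.span
            bg_intervals.append((g.scaffold_id, s, e))

    out: dict[str, list[tuple[str, str, str]]] = {sid: [] for sid in sample_ids}
    for sid in sample_ids:
        reads: list[str] = []
        for plant in truth.plants:
            spec = plant.spec
            for arm in ("5p", "3p"):
                n = counts.get((plant.precursor_id, arm, sid), 0)
                if n == 0:
                    continue
                is_guide = arm == spec.guide_arm
                if spec.violated_criterion == 3 and is_guide:
                    split = rng.multinomial(n, [0.5, 0.3, 0.2])
                    shifts = [(0, 0)] * split[0] + [(1, 0)] * split[1] + \
                             [(-1, 0)] * split[2]
                elif spec.violated_criterion == 6 and not is_guide:
                    shifts = [(2, 2)] * n
                elif spec.violated_criterion is not None:
                    # decoys other than criterion 3 emit clean 5' ends so
                    # their label stays a single-criterion failure
                    shifts = [(0, 0)] * n
                else:
                    n_jit = rng.binomial(n, noise.five_prime_jitter_rate)
                    dirs = rng.choice([-1, 1], size=n_jit)
                    shifts = [(0, 0)] * (n - n_jit) + [(int(d), 0) for d in dirs]
                for s5, s3 in shifts:
                    rec = _arm_read(plant, truth.genome, arm, s5, s3)
                    if rec is not None:
                        reads.append(rec[0])
        n_plant = len(reads)
        n_bg = int(round(noise.background_rate * n_plant
                         / max(1e-9, 1 - noise.background_rate)))
        truth.background[sid] = n_bg
        plant_loci: dict[str, list[tuple[int, int]]] = {}
        for p in truth.plants:
            plant_loci.setdefault(p.scaffold_id, []).append(
                (p.start - 30, p.end + 30))
            for esc, es, ee in p.extra_loci:
                plant_loci.setdefault(esc, []).append((es - 30, ee + 30))
        for _ in range(n_bg):
            size = int(rng.integers(18, 27))
            for _try in range(20):  # keep degradation out of planted loci
                if bg_intervals and rng.random() < 0.5:
                    sc, s, e = bg_intervals[int(rng.integers(len(bg_intervals)))]
                    pos = int(rng.integers(s, e - size)) if e - s > size else s
                else:
                    sc = list(truth.genome)[int(rng.integers(len(truth.genome)))]
                    pos = int(rng.integers(0, len(truth.genome[sc]) - size))
                if not any(pos < e and s < pos + size
                           for s, e in plant_loci.get(sc, [])):
                    break
            frag = truth.genome[sc][pos: pos + size]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads.append(frag)
        # a slice of extra reads that must fail QC
        n_bad = rng.binomial(len(reads), noise.qc_fail_rate)
        truth.qc_fail[sid] = int(n_bad)
        bad_idx = rng.choice(len(reads), size=n_bad, replace=False) if n_bad else []
        order = rng.permutation(len(reads))
        good_q = "I"  # Q40
        for i, ridx in enumerate(order):
            seq = reads[int(ridx)]
            out[sid].append((f"{sid}_r{i:06d}", seq, good_q * len(seq)))
        for j, ridx in enumerate(bad_idx):
            seq = reads[int(ridx)]
            qual = "*" * 5 + good_q * (len(seq) - 5)  # five Q9 bases
            out[sid].append((f"{sid}_bad{j:04d}", seq, qual))
    return out


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ------------------------------------------------- expression profiles


def stage_peaked_profile(
    rank: int, max_rank: int, samples: SampleSheet,
    base_mean: float = 20.0, peak_mean: float = 80.0,
    peak_stage_order: int = 4, width: float = 1.5,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Phylostratum-structured expression: old ranks flat across stages,
    young ranks peaked around mid-development; organs/mixtures get a
    moderate flat level."""
    youngness = (rank - 1) / max(1, max_rank - 1)
    prof = {}
    for s in samples:
        if s.group == "development":
            flat = base_mean * (1.2 - 0.4 * youngness)
            peak = peak_mean * youngness * np.exp(
                -((s.stage_order - peak_stage_order) ** 2) / (2 * width ** 2)
            )
            prof[s.sample_id] = flat * (1 - youngness) + peak + 2.0
        else:
            prof[s.sample_id] = base_mean * 0.6 + 2.0
    return prof


def simulate_stage_counts(
    n_mirnas: int, n_stages: int, seed: int,
    peak_stage: int | None = None, max_rank: int = 6,
    base_mean: float = 30.0, peak_mean: float = 150.0,
    dispersion: float = 8.0,
):
    """Stand-alone count simulator for miRPAI recovery experiments:
    returns (counts DataFrame [miRNA x stage], ranks, designed peak stage
    index)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    if peak_stage is None:
        peak_stage = n_stages // 2
    stages = [f"stage{j + 1}" for j in range(n_stages)]
    ranks = {}
    rows = np.zeros((n_mirnas, n_stages), dtype=int)
    for i in range(n_mirnas):
        rank = int(rng.integers(1, max_rank + 1))
        ranks[f"mir{i + 1:04d}"] = rank
        youngness = (rank - 1) / (max_rank - 1)
        for j in range(n_stages):
            flat = base_mean * (1.3 - youngness)
            peak = peak_mean * youngness * np.exp(-((j - peak_stage) ** 2) / 2.0)
            rows[i, j] = _nb_draw(rng, flat + peak, dispersion)
    counts = pd.DataFrame(rows, index=list(ranks), columns=stages)
    return counts, ranks, peak_stage


# ---------------------------------------------------------- truth output


def write_truth(truth: SyntheticTruth, tsv_path: str | Path,
                json_path: str | Path | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("precursor_id\tscaffold\tstart\tend\tstrand\tcontext\t"
                 "cluster_id\tphylostratum\tviolated_criterion\tguide_arm\t"
                 "conserved\tn_loci\n")
        for p in truth.plants:
            s = p.spec
            fh.write(
                f"{p.precursor_id}\t{p.scaffold_id}\t{p.start}\t{p.end}\t"
                f"{p.strand}\t{s.context}\t{s.cluster_id or ''}\t"
                f"{s.phylostratum}\t{s.violated_criterion or ''}\t"
                f"{s.guide_arm}\t{int(s.conserved)}\t{1 + len(p.extra_loci)}\n"
            )
    if json_path is not None:
        payload = {
            "plants": [
                {
                    "precursor_id": p.precursor_id,
                    "scaffold": p.scaffold_id,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "context": p.spec.context,
                    "cluster_id": p.spec.cluster_id,
                    "phylostratum": p.spec.phylostratum,
                    "violated_criterion": p.spec.violated_criterion,
                    "guide_arm": p.spec.guide_arm,
                    "extra_loci": p.extra_loci,
                    "mature_5p": p.mature_genomic("5p"),
                    "mature_3p": p.mature_genomic("3p"),
                }
                for p in truth.plants
            ],
            "emitted": {
                f"{k[0]}|{k[1]}|{k[2]}": v for k, v in truth.emitted.items()
            },
            "background": truth.background,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ------------------------------------------------------- study designs


def study_plants(
    samples: SampleSheet,
    n_true: int = 40,
    n_decoys_per_criterion: int = 10,
    seed: int = 0,
    p_intronic_sense: float = 0.38,
    p_intronic_antisense: float = 0.12,
    n_clusters: int = 4,
    cluster_size: int = 3,
    max_rank: int = 6,
) -> list[PlantSpec]:
    """The default synthetic study: true plants with a phylostratum-
    structured expression design and per-criterion decoy sets."""
    rng = np.random.default_rng(seed)
    specs: list[PlantSpec] = []
    contexts = ["intronic_sense", "intronic_antisense", "intergenic"]
    probs = [p_intronic_sense, p_intronic_antisense,
             1 - p_intronic_sense - p_intronic_antisense]
    clustered = min(n_true, n_clusters * cluster_size)
    for i in range(n_true):
        rank = int(rng.integers(1, max_rank + 1))
        cluster_id = None
        ctx = contexts[int(rng.choice(3, p=probs))]
        if i < clustered:
            k = i // cluster_size
            cluster_id = f"truthcluster{k + 1}"
            # the first cluster sits in a host-gene intron (the classic
            # intronic-cluster arrangement); the rest are intergenic
            ctx = "intronic_sense" if k == 0 else "intergenic"
        specs.append(
            PlantSpec(
                precursor_id=f"true{i + 1:03d}",
                context=ctx,
                cluster_id=cluster_id,
                phylostratum=rank,
                violated_criterion=None,
                expression_profile=stage_peaked_profile(rank, max_rank, samples),
                guide_arm="5p" if rng.random() < 0.6 else "3p",
                co_mature=rng.random() < 0.1,
                conserved=rank < max_rank and rng.random() < 0.7,
            )
        )
    # two organ markers: strongly organ-restricted expression so the
    # specificity screen has designed positives (mantle and muscle)
    markers = [s for s in specs[clustered:] if not s.co_mature][:2]
    organ_sets = [{"t01.Mao", "t02.Mai"}, {"t05.Amu"}]
    for spec, organs in zip(markers, organ_sets):
        spec.expression_profile = {
            s.sample_id: (120.0 if s.sample_id in organs else 3.0)
            for s in samples
        }
    k = 0
    for crit in range(1, 7):
        for j in range(n_decoys_per_criterion):
            k += 1
            rank = int(rng.integers(1, max_rank + 1))
            specs.append(
                PlantSpec(
                    precursor_id=f"decoy_c{crit}_{j + 1:02d}",
                    context="intergenic",
                    cluster_id=None,
                    phylostratum=rank,
                    violated_criterion=crit,
                    expression_profile=stage_peaked_profile(rank, max_rank,
                                                            samples),
                    conserved=False,
                )
            )
    return specs
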