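"""Shared domain objects.

Coordinate convention, binding everywhere in the package: internal
coordinates are 0-based half-open on the forward strand of a scaffold;
on-disk GFF3 is 1-based inclusive.  DNA alphabet is {A,C,G,T,N}; RNA input
is normalised to DNA (U -> T) at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BIOTYPES = ("protein_coding", "rRNA", "tRNA", "snRNA", "repeat")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand, a biotype and a sorted list of exon intervals.

    The gene span is [first exon start, last exon end); introns are the
    gaps between consecutive exons.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str  # development | organ | mixture
    stage_order: int | None = None
    merge_group: str | None = None

    def __post_init__(self) -> None:
        if self.group not in ("development", "organ", "mixture"):
            raise ValueError(f"bad group {self.group!r} for {self.sample_id}")
        if self.group == "development" and self.stage_order is None:
            raise ValueError(f"development sample {self.sample_id} needs stage_order")


class SampleSheet:
    """Ordered, unique collection of samples."""

    def __init__(self, samples: list[Sample]):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample sheet")
        dev = [s for s in samples if s.group == "development"]
        orders = [s.stage_order for s in dev]
        if len(set(orders)) != len(orders):
            raise ValueError("development stage_order values must be distinct")
        self.samples = list(samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def development_samples(self) -> list[Sample]:
        dev = [s for s in self.samples if s.group == "development"]
        return sorted(dev, key=lambda s: s.stage_order)

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def oyster_sample_sheet() -> SampleSheet:
    """The 21-library layout the study design assumes: an egg-to-juvenile
    developmental series (s01..s10), eight adult organs (t01..t08, the two
    mantle parts sharing a merge group), and three mixtures."""
    dev = ["s01.E", "s02.B", "s03.T1", "s04.T2", "s05.D",
           "s06.U", "s07.P1", "s08.P2", "s09.S", "s10.J"]
    organs = ["t01.Mao", "t02.Mai", "t03.Dgl", "t04.Gil",
              "t05.Amu", "t06.Hem", "t07.Lpa", "t08.Fgo"]
    mixtures = ["m01.Early", "m02.Late", "m03.Adult"]
    samples = [Sample(sid, "development", i + 1) for i, sid in enumerate(dev)]
    samples += [
        Sample(sid, "organ", None, "mantle" if sid in ("t01.Mao", "t02.Mai") else None)
        for sid in organs
    ]
    samples += [Sample(sid, "mixture") for sid in mixtures]
    return SampleSheet(samples)


@dataclass
class ReadTag:
    """A distinct small-RNA sequence with per-sample read counts."""

    sequence: str
    per_sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class TagAlignment:
    """An exact full-length placement of a tag on the genome."""

    tag: ReadTag
    scaffold_id: str
    start: int  # 0-based, forward-strand coordinate of leftmost base
    strand: str
    n_genomic_loci: int = 1

    @property
    def end(self) -> int:
        return self.start + len(self.tag.sequence)
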