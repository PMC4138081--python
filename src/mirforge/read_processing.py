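"""Quality filtering, tag collapsing, exact genome mapping and removal of
reads attributable to annotated non-miRNA classes.

QC keeps a read iff it is >= 18 nt, its mean per-base error probability
(10^(-Q/10)) is < 0.01, at most 4 bases have Q < 10 and at most 6 bases
have Q < 13.  Mapping is exact full-length matching on both strands,
seeded on the first 18 nt; multi-mapping tags are kept with their locus
count recorded (the single-locus decision belongs to criterion 1 at the
precursor level).  Exclusion is strand-blind with a >= 1 bp overlap rule,
the most exclusionary reading of "mapped to annotated exons, repeats,
rRNAs, tRNAs, or snRNAs".
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .formats_io import FormatError
from .models import GeneModel, ReadTag, TagAlignment, revcomp

MIN_READ_LENGTH = 18
MAX_MEAN_ERROR = 0.01
MAX_BASES_Q10 = 4
MAX_BASES_Q13 = 6

_SEED_K = 18  # = MIN_READ_LENGTH, so every valid tag has a full seed

_PHRED_ERR = [10.0 ** (-q / 10.0) for q in range(100)]


@dataclass
class QCResult:
    passed: list[tuple[str, list[int]]] = field(default_factory=list)
    rejected: dict[str, int] = field(
        default_factory=lambda: {"length": 0, "mean_error": 0, "q10": 0, "q13": 0}
    )

    @property
    def n_passed(self) -> int:
        return len(self.passed)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


def qc_read(sequence: str, qualities: list[int]) -> str | None:
    """None if the read passes QC, else the (first) rejection reason.
    Reasons are checked in the order length, mean_error, q10, q13 so the
    tally partitions all rejections."""
    if len(sequence) != len(qualities):
        raise FormatError("quality string length != sequence length")
    if len(sequence) < MIN_READ_LENGTH:
        return "length"
    mean_err = sum(_PHRED_ERR[min(q, 99)] for q in qualities) / len(qualities)
    if not mean_err < MAX_MEAN_ERROR:
        return "mean_error"
    if sum(1 for q in qualities if q < 10) > MAX_BASES_Q10:
        return "q10"
    if sum(1 for q in qualities if q < 13) > MAX_BASES_Q13:
        return "q13"
    return None


def qc_filter(fastq_path: str | Path) -> QCResult:
    """Filter a FASTQ file; returns passing (sequence, qualities) records
    and a rejection tally by reason."""
    res = QCResult()
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq).upper().replace("U", "T")
        quals = rec.letter_annotations["phred_quality"]
        reason = qc_read(seq, quals)
        if reason is None:
            res.passed.append((seq, quals))
        else:
            res.rejected[reason] += 1
    return res


def collapse(
    reads: list[tuple[str, list[int]]] | list[str],
    sample_id: str,
    into: dict[str, ReadTag] | None = None,
) -> dict[str, ReadTag]:
    """Collapse QC-passed reads of one sample into distinct tags; pass
    ``into`` to merge several samples (per-sample maps summed)."""
    tags = into if into is not None else {}
    for item in reads:
        seq = item[0] if isinstance(item, tuple) else item
        tag = tags.get(seq)
        if tag is None:
            tag = tags[seq] = ReadTag(seq)
        tag.per_sample_counts[sample_id] = tag.per_sample_counts.get(sample_id, 0) + 1
    return tags


@dataclass
class MapResult:
    alignments: list[TagAlignment]
    unmapped: list[ReadTag]

    @property
    def n_unmapped_reads(self) -> int:
        return sum(t.total_count for t in self.unmapped)


def map_exact(tags: dict[str, ReadTag] | list[ReadTag],
              genome: dict[str, str]) -> MapResult:
    """All exact full-length placements of every tag on both strands."""
    taglist = list(tags.values()) if isinstance(tags, dict) else list(tags)
    want: dict[str, list[tuple[ReadTag, str]]] = defaultdict(list)
    for tag in taglist:
        want[tag.sequence[:_SEED_K]].append((tag, "+"))
        rc = revcomp(tag.sequence)
        want[rc[:_SEED_K]].append((tag, "-"))
    hits: dict[int, list[tuple[str, int, str]]] = defaultdict(list)  # id(tag)
    for scaffold, seq in genome.items():
        n = len(seq)
        for pos in range(n - _SEED_K + 1):
            seed = seq[pos : pos + _SEED_K]
            for tag, strand in want.get(seed, ()):
                full = tag.sequence if strand == "+" else revcomp(tag.sequence)
                if seq.startswith(full, pos):
                    hits[id(tag)].append((scaffold, pos, strand))
    alignments, unmapped = [], []
    for tag in taglist:
        placements = hits.get(id(tag), [])
        if not placements:
            unmapped.append(tag)
            continue
        for scaffold, pos, strand in placements:
            alignments.append(
                TagAlignment(tag, scaffold, pos, strand, n_genomic_loci=len(placements))
            )
    return MapResult(alignments, unmapped)


_CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "repeat", "exon")


class ExclusionIndex:
    """Sorted-interval index of excluded regions per scaffold with class
    labels; overlap >= 1 bp, strand-blind."""

    def __init__(self, annotations: list[GeneModel]):
        raw: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for g in annotations:
            if g.biotype == "protein_coding":
                for s, e in g.exons:
                    raw[g.scaffold_id].append((s, e, "exon"))
            else:
                s, e = g.span
                raw[g.scaffold_id].append((s, e, g.biotype))
        self._starts: dict[str, list[int]] = {}
        self._ivals: dict[str, list[tuple[int, int, str]]] = {}
        for scaffold, ivals in raw.items():
            ivals.sort()
            self._ivals[scaffold] = ivals
            self._starts[scaffold] = [s for s, _, _ in ivals]

    def overlap_classes(self, scaffold: str, start: int, end: int) -> set[str]:
        ivals = self._ivals.get(scaffold)
        if not ivals:
            return set()
        out = set()
        # intervals are short (exons/ncRNAs); scan back from insertion point
        i = bisect_right(self._starts[scaffold], end - 1) - 1
        while i >= 0:
            s, e, cls = ivals[i]
            if e > start:
                out.add(cls)
            elif start - s > 1_000_000:  # far past any plausible feature
                break
            i -= 1
        return out


@dataclass
class ExclusionResult:
    retained: list[TagAlignment]
    excluded: list[TagAlignment]
    tally: dict[str, int]  # class -> excluded alignment count


def exclude_annotated(
    alignments: list[TagAlignment], annotations: list[GeneModel]
) -> ExclusionResult:
    """Drop alignments overlapping (>= 1 bp, either strand) protein-coding
    exons or repeat/rRNA/tRNA/snRNA intervals; tally by class with priority
    rRNA > tRNA > snRNA > repeat > exon for multi-class overlaps."""
    index = ExclusionIndex(annotations)
    retained, excluded = [], []
    tally = {c: 0 for c in _CLASS_PRIORITY}
    for a in alignments:
        classes = index.overlap_classes(a.scaffold_id, a.start, a.end)
        if not classes:
            retained.append(a)
            continue
        excluded.append(a)
        for cls in _CLASS_PRIORITY:
            if cls in classes:
                tally[cls] += 1
                break
    return ExclusionResult(retained, excluded, tally)
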