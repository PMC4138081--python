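"""Genomic context of accepted precursors: intronic/intergenic
classification, the contiguous-window null model with a chi-square
comparison, flank-extension profiles and 10-kb cluster detection.

"Gene region" throughout means the gene span (first exon start to last
exon end), introns included; only protein-coding genes define context.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .discovery import CandidatePrecursor
from .models import GeneModel

DEFAULT_WINDOW = 79  # bp, the average precursor length
DEFAULT_FLANKS = (0, 500, 1000, 2000)
DEFAULT_MAX_GAP = 10_000  # bp, cluster definition


@dataclass
class AnnotatedPrecursor:
    precursor: CandidatePrecursor
    location_class: str  # intronic_sense | intronic_antisense | exonic | intergenic
    host_gene_id: str | None
    distance_to_nearest_gene: int
    cluster_id: str | None = None
    boundary_flag: bool = False  # spans a gene boundary, classed by majority


@dataclass
class WindowNullResult:
    window_length: int
    flank: int
    n_windows: int
    n_overlapping_gene: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping_gene / self.n_windows


def _coding(genes: list[GeneModel]) -> list[GeneModel]:
    return [g for g in genes if g.biotype == "protein_coding"]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_location(
    precursor: CandidatePrecursor, genes: list[GeneModel]
) -> AnnotatedPrecursor:
    """Exonic if the precursor overlaps an exon of a host gene; else
    intronic (sense/antisense) if inside a gene span; else intergenic with
    the distance to the nearest gene span recorded.  A precursor spanning a
    gene boundary is classed by majority overlap and flagged."""
    s, e = precursor.interval
    best_host: GeneModel | None = None
    best_ov = 0
    min_dist: int | None = None
    for g in _coding(genes):
        if g.scaffold_id != precursor.scaffold_id:
            continue
        gs, ge = g.span
        ov = _overlap((s, e), (gs, ge))
        if ov > best_ov:
            best_ov, best_host = ov, g
        if ov == 0:
            dist = gs - e if gs >= e else s - ge
            if min_dist is None or dist < min_dist:
                min_dist = dist
    if best_host is None:
        return AnnotatedPrecursor(
            precursor, "intergenic", None,
            -1 if min_dist is None else min_dist,
        )
    boundary = best_ov < (e - s)
    if best_ov * 2 < (e - s):  # majority outside every gene span
        return AnnotatedPrecursor(precursor, "intergenic", None, 0,
                                  boundary_flag=True)
    exon_ov = sum(_overlap((s, e), ex) for ex in best_host.exons)
    if exon_ov > 0:
        cls = "exonic"
    elif precursor.strand == best_host.strand:
        cls = "intronic_sense"
    else:
        cls = "intronic_antisense"
    return AnnotatedPrecursor(
        precursor, cls, best_host.gene_id, 0, boundary_flag=boundary
    )


def window_null(
    genome: dict[str, str],
    genes: list[GeneModel],
    window_length: int = DEFAULT_WINDOW,
    flank: int = 0,
    keep_partial_half: bool = True,
    sense_strand: str | None = None,
) -> WindowNullResult:
    """Tile every scaffold from position 0 into contiguous windows of
    ``window_length``; the final partial window is kept iff >= half length
    (``keep_partial_half``).  Each window, extended by ``flank`` on both
    sides (clamped to the scaffold), counts as overlapping when it shares
    >= 1 bp with any gene span.  ``sense_strand`` restricts the gene set to
    one strand, mirroring the sense-strand-restricted variant."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in _coding(genes):
        if sense_strand is not None and g.strand != sense_strand:
            continue
        spans.setdefault(g.scaffold_id, []).append(g.span)
    for v in spans.values():
        v.sort()
    n_windows = 0
    n_hit = 0
    for scaffold, seq in genome.items():
        L = len(seq)
        gspans = spans.get(scaffold, [])
        pos = 0
        while pos < L:
            wend = min(L, pos + window_length)
            if wend - pos < window_length and not (
                keep_partial_half and (wend - pos) * 2 >= window_length
            ):
                break
            n_windows += 1
            fs, fe = max(0, pos - flank), min(L, wend + flank)
            if any(gs < fe and fs < ge for gs, ge in gspans):
                n_hit += 1
            pos += window_length
    return WindowNullResult(window_length, flank, n_windows, n_hit)


def compare_proportions(k1: int, n1: int, k2: int, n2: int):
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[k1, n1-k1], [k2, n2-k2]]; returns (statistic, p, low_expected_flag)."""
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("invalid counts")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    row = [sum(r) for r in table]
    col = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    total = row[0] + row[1]
    if 0 in row or 0 in col:
        raise ValueError("zero margin: chi-square undefined")
    stat = 0.0
    low_expected = False
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / total
            if expected < 5:
                low_expected = True
            stat += (table[i][j] - expected) ** 2 / expected
    p = float(chi2.sf(stat, df=1))
    return stat, p, low_expected


def find_clusters(
    precursors: list[AnnotatedPrecursor], max_gap: int = DEFAULT_MAX_GAP
) -> list[AnnotatedPrecursor]:
    """Single-linkage chaining on each scaffold: consecutive precursors
    whose end-to-start gap is <= max_gap share a cluster (strand-blind).
    Singletons keep cluster_id None.  Assigns cluster ids in place and
    returns the list sorted by (scaffold, start)."""
    ordered = sorted(
        precursors, key=lambda ap: (ap.precursor.scaffold_id, ap.precursor.interval)
    )
    chains: list[list[AnnotatedPrecursor]] = []
    for ap in ordered:
        if chains:
            prev = chains[-1][-1]
            same = prev.precursor.scaffold_id == ap.precursor.scaffold_id
            gap = ap.precursor.interval[0] - max(
                m.precursor.interval[1] for m in chains[-1]
            )
            if same and gap <= max_gap:
                chains[-1].append(ap)
                continue
        chains.append([ap])
    cluster_n = 0
    for chain in chains:
        if len(chain) == 1:
            chain[0].cluster_id = None
            continue
        cluster_n += 1
        for ap in chain:
            ap.cluster_id = f"cluster{cluster_n:02d}"
    return ordered


def flank_extension_profile(
    precursors: list[AnnotatedPrecursor],
    genome: dict[str, str],
    genes: list[GeneModel],
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
    window_length: int = DEFAULT_WINDOW,
) -> list[dict]:
    """For each flank, the fraction of precursors whose flank-extended
    interval overlaps a gene span, paired with the matched window-null
    fraction.  Fractions are monotone non-decreasing in the flank."""
    if list(flanks) != sorted(flanks):
        raise ValueError("flanks must be sorted ascending")
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in _coding(genes):
        spans.setdefault(g.scaffold_id, []).append(g.span)
    rows = []
    for flank in flanks:
        n_intragenic = 0
        for ap in precursors:
            s, e = ap.precursor.interval
            fs, fe = s - flank, e + flank
            gspans = spans.get(ap.precursor.scaffold_id, [])
            if any(gs < fe and fs < ge for gs, ge in gspans):
                n_intragenic += 1
        null = window_null(genome, genes, window_length, flank)
        rows.append(
            {
                "flank": flank,
                "n_precursors": len(precursors),
                "n_intragenic": n_intragenic,
                "precursor_fraction": (
                    n_intragenic / len(precursors) if precursors else 0.0
                ),
                "null_fraction": null.fraction,
                "null": null,
            }
        )
    return rows
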