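"""Readers and writers for the external formats the pipeline touches.

FASTA via Biopython; GFF3 restricted to the gene/exon (+ ncRNA/repeat)
subset the pipeline needs; TSV matrices via pandas.  All validation is
strict: malformed input raises ``FormatError`` naming the offending record.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .models import GeneModel, Sample, SampleSheet

GENOME_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the format contract."""


# ---------------------------------------------------------------- FASTA


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {scaffold_id: sequence}.

    Sequences are uppercased and U is normalised to T; any other letter
    outside {A,C,G,T,N} is an error.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate scaffold id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------- GFF3


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


_BIOTYPE_FEATURES = {"rRNA", "tRNA", "snRNA", "repeat", "repeat_region"}


def read_gff_annotations(
    path: str | Path, genome: dict[str, str]
) -> list[GeneModel]:
    """Read gene models (gene + exon features) and ncRNA/repeat intervals.

    On-disk coordinates are 1-based inclusive and converted to 0-based
    half-open.  ``rRNA``/``tRNA``/``snRNA``/``repeat`` features become
    single-exon gene models of that biotype.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    exons: list[tuple[str, int, int]] = []  # (parent, start, end)
    others: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            scaffold, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if scaffold not in genome:
                raise FormatError(f"{path}:{lineno}: unknown scaffold {scaffold!r}")
            if end1 > len(genome[scaffold]):
                raise FormatError(
                    f"{path}:{lineno}: feature beyond scaffold length"
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "scaffold": scaffold,
                    "strand": strand,
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon without Parent")
                exons.append((parent, start, end))
            elif ftype in _BIOTYPE_FEATURES:
                biotype = "repeat" if ftype == "repeat_region" else ftype
                fid = attrs.get("ID", f"{ftype}_{scaffold}_{start}")
                others.append(
                    GeneModel(fid, scaffold, strand if strand in "+-" else "+",
                              ((start, end),), biotype)
                )
            # other feature types ignored
    by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    for parent, start, end in exons:
        if parent not in genes:
            raise FormatError(f"{path}: exon with unknown Parent {parent!r}")
        by_gene[parent].append((start, end))
    models = []
    for gid, info in genes.items():
        ex = sorted(by_gene[gid])
        if not ex:
            raise FormatError(f"{path}: gene {gid!r} has no exons")
        models.append(
            GeneModel(gid, info["scaffold"], info["strand"], tuple(ex), info["biotype"])
        )
    return models + others


def write_gene_gff(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            if g.biotype == "protein_coding":
                fh.write(
                    f"{g.scaffold_id}\tmirforge\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};biotype={g.biotype}\n"
                )
                for i, (xs, xe) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.scaffold_id}\tmirforge\texon\t{xs + 1}\t{xe}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                    )
            else:
                ftype = g.biotype if g.biotype != "repeat" else "repeat_region"
                fh.write(
                    f"{g.scaffold_id}\tmirforge\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )


def write_precursor_gff(precursors, path: str | Path) -> None:
    """Write accepted precursors as miRNA_primary_transcript features with
    child miRNA features (1-based inclusive on disk).

    Accepts ``AnnotatedPrecursor`` objects (with location/cluster fields) or
    bare ``CandidatePrecursor``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ap in precursors:
            cand = getattr(ap, "precursor", ap)
            s, e = cand.interval
            attrs = [f"ID={cand.precursor_id}", f"mfe={cand.mfe:.2f}"]
            if hasattr(ap, "location_class"):
                attrs.append(f"location={ap.location_class}")
                if ap.host_gene_id:
                    attrs.append(f"host_gene={ap.host_gene_id}")
                attrs.append(f"cluster={ap.cluster_id if ap.cluster_id else 'NA'}")
            if cand.verdict is not None:
                v = ",".join(
                    f"c{i}:{'pass' if cand.verdict.per_criterion[i][0] else 'fail'}"
                    for i in range(1, 7)
                )
                attrs.append(f"criteria={v}")
            fh.write(
                f"{cand.scaffold_id}\tmirforge\tmiRNA_primary_transcript\t"
                f"{s + 1}\t{e}\t.\t{cand.strand}\t.\t" + ";".join(attrs) + "\n"
            )
            for m in cand.matures():
                ms, me = m.interval
                fh.write(
                    f"{cand.scaffold_id}\tmirforge\tmiRNA\t{ms + 1}\t{me}\t.\t"
                    f"{cand.strand}\t.\tID={m.mature_id};Parent={cand.precursor_id};"
                    f"arm={m.arm};role={m.role}\n"
                )


def read_precursor_gff(path: str | Path) -> list[dict]:
    """Parse a precursor GFF back into plain dicts (round-trip checking and
    downstream context analysis)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 columns")
            scaffold, _, ftype, s1, e1, _, strand, _, attr_s = cols
            attrs = _parse_attributes(attr_s)
            out.append(
                {
                    "scaffold_id": scaffold,
                    "type": ftype,
                    "interval": (int(s1) - 1, int(e1)),
                    "strand": strand,
                    "attributes": attrs,
                }
            )
    return out


# ------------------------------------------------------------------ TSV


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV matrix: first column row ids, header row sample ids; all cells
    numeric (scientific notation allowed)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row id(s) {dupes}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    return df


def write_alignment_tsv(alignments, path: str | Path) -> None:
    """The 6-column alignment dump: tag, scaffold, start, strand, count, n_loci."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "scaffold", "start", "strand", "count", "n_loci"])
        for a in alignments:
            w.writerow(
                [a.tag.sequence, a.scaffold_id, a.start, a.strand,
                 a.tag.total_count, a.n_genomic_loci]
            )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """TSV with columns sample_id, group, stage_order, merge_group."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            Sample(
                row["sample_id"],
                row["group"],
                int(row["stage_order"]) if row.get("stage_order", "") else None,
                row["merge_group"] or None,
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group", "stage_order", "merge_group"])
        for s in sheet:
            w.writerow(
                [s.sample_id, s.group,
                 "" if s.stage_order is None else s.stage_order,
                 s.merge_group or ""]
            )


def read_phylostratum_catalog(path: str | Path) -> list[tuple[str, str, int]]:
    """TSV with columns sequence, family, phylostratum (rank; larger = younger)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "family": str})
    entries = []
    for _, row in df.iterrows():
        seq = str(row["sequence"]).upper().replace("U", "T")
        rank = int(row["phylostratum"])
        if rank <= 0:
            raise FormatError(f"{path}: non-positive phylostratum rank {rank}")
        if not 18 <= len(seq) <= 26:
            raise FormatError(f"{path}: catalog sequence length {len(seq)} outside 18-26")
        entries.append((seq, str(row["family"]), rank))
    return entries
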