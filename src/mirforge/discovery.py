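"""Candidate precursor extraction and the six-criterion annotation engine.

From retained read alignments, read stacks seed candidate windows; each
window is folded, trimmed to the read-defined precursor, refolded, and
judged against the six annotation criteria:

1. the precursor sequence maps to a single genomic locus;
2. the precursor folds with MFE below -21 kcal/mol (active backend);
3. the 5'-end of the major reads is consistent on both arms (modal
   5'-end fraction >= 0.8 by default);
4. mature reads come from both arms, with >= 50 reads combined over all
   samples;
5. the two modal matures share >= 16 complementary (paired) positions;
6. the mature is conserved in widely diverged taxa, or the duplex shows
   the Dicer-signature 2-nt 3' overhang at both ends.

Trimming before scoring matters: the MFE criterion is about the precursor
hairpin, not about whatever flanking sequence the extraction window drags
in, and duplex geometry is only meaningful on the trimmed hairpin.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .folding import FoldResult, fold
from .homology import match_catalog
from .models import TagAlignment, revcomp

MFE_MAX = -21.0  # kcal/mol, criterion 2 (strict <)
MIN_DUPLEX_PAIRS = 16  # criterion 5
MIN_TOTAL_READS = 50  # criterion 4, combined arms, all samples
MODAL_FRACTION_MIN = 0.8  # criterion 3 quantification of "consistent"
DICER_OVERHANG = 2  # criterion 6, exact
GUIDE_RATIO = 5.0  # guide/star call, strict >
MATURE_MIN_READS = 50  # expression-set retention floor


@dataclass
class ExtractionParams:
    min_stack_reads: int = 10
    flank: int = 8  # nt upstream of the stack 5' end
    window_length: int = 100  # nt, <= 120
    min_window: int = 40  # shorter clipped windows are discarded


@dataclass
class CriteriaThresholds:
    mfe_max: float = MFE_MAX
    min_duplex: int = MIN_DUPLEX_PAIRS
    min_total_reads: int = MIN_TOTAL_READS
    modal_fraction_min: float = MODAL_FRACTION_MIN
    overhang: int = DICER_OVERHANG
    guide_ratio: float = GUIDE_RATIO
    mature_min_reads: int = MATURE_MIN_READS
    multi_locus_whitelist: frozenset[str] = frozenset()  # precursor seqs


@dataclass
class ArmProfile:
    """Read support for one arm, in precursor-local 5'->3' coordinates."""

    arm: str  # 5p | 3p
    read_stack: list[tuple[int, int, int]]  # (local start, local end, count)
    modal_start: int
    modal_length: int
    modal_fraction: float
    total_reads: int

    @property
    def modal_interval(self) -> tuple[int, int]:
        return (self.modal_start, self.modal_start + self.modal_length)


@dataclass
class DuplexGeometry:
    n_complementary: int
    overhang_base_end: int | None  # 3p-mature 3' protrusion, hairpin base side
    overhang_loop_end: int | None  # 5p-mature 3' protrusion, loop side

    @property
    def dicer_signature(self) -> bool:
        return (
            self.overhang_base_end == DICER_OVERHANG
            and self.overhang_loop_end == DICER_OVERHANG
        )


@dataclass
class CriterionVerdict:
    # criterion -> (passed, measured value)
    per_criterion: dict[int, tuple[bool, object]]

    @property
    def accepted(self) -> bool:
        return all(p for p, _ in self.per_criterion.values())

    @property
    def failed(self) -> frozenset[int]:
        return frozenset(c for c, (p, _) in self.per_criterion.items() if not p)


@dataclass
class MatureMiRNA:
    mature_id: str
    precursor_id: str
    arm: str
    sequence: str
    interval: tuple[int, int]  # genomic, 0-based half-open
    role: str  # guide | star | co_mature
    total_reads: int
    in_expression_set: bool
    phylostratum: int | None = None


@dataclass
class CandidatePrecursor:
    precursor_id: str
    scaffold_id: str
    interval: tuple[int, int]  # genomic, trimmed precursor
    strand: str
    sequence: str  # strand-adjusted (5'->3')
    structure: str
    mfe: float
    arm_profiles: dict[str, ArmProfile]
    n_genomic_loci: int
    geometry: DuplexGeometry | None = None
    conserved: bool = False
    verdict: CriterionVerdict | None = None
    _matures: list[MatureMiRNA] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(p.total_reads for p in self.arm_profiles.values())

    def matures(self) -> list[MatureMiRNA]:
        return self._matures

    def local_to_genomic(self, s: int, e: int) -> tuple[int, int]:
        ps, pe = self.interval
        if self.strand == "+":
            return (ps + s, ps + e)
        return (pe - e, pe - s)


# ------------------------------------------------------------ extraction


def _stack_groups(alignments: list[TagAlignment]):
    """Single-linkage grouping of overlapping alignments per (scaffold,
    strand); yields lists of alignments (read stacks)."""
    by_key: dict[tuple[str, str], list[TagAlignment]] = defaultdict(list)
    for a in alignments:
        by_key[(a.scaffold_id, a.strand)].append(a)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda a: (a.start, a.end))
        stack: list[TagAlignment] = []
        max_end = None
        for a in group:
            if max_end is not None and a.start >= max_end:
                yield key, stack
                stack, max_end = [], None
            stack.append(a)
            max_end = a.end if max_end is None else max(max_end, a.end)
        if stack:
            yield key, stack


def _modal_five_prime(stack: list[TagAlignment], strand: str) -> int:
    """Count-weighted modal 5' end in forward coordinates."""
    counts: Counter[int] = Counter()
    for a in stack:
        pos = a.start if strand == "+" else a.end
        counts[pos] += a.tag.total_count
    # tie -> position closest to the 5' side of the stack
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0] if strand == "+" else kv[0]))
    return best[0]


def extract_candidates(
    alignments: list[TagAlignment],
    genome: dict[str, str],
    params: ExtractionParams | None = None,
) -> list[tuple[str, str, int, int]]:
    """Candidate windows (scaffold, strand, start, end), two per qualifying
    stack: the stack read as the 5p arm and as the 3p arm."""
    params = params or ExtractionParams()
    windows: list[tuple[str, str, int, int]] = []
    seen = set()
    for (scaffold, strand), stack in _stack_groups(alignments):
        total = sum(a.tag.total_count for a in stack)
        if total < params.min_stack_reads:
            continue
        L = len(genome[scaffold])
        five = _modal_five_prime(stack, strand)
        if strand == "+":
            # stack as 5p arm: hairpin extends downstream of the 5' end;
            # stack as 3p arm: hairpin extends upstream of the stack 3' end
            stack_3p_end = max(a.end for a in stack)
            cand = [
                (five - params.flank, five - params.flank + params.window_length),
                (stack_3p_end + params.flank - params.window_length,
                 stack_3p_end + params.flank),
            ]
        else:
            stack_3p_end = min(a.start for a in stack)
            cand = [
                (five + params.flank - params.window_length, five + params.flank),
                (stack_3p_end - params.flank,
                 stack_3p_end - params.flank + params.window_length),
            ]
        for ws, we in cand:
            ws, we = max(0, ws), min(L, we)
            if we - ws < params.min_window:
                continue
            if "N" in genome[scaffold][ws:we]:
                continue
            key = (scaffold, strand, ws, we)
            if key not in seen:
                seen.add(key)
                windows.append(key)
    return windows


# ------------------------------------------------------------ evaluation


def count_genomic_loci(sequence: str, genome: dict[str, str]) -> int:
    """Occurrences of a sequence in the genome, both strands."""
    rc = revcomp(sequence)
    n = 0
    for seq in genome.values():
        n += seq.count(sequence)
        if rc != sequence:
            n += seq.count(rc)
    return n


def _loop_midpoint(struct: str) -> float | None:
    """Midpoint of the main hairpin loop: among all loops (an '(' directly
    facing its ')'), the one under the deepest stem.  Small hairpins in
    the flanks of an extraction window must not win over the precursor
    stem.  None if the structure has no pair."""
    best = None
    best_depth = 0
    depth = 0
    last_open = None
    for i, c in enumerate(struct):
        if c == "(":
            depth += 1
            last_open = i
        elif c == ")":
            if last_open is not None and depth > best_depth:
                best_depth = depth
                best = (last_open + i) / 2.0
            last_open = None
            depth -= 1
    return best


def _arm_profile(arm: str, reads: list[tuple[int, int, int]]) -> ArmProfile | None:
    if not reads:
        return None
    total = sum(c for _, _, c in reads)
    start_counts: Counter[int] = Counter()
    for s, _e, c in reads:
        start_counts[s] += c
    modal_start = max(start_counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    modal_count = start_counts[modal_start]
    len_counts: Counter[int] = Counter()
    for s, e, c in reads:
        if s == modal_start:
            len_counts[e - s] += c
    modal_length = max(len_counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return ArmProfile(
        arm=arm,
        read_stack=sorted(reads),
        modal_start=modal_start,
        modal_length=modal_length,
        modal_fraction=modal_count / total,
        total_reads=total,
    )


def duplex_geometry(
    fold_result: FoldResult,
    mature_5p: tuple[int, int],
    mature_3p: tuple[int, int],
) -> DuplexGeometry:
    """Paired-position count and 3' overhangs between the two modal matures,
    from the folded structure.

    Overhangs are measured in the duplex alignment implied by the
    outermost/innermost mature-to-mature structural pair; they may be
    negative (recessed end).
    """
    a5, e5 = mature_5p
    a3, e3 = mature_3p
    pairs = fold_result.pair_map()
    duplex = [
        (p, pairs[p])
        for p in range(a5, e5)
        if p in pairs and a3 <= pairs[p] < e3
    ]
    n_comp = len(duplex)
    if n_comp == 0:
        return DuplexGeometry(0, None, None)
    p_out, q_out = duplex[0]  # outermost pair: smallest 5p position
    p_in, q_in = duplex[-1]  # innermost pair: largest 5p position
    # hairpin-base end: 3p 3' end vs column of the 5p 5' end
    over_base = (p_out - a5) + ((e3 - 1) - q_out)
    # loop end: 5p 3' end vs column of the 3p 5' end
    over_loop = ((e5 - 1) - p_in) + (q_in - a3)
    return DuplexGeometry(n_comp, over_base, over_loop)


def apply_criteria(
    cand: CandidatePrecursor,
    thresholds: CriteriaThresholds | None = None,
) -> CriterionVerdict:
    """Judge an evaluated candidate against the six annotation criteria;
    measured values are recorded alongside every verdict."""
    t = thresholds or CriteriaThresholds()
    p5 = cand.arm_profiles.get("5p")
    p3 = cand.arm_profiles.get("3p")
    per: dict[int, tuple[bool, object]] = {}
    per[1] = (
        cand.n_genomic_loci == 1 or cand.sequence in t.multi_locus_whitelist,
        cand.n_genomic_loci,
    )
    per[2] = (cand.mfe < t.mfe_max, cand.mfe)
    fracs = tuple(p.modal_fraction for p in (p5, p3) if p is not None)
    per[3] = (
        len(fracs) == 2 and all(f >= t.modal_fraction_min for f in fracs),
        fracs,
    )
    n5 = p5.total_reads if p5 else 0
    n3 = p3.total_reads if p3 else 0
    per[4] = (n5 >= 1 and n3 >= 1 and n5 + n3 >= t.min_total_reads, (n5, n3))
    geom = cand.geometry
    ncomp = geom.n_complementary if geom else 0
    per[5] = (ncomp >= t.min_duplex, ncomp)
    overhangs = (
        (geom.overhang_base_end, geom.overhang_loop_end) if geom else (None, None)
    )
    dicer = geom.dicer_signature if geom else False
    per[6] = (cand.conserved or dicer, {"conserved": cand.conserved,
                                        "overhangs": overhangs})
    return CriterionVerdict(per)


def assign_roles(
    cand: CandidatePrecursor,
    thresholds: CriteriaThresholds | None = None,
) -> list[MatureMiRNA]:
    """Guide/star call for an accepted precursor: the more-read arm is the
    guide when the ratio exceeds 5-fold (strict), otherwise both arms are
    co-mature.  Matures under 50 reads total stay in the annotation (as
    star) but are dropped from the expression-analysis set."""
    t = thresholds or CriteriaThresholds()
    p5, p3 = cand.arm_profiles.get("5p"), cand.arm_profiles.get("3p")
    if p5 is None or p3 is None:
        raise ValueError(f"{cand.precursor_id}: both arms required for role call")
    n5, n3 = p5.total_reads, p3.total_reads
    lo, hi = min(n5, n3), max(n5, n3)
    ratio = float("inf") if lo == 0 else hi / lo
    if ratio > t.guide_ratio:
        roles = {"5p": "guide", "3p": "star"} if n5 >= n3 else {"5p": "star",
                                                               "3p": "guide"}
    else:
        roles = {"5p": "co_mature", "3p": "co_mature"}
    matures = []
    for arm, prof in (("5p", p5), ("3p", p3)):
        s, e = prof.modal_interval
        gs, ge = cand.local_to_genomic(s, e)
        matures.append(
            MatureMiRNA(
                mature_id=f"{cand.precursor_id}-{arm}",
                precursor_id=cand.precursor_id,
                arm=arm,
                sequence=cand.sequence[s:e],
                interval=(gs, ge),
                role=roles[arm],
                total_reads=prof.total_reads,
                in_expression_set=prof.total_reads >= t.mature_min_reads,
            )
        )
    return matures


def evaluate_window(
    scaffold: str,
    strand: str,
    window: tuple[int, int],
    alignments: list[TagAlignment],
    genome: dict[str, str],
    thresholds: CriteriaThresholds | None = None,
    conserved_catalog: list[tuple[str, str, int]] | None = None,
    precursor_id: str = "cand",
    backend: str = "builtin",
) -> CandidatePrecursor | None:
    """Fold a window, trim to the read-defined precursor, refold, and judge.

    Returns None when the window cannot define a precursor (no structure,
    or no reads on the window).
    """
    t = thresholds or CriteriaThresholds()
    ws, we = window
    seq_fwd = genome[scaffold][ws:we]
    wseq = seq_fwd if strand == "+" else revcomp(seq_fwd)
    first = fold(wseq, backend=backend)
    mid = _loop_midpoint(first.structure)
    if mid is None:
        return None

    def to_local(a: TagAlignment) -> tuple[int, int]:
        if strand == "+":
            return (a.start - ws, a.end - ws)
        return (we - a.end, we - a.start)

    local_reads: list[tuple[int, int, int]] = []
    for a in alignments:
        if a.scaffold_id != scaffold or a.strand != strand:
            continue
        s, e = to_local(a)
        if s < 0 or e > we - ws:
            continue
        local_reads.append((s, e, a.tag.total_count))
    # arm assignment is read-driven: overlapping reads form stacks; with
    # two or more stacks the outermost pair brackets the duplex and the
    # boundary between them splits the arms.  Only a lone stack falls
    # back on the folded loop position.
    clusters: list[list[tuple[int, int, int]]] = []
    for r in sorted(local_reads):
        if clusters and r[0] < max(e for _s, e, _c in clusters[-1]):
            clusters[-1].append(r)
        else:
            clusters.append([r])
    reads5, reads3 = [], []
    if len(clusters) >= 2:
        first_end = max(e for _s, e, _c in clusters[0])
        last_start = clusters[-1][0][0]
        boundary = (first_end + last_start) / 2.0
        for s, e, c in local_reads:
            (reads5 if (s + e) / 2.0 <= boundary else reads3).append((s, e, c))
    else:
        for s, e, c in local_reads:
            (reads5 if (s + e) / 2.0 <= mid else reads3).append((s, e, c))
    prof5 = _arm_profile("5p", reads5)
    prof3 = _arm_profile("3p", reads3)
    if prof5 is None and prof3 is None:
        return None

    # trim to read-defined precursor and refold
    lo = prof5.modal_start - 2 if prof5 else prof3.modal_start - 2
    hi = (prof3.modal_interval[1] + 2 if prof3 else prof5.modal_interval[1] + 2)
    lo, hi = max(0, lo), min(len(wseq), hi)
    while hi - lo < 40:  # widen symmetric so the fold contract holds
        if lo > 0:
            lo -= 1
        if hi < len(wseq) and hi - lo < 40:
            hi += 1
        if lo == 0 and hi == len(wseq):
            break
    if hi - lo < 40:
        return None
    pseq = wseq[lo:hi]
    final = fold(pseq, backend=backend)

    def shift(prof: ArmProfile | None) -> ArmProfile | None:
        if prof is None:
            return None
        return ArmProfile(
            arm=prof.arm,
            read_stack=[(s - lo, e - lo, c) for s, e, c in prof.read_stack],
            modal_start=prof.modal_start - lo,
            modal_length=prof.modal_length,
            modal_fraction=prof.modal_fraction,
            total_reads=prof.total_reads,
        )

    prof5, prof3 = shift(prof5), shift(prof3)
    if strand == "+":
        ginterval = (ws + lo, ws + hi)
    else:
        ginterval = (we - hi, we - lo)
    geom = None
    if prof5 is not None and prof3 is not None:
        geom = duplex_geometry(final, prof5.modal_interval, prof3.modal_interval)
    conserved = False
    if conserved_catalog:
        for prof in (prof5, prof3):
            if prof is None:
                continue
            s, e = prof.modal_interval
            mseq = pseq[max(0, s):e]
            if len(mseq) >= 8 and match_catalog(mseq, conserved_catalog) is not None:
                conserved = True
    cand = CandidatePrecursor(
        precursor_id=precursor_id,
        scaffold_id=scaffold,
        interval=ginterval,
        strand=strand,
        sequence=pseq,
        structure=final.structure,
        mfe=final.mfe,
        arm_profiles={
            k: v for k, v in (("5p", prof5), ("3p", prof3)) if v is not None
        },
        n_genomic_loci=count_genomic_loci(pseq, genome),
        geometry=geom,
        conserved=conserved,
    )
    cand.verdict = apply_criteria(cand, t)
    if cand.verdict.accepted:
        cand._matures = assign_roles(cand, t)
    return cand


def _dedupe(cands: list[CandidatePrecursor]) -> list[CandidatePrecursor]:
    """Collapse same-strand candidates whose trimmed intervals overlap,
    keeping the best-supported (reads, then MFE, then leftmost)."""
    out: list[CandidatePrecursor] = []
    for c in sorted(
        cands,
        key=lambda c: (-c.total_reads, c.mfe, c.scaffold_id, c.interval[0]),
    ):
        clash = False
        for kept in out:
            if (
                kept.scaffold_id == c.scaffold_id
                and kept.strand == c.strand
                and c.interval[0] < kept.interval[1]
                and kept.interval[0] < c.interval[1]
            ):
                clash = True
                break
        if not clash:
            out.append(c)
    out.sort(key=lambda c: (c.scaffold_id, c.interval[0]))
    return out


def discover(
    alignments: list[TagAlignment],
    genome: dict[str, str],
    params: ExtractionParams | None = None,
    thresholds: CriteriaThresholds | None = None,
    conserved_catalog: list[tuple[str, str, int]] | None = None,
    backend: str = "builtin",
) -> tuple[list[CandidatePrecursor], list[CandidatePrecursor]]:
    """Run extraction + evaluation; returns (accepted, all_candidates).

    Accepted precursors are deduplicated by overlap; rejected candidates
    are kept (deduplicated likewise) so per-locus failure reasons remain
    inspectable.
    """
    windows = extract_candidates(alignments, genome, params)
    evaluated: list[CandidatePrecursor] = []
    for i, (scaffold, strand, ws, we) in enumerate(windows):
        cand = evaluate_window(
            scaffold, strand, (ws, we), alignments, genome, thresholds,
            conserved_catalog, precursor_id=f"cand{i:04d}", backend=backend,
        )
        if cand is not None:
            evaluated.append(cand)
    accepted = _dedupe([c for c in evaluated if c.verdict.accepted])
    rejected = _dedupe([c for c in evaluated if not c.verdict.accepted])
    # a locus is accepted if any candidate there is; drop rejected twins
    rejected = [
        r for r in rejected
        if not any(
            a.scaffold_id == r.scaffold_id
            and a.interval[0] < r.interval[1]
            and r.interval[0] < a.interval[1]
            for a in accepted
        )
    ]
    allc = sorted(accepted + rejected, key=lambda c: (c.scaffold_id, c.interval[0]))
    for i, c in enumerate(allc, 1):
        c.precursor_id = f"pre{i:04d}"
        for m in c._matures:
            m.precursor_id = c.precursor_id
            m.mature_id = f"{c.precursor_id}-{m.arm}"
    return accepted, allc
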