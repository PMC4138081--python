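"""Seed-anchored homology matching of mature miRNAs against a reference
catalog.

A candidate matches a catalog entry iff the seed (positions 2-8, 1-based)
is identical and overall identity is >= ``min_identity``, where identity is
the number of identical positions under an ungapped alignment anchored at
the seed, divided by the length of the *longer* sequence.
"""

from __future__ import annotations

SEED_SLICE = slice(1, 8)  # positions 2..8, 1-based inclusive


def seed(seq: str) -> str:
    return seq[SEED_SLICE]


def identity(a: str, b: str) -> float:
    """Ungapped, start-anchored identity over the longer length."""
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / max(len(a), len(b))


def match_catalog(
    mature: str,
    entries: list[tuple[str, str, int]],
    min_identity: float = 0.8,
) -> tuple[str, int] | None:
    """Best (family, rank) match for a mature sequence, or None.

    Ties on identity resolve to the oldest (smallest) rank, then catalog
    order, so assignment is deterministic.
    """
    if len(mature) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature!r}")
    best: tuple[float, int, str] | None = None  # (identity, rank, family)
    for ref_seq, family, rank in entries:
        if seed(ref_seq) != seed(mature):
            continue
        ident = identity(mature, ref_seq)
        if ident < min_identity:
            continue
        key = (-ident, rank)
        if best is None or key < (-best[0], best[1]):
            best = (ident, rank, family)
    if best is None:
        return None
    return best[2], best[1]
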