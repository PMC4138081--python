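"""Secondary-structure prediction for candidate precursors.

The built-in model maximises the total pseudo-energy of a nested set of
base pairs (Nussinov-style dynamic programme) with pair weights

    G:C  3.0    A:T  2.0    G:T  1.0   (kcal/mol, sign-flipped)

and a minimum hairpin loop of 3 unpaired nucleotides.  The reported MFE is
minus the optimal score, so it is <= 0 by construction.  These weights are
deliberately simple pseudo-energies, not a thermodynamic parameter set: the
-21 kcal/mol acceptance threshold applies to whichever backend is active,
and the synthetic-data generator calibrates its plants against the active
backend.  An external thermodynamic backend (ViennaRNA's RNAfold) can be
plugged in with the identical contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_LOOP = 3  # unpaired nt enclosed by any pair

_PAIR_WEIGHT = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# weight matrix indexed by base codes; N pairs nothing
_WMAT = np.zeros((5, 5), dtype=np.float64)
for (x, y), w in _PAIR_WEIGHT.items():
    _WMAT[_BASE_INDEX[x], _BASE_INDEX[y]] = w


def pair_weight(a: str, b: str) -> float:
    return _PAIR_WEIGHT.get((a, b), 0.0)


def _fill_py(codes: np.ndarray, wmat: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    m = np.zeros((n, n), dtype=np.float64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = m[i + 1, j]  # i unpaired
            # i paired with k
            for k in range(i + MIN_LOOP + 1, j + 1):
                w = wmat[codes[i], codes[k]]
                if w > 0.0:
                    inner = m[i + 1, k - 1] if k - 1 > i + 1 else 0.0
                    right = m[k + 1, j] if k + 1 < j else 0.0
                    s = w + inner + right
                    if s > best:
                        best = s
            m[i, j] = best
    return m


try:  # optional speed-up; identical semantics
    from numba import njit

    _fill_fast = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover - numba present in the supported env
    _fill_fast = None


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    mfe: float  # kcal/mol, <= 0

    def pair_map(self) -> dict[int, int]:
        """Position -> paired position (symmetric), from the dot-bracket."""
        stack: list[int] = []
        pairs: dict[int, int] = {}
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pairs[i] = j
                pairs[j] = i
        return pairs


def _traceback(codes: np.ndarray, m: np.ndarray) -> str:
    """Deterministic traceback: on ties, prefer pairing i, and pair it with
    the largest (outermost) achieving partner.  This resolves the many
    equal-score structures of wobble-rich stems into the canonical ladder."""
    n = codes.shape[0]
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            w = _WMAT[codes[i], codes[k]]
            if w > 0.0:
                inner = m[i + 1, k - 1] if k - 1 > i + 1 else 0.0
                right = m[k + 1, j] if k + 1 < j else 0.0
                if w + inner + right == m[i, j]:
                    struct[i] = "("
                    struct[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(struct)


def fold(sequence: str, backend: str = "builtin", min_length: int = 40) -> FoldResult:
    """Fold a precursor-scale DNA sequence; length below ``min_length`` is a
    parameter error (too short to be a plausible hairpin precursor)."""
    seq = sequence.upper().replace("U", "T")
    if len(seq) < min_length:
        raise ValueError(f"sequence length {len(seq)} < {min_length}")
    if backend == "builtin":
        return _fold_builtin(seq)
    if backend == "vienna":
        return _fold_vienna(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


def _fold_builtin(seq: str) -> FoldResult:
    codes = np.array([_BASE_INDEX.get(c, 4) for c in seq], dtype=np.int64)
    n = len(seq)
    if n < 2:
        return FoldResult(seq, "." * n, 0.0)
    fill = _fill_fast if _fill_fast is not None else _fill_py
    m = fill(codes, _WMAT)
    struct = _traceback(codes, m)
    mfe = -float(m[0, n - 1])
    return FoldResult(seq, struct, mfe if mfe != 0.0 else 0.0)


def _fold_vienna(seq: str) -> FoldResult:  # pragma: no cover - optional backend
    import subprocess

    rna = seq.replace("T", "U")
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", capture_output=True,
        text=True, check=True,
    )
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    struct = struct_line.split(" ", 1)[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(seq, struct, mfe)
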