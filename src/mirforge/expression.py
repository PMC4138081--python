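"""Expression analytics: RPM normalisation, phylostratum assignment, the
miRNA profile age index (miRPAI), host-gene co-expression, coefficient of
variation, and organ/stage specificity screens.

miRPAI for a stage is the expression-weighted mean phylostratum,

    miRPAI(stage) = sum_i ps_i * e_i / sum_i e_i,

with ps_i the phylostratum rank of miRNA i (larger = younger) and e_i its
raw read count in that stage; a higher value means a younger miRNA
profile.  An RPM-weighted variant sits behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .homology import match_catalog
from .models import SampleSheet

COEXPR_R_MIN = 0.8
COEXPR_P_MAX = 1e-4
SPECIFICITY_FOLD = 5.0


def assign_phylostratum(
    mature_sequence: str,
    catalog: list[tuple[str, str, int]],
    novel_rank: int,
    min_identity: float = 0.8,
) -> int:
    """Phylostratum rank by seed-anchored homology: seed (positions 2-8)
    identical and identity >= 0.8 over the longer sequence; no catalog
    match assigns ``novel_rank`` (the youngest stratum)."""
    if not catalog:
        raise ValueError("empty phylostratum catalog")
    hit = match_catalog(mature_sequence, catalog, min_identity)
    return novel_rank if hit is None else hit[1]


def novel_rank_for(catalog: list[tuple[str, str, int]]) -> int:
    return max(rank for _, _, rank in catalog) + 1


@dataclass
class ExpressionMatrix:
    """Mature-miRNA x sample raw counts with RPM alongside."""

    raw: pd.DataFrame  # integer counts
    rpm: pd.DataFrame
    library_sizes: pd.Series

    @classmethod
    def from_counts(
        cls, raw: pd.DataFrame, library_mapped_reads: dict[str, int] | pd.Series
    ) -> "ExpressionMatrix":
        sizes = pd.Series(library_mapped_reads, dtype=float).reindex(raw.columns)
        if sizes.isna().any():
            missing = sizes[sizes.isna()].index.tolist()
            raise ValueError(f"missing library sizes for {missing}")
        if (sizes <= 0).any():
            raise ValueError("library sizes must be > 0")
        rpm = raw.div(sizes, axis=1) * 1e6
        return cls(raw.astype(int), rpm, sizes.astype(int))


def compute_rpm(
    raw: pd.DataFrame, library_mapped_reads: dict[str, int] | pd.Series
) -> ExpressionMatrix:
    return ExpressionMatrix.from_counts(raw, library_mapped_reads)


@dataclass
class MiRPAIProfile:
    values: dict[str, float]  # stage -> miRPAI
    n: int  # miRNAs included

    def argmax_stage(self) -> str:
        return max(self.values.items(), key=lambda kv: kv[1])[0]


def mirpai(
    matrix: ExpressionMatrix | pd.DataFrame,
    ranks: dict[str, int],
    stages: list[str],
    use_rpm: bool = False,
) -> MiRPAIProfile:
    """Expression-weighted mean phylostratum per stage; every included
    miRNA must carry a rank, and a stage with zero total counts is an
    error (the index is undefined there)."""
    counts = (
        (matrix.rpm if use_rpm else matrix.raw)
        if isinstance(matrix, ExpressionMatrix)
        else matrix
    )
    missing = [m for m in counts.index if m not in ranks]
    if missing:
        raise ValueError(f"miRNAs without phylostratum rank: {missing[:5]}")
    ps = np.array([ranks[m] for m in counts.index], dtype=float)
    values = {}
    for stage in stages:
        e = counts[stage].to_numpy(dtype=float)
        tot = e.sum()
        if tot <= 0:
            raise ValueError(f"stage {stage!r} has zero total counts; miRPAI undefined")
        values[stage] = float((ps * e).sum() / tot)
    return MiRPAIProfile(values, n=len(counts.index))


@dataclass
class CoexpressionResult:
    mature_id: str
    gene_id: str
    r: float
    p_value: float
    co_expressed: bool
    degenerate: bool = False  # zero variance in an input vector


def coexpression(
    mirna: np.ndarray | list[float],
    host: np.ndarray | list[float],
    mature_id: str = "",
    gene_id: str = "",
    r_min: float = COEXPR_R_MIN,
    p_max: float = COEXPR_P_MAX,
) -> CoexpressionResult:
    """Pearson r over matched samples with a two-sided P from
    t = r sqrt((n-2)/(1-r^2)) on n-2 df; co-expressed iff r > 0.8 and
    P < 0.0001."""
    x = np.asarray(mirna, dtype=float)
    y = np.asarray(host, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need matched 1-d vectors of length >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        return CoexpressionResult(mature_id, gene_id, float("nan"), float("nan"),
                                  False, degenerate=True)
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return CoexpressionResult(mature_id, gene_id, r, p, r > r_min and p < p_max)


def coefficient_of_variation(values: np.ndarray | list[float]) -> float:
    """Sample sd (n-1) over mean; undefined (error) for mean <= 0."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    if len(v) < 2:
        raise ValueError("CV needs >= 2 values")
    return float(v.std(ddof=1) / mean)


def merge_sample_groups(
    rpm: pd.DataFrame, samples: SampleSheet
) -> pd.DataFrame:
    """Average RPM over each merge group (e.g. the two mantle parts) into a
    single pseudo-sample named after the group."""
    groups: dict[str, list[str]] = {}
    keep: list[str] = []
    for s in samples:
        if s.sample_id not in rpm.columns:
            continue
        if s.merge_group:
            groups.setdefault(s.merge_group, []).append(s.sample_id)
        else:
            keep.append(s.sample_id)
    out = rpm[keep].copy()
    for group, members in groups.items():
        out[group] = rpm[members].mean(axis=1)
    return out


def specificity_screen(
    rpm: pd.DataFrame,
    samples: SampleSheet,
    fold: float = SPECIFICITY_FOLD,
) -> pd.DataFrame:
    """Per-mature specificity calls after merge-group averaging:
    specific_high in s iff rpm(s) >= 5 x rpm(s') for every other s' (and
    rpm(s) > 0); specific_low iff rpm(s) <= rpm(s')/5 for every other s'.
    Thresholds are inclusive; the two screens are independent, so a
    marker can be specifically high in one sample and absent in another."""
    merged = merge_sample_groups(rpm, samples)
    if merged.shape[1] < 3:
        raise ValueError("need >= 3 samples after merging")
    rows = []
    cols = list(merged.columns)
    for mature_id, row in merged.iterrows():
        vals = row.to_numpy(dtype=float)
        high_in = low_in = None
        for i, s in enumerate(cols):
            others = np.delete(vals, i)
            if high_in is None and vals[i] > 0 and np.all(
                    vals[i] >= fold * others):
                high_in = s
            if low_in is None and np.all(vals[i] <= others / fold):
                low_in = s
        call = {
            (True, True): "specific_high+low",
            (True, False): "specific_high",
            (False, True): "specific_low",
            (False, False): "none",
        }[(high_in is not None, low_in is not None)]
        rows.append({"mature_id": mature_id, "call": call,
                     "sample": high_in if high_in is not None else low_in,
                     "high_in": high_in, "low_in": low_in})
    return pd.DataFrame(rows).set_index("mature_id")
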