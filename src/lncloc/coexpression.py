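"""Neighboring-gene assignment and co-expression vs a random-pair null.

Each lncRNA is assigned its nearest protein-coding gene by span-to-span
gap on the same chromosome (strand ignored) and binned: ``overlap``
(gap 0), ``lt5k`` (0 < d < 5 kb), ``lt10k`` (5 kb <= d < 10 kb),
``ge10k`` (d >= 10 kb).  Co-expression compares the Pearson r of
lncRNA-neighbor pairs with r of randomly drawn lncRNA/non-neighbor gene
pairs (Welch t-test); |r| > 0.8 flags a strong pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, TranscriptModel

logger = logging.getLogger(__name__)

DISTANCE_BINS = ("overlap", "lt5k", "lt10k", "ge10k")


def bin_distance(distance: float) -> str:
    """Half-open distance bins partitioning [0, inf)."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0:
        return "overlap"
    if distance < 5000:
        return "lt5k"
    if distance < 10000:
        return "lt10k"
    return "ge10k"


@dataclass(frozen=True)
class NeighborAssignment:
    lnc_id: str
    nearest_gene_id: str | None
    distance: float  # nt; 0 when spans overlap; inf when no gene on chrom
    bin: str
    flagged: bool = False  # True when no gene exists on the chromosome


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end)


def nearest_gene(lnc: TranscriptModel, ann: GenomeAnnotation) -> NeighborAssignment:
    """Nearest gene by span-to-span gap, any strand; ties -> smallest gene_id."""
    genes = ann.genes_on_chrom(lnc.chrom)
    if not genes:
        logger.warning(
            "lncRNA %s: no gene on chromosome %s", lnc.transcript_id, lnc.chrom
        )
        return NeighborAssignment(
            lnc.transcript_id, None, math.inf, "ge10k", flagged=True
        )
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    gaps = np.maximum(starts - lnc.end, lnc.start - ends)
    gaps = np.maximum(gaps, 0)
    gaps[(starts < lnc.end) & (lnc.start < ends)] = 0
    best = np.flatnonzero(gaps == gaps.min())
    gene = min((genes[i] for i in best), key=lambda g: g.gene_id)
    d = float(gaps.min())
    return NeighborAssignment(lnc.transcript_id, gene.gene_id, d, bin_distance(d))


def assign_neighbors(
    lncs: Iterable[TranscriptModel], ann: GenomeAnnotation
) -> list[NeighborAssignment]:
    return [nearest_gene(t, ann) for t in lncs]


def bin_counts(assignments: Sequence[NeighborAssignment]) -> dict[str, int]:
    counts = {b: 0 for b in DISTANCE_BINS}
    for a in assignments:
        counts[a.bin] += 1
    return counts


# ---------------------------------------------------------------------------
# Pearson correlation and the observed-vs-null test
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on short or constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("correlation needs >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CoexpressionResult:
    observed_r: list[float]
    null_r: list[float]
    observed_mean: float
    null_mean: float
    t_statistic: float
    p_value: float
    strong_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_dropped_pairs: int = 0

    def summary(self) -> dict:
        return {
            "n_neighbor_pairs": len(self.observed_r),
            "n_null_pairs": len(self.null_r),
            "observed_mean_r": self.observed_mean,
            "null_mean_r": self.null_mean,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_strong_pairs": len(self.strong_pairs),
            "n_dropped_pairs": self.n_dropped_pairs,
        }


def coexpression_test(
    pairs: Sequence[tuple[str, str]],
    m: pd.DataFrame,
    *,
    gene_ids: Sequence[str] | None = None,
    n_random: int = 1000,
    seed: int = 0,
    strong_threshold: float = 0.8,
    exclude: Iterable[tuple[str, str]] = (),
) -> CoexpressionResult:
    """Observed neighbor-pair correlation vs a random-pair null.

    ``pairs`` are (lnc_id, gene_id) neighbor pairs; the null draws
    ``n_random`` (lnc, gene) pairs uniformly (with replacement, fixed
    ``seed``) from the same lncRNAs and the gene pool (``gene_ids``, or
    all gene ids seen in ``pairs`` if omitted), excluding true neighbor
    pairs and anything in ``exclude``.  The two r distributions are
    compared with a Welch t-test.  Pairs with a member missing from the
    matrix, or with constant expression, are dropped and counted.
    """
    if n_random < len(pairs):
        raise ValueError("n_random must be >= the number of neighbor pairs")
    rng = np.random.default_rng(seed)
    idx = set(map(str, m.index))

    def usable(row_id: str) -> bool:
        return row_id in idx and m.loc[row_id].std() > 0

    observed_r: list[float] = []
    strong: list[tuple[str, str, float]] = []
    dropped = 0
    kept_pairs: list[tuple[str, str]] = []
    for lnc_id, gid in pairs:
        if not (usable(lnc_id) and usable(gid)):
            dropped += 1
            continue
        r = pearson_r(m.loc[lnc_id], m.loc[gid])
        observed_r.append(r)
        kept_pairs.append((lnc_id, gid))
        if abs(r) > strong_threshold:
            strong.append((lnc_id, gid, r))
    if dropped:
        logger.warning("dropped %d neighbor pairs missing/constant in matrix", dropped)
    if len(observed_r) < 2:
        raise ValueError("need >= 2 usable neighbor pairs")

    forbidden = set(pairs) | set(exclude)
    lnc_pool = sorted({p[0] for p in kept_pairs})
    if gene_ids is None:
        gene_pool = sorted({p[1] for p in kept_pairs})
    else:
        gene_pool = sorted(g for g in map(str, gene_ids) if usable(g))
    if not gene_pool:
        raise ValueError("empty gene pool for the null")

    null_r: list[float] = []
    max_draws = 50 * n_random
    draws = 0
    while len(null_r) < n_random and draws < max_draws:
        draws += 1
        lnc_id = lnc_pool[rng.integers(len(lnc_pool))]
        gid = gene_pool[rng.integers(len(gene_pool))]
        if (lnc_id, gid) in forbidden or lnc_id == gid:
            continue
        null_r.append(pearson_r(m.loc[lnc_id], m.loc[gid]))
    if len(null_r) < n_random:
        raise RuntimeError("could not draw enough null pairs outside the exclusions")

    t_stat, p = stats.ttest_ind(observed_r, null_r, equal_var=False)
    return CoexpressionResult(
        observed_r=observed_r,
        null_r=null_r,
        observed_mean=float(np.mean(observed_r)),
        null_mean=float(np.mean(null_r)),
        t_statistic=float(t_stat),
        p_value=float(p),
        strong_pairs=strong,
        n_dropped_pairs=dropped,
    )


def neighbor_table(
    assignments: Sequence[NeighborAssignment],
    result: CoexpressionResult | None = None,
) -> pd.DataFrame:
    """Per-lncRNA TSV-ready table: nearest gene, distance, bin (+ r if known)."""
    r_by_pair: dict[tuple[str, str], float] = {}
    strong: set[tuple[str, str]] = set()
    if result is not None:
        for lnc_id, gid, r in result.strong_pairs:
            strong.add((lnc_id, gid))
    rows = []
    for a in assignments:
        rows.append(
            {
                "lnc_id": a.lnc_id,
                "gene_id": a.nearest_gene_id or "",
                "distance": a.distance,
                "bin": a.bin,
                "strong": (a.lnc_id, a.nearest_gene_id) in strong,
            }
        )
    return pd.DataFrame(rows)
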