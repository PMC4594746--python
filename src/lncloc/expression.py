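"""Expression analysis over FPKM matrices.

Three callers operate on a pandas DataFrame of FPKM values (rows =
transcripts/genes, columns = samples):

* :func:`call_specific` — sample-specific expression: > ``hi`` FPKM in
  one sample, < ``lo`` FPKM in every other sample, and at least
  ``fold``-fold above the maximum of the other samples (defaults
  3 / 1 / 10-fold).
* :func:`call_differential` — per-row Welch t-test between two
  replicate groups on log2(FPKM + 1), Benjamini-Hochberg FDR, calls at
  p < 0.01 and q < 0.05 by default.  Matrices without replicates get
  fold-change ranking only (:func:`rank_by_fold_change`) — no p-values
  are fabricated for unreplicated designs.
* :func:`cluster_expression` — average-linkage (UPGMA) hierarchical
  clustering on 1 - Pearson correlation between rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read an FPKM TSV (first column = id, header = sample names).

    Missing cells are imputed as 0.0 (count logged); negative values
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("imputed %d missing FPKM cells as 0.0", n_missing)
        df = df.fillna(0.0)
    if (df.values < 0).any():
        raise ValueError("FPKM matrix contains negative values")
    return df.astype(float)


def write_fpkm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Specific expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecificityCall:
    transcript_id: str
    sample_id: str
    value: float
    max_other: float

    @property
    def rule1_pass(self) -> bool:
        """Expression rule: > hi here, < lo elsewhere (true by construction)."""
        return True

    @property
    def rule2_pass(self) -> bool:
        """Fold rule: >= fold x the best other sample (true by construction)."""
        return True


def call_specific(
    m: pd.DataFrame,
    *,
    hi: float = 3.0,
    lo: float = 1.0,
    fold: float = 10.0,
) -> list[SpecificityCall]:
    """Call sample-specific rows of an FPKM matrix.

    Row t is specific in sample s iff m[t, s] > hi, every other sample
    is < lo, and m[t, s] >= fold * max(other samples).  With hi >= lo at
    most one sample per row can qualify.  The fold rule compares
    against the *maximum* of the other samples (the stricter reading).
    """
    if m.shape[1] < 2:
        raise ValueError("specificity calling needs >= 2 samples")
    X = m.to_numpy(dtype=float)
    top_idx = np.argmax(X, axis=1)
    top = X[np.arange(len(X)), top_idx]
    masked = X.copy()
    masked[np.arange(len(X)), top_idx] = -np.inf
    second = masked.max(axis=1)
    ok = (top > hi) & (second < lo) & (top >= fold * second)
    calls = []
    for i in np.flatnonzero(ok):
        calls.append(
            SpecificityCall(
                transcript_id=str(m.index[i]),
                sample_id=str(m.columns[top_idx[i]]),
                value=float(top[i]),
                max_other=float(second[i]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffCall:
    transcript_id: str
    contrast: tuple[str, str]
    log2_fold_change: float
    p_value: float
    q_value: float


def _two_groups(
    m: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[str, str, list[str], list[str]]:
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    ga = [s for s in m.columns if groups.get(s) == names[0]]
    gb = [s for s in m.columns if groups.get(s) == names[1]]
    if not ga or not gb:
        raise ValueError("each group needs >= 1 sample column present in the matrix")
    return names[0], names[1], ga, gb


def differential_table(
    m: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-row Welch t-test on log2(FPKM + 1) between two groups.

    Returns a DataFrame (index = row ids) with log2_fc (group A minus
    group B), p_value and BH q_value for every row.  Rows where both
    groups have zero variance get p = 1 when the means agree and p = 0
    otherwise.
    """
    name_a, name_b, cols_a, cols_b = _two_groups(m, groups)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            "differential testing needs >= 2 replicates per group; use"
            " rank_by_fold_change for unreplicated designs"
        )
    A = np.log2(m[cols_a].to_numpy(dtype=float) + 1.0)
    B = np.log2(m[cols_b].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    p[degenerate & np.isclose(mean_a, mean_b)] = 1.0
    p[degenerate & ~np.isclose(mean_a, mean_b)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    q = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {
            "log2_fc": mean_a - mean_b,
            "p_value": p,
            "q_value": q,
            "contrast": f"{name_a}_vs_{name_b}",
        },
        index=m.index,
    )


def call_differential(
    m: pd.DataFrame,
    groups: Mapping[str, str],
    *,
    p_cut: float = 0.01,
    q_cut: float = 0.05,
) -> list[DiffCall]:
    """Differential calls at p < p_cut and q < q_cut."""
    table = differential_table(m, groups)
    name_a, name_b = table["contrast"].iloc[0].split("_vs_") if len(table) else ("", "")
    sig = table[(table["p_value"] < p_cut) & (table["q_value"] < q_cut)]
    return [
        DiffCall(
            transcript_id=str(tid),
            contrast=(name_a, name_b),
            log2_fold_change=float(row["log2_fc"]),
            p_value=float(row["p_value"]),
            q_value=float(row["q_value"]),
        )
        for tid, row in sig.iterrows()
    ]


def rank_by_fold_change(
    m: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Fold-change ranking for unreplicated designs (no p-values).

    log2 fold change of group means on log2(FPKM + 1); rows sorted by
    absolute fold change, descending.
    """
    logger.warning(
        "no replicates: producing fold-change ranking only, no significance"
    )
    name_a, name_b, cols_a, cols_b = _two_groups(m, groups)
    A = np.log2(m[cols_a].to_numpy(dtype=float) + 1.0).mean(axis=1)
    B = np.log2(m[cols_b].to_numpy(dtype=float) + 1.0).mean(axis=1)
    out = pd.DataFrame(
        {"log2_fc": A - B, "contrast": f"{name_a}_vs_{name_b}"}, index=m.index
    )
    return out.reindex(out["log2_fc"].abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    ids: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]


def correlation_distance_matrix(m: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r between rows; constant rows get r = 0 (distance 1)."""
    X = m.to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant rows: correlation undefined, treated as r = 0",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.where(np.isnan(r), 0.0, r)
    D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cluster_expression(m: pd.DataFrame) -> ClusterResult:
    """UPGMA clustering of matrix rows on correlation distance.

    Rows are sorted by id before clustering so tie-breaking is
    deterministic; output is invariant (up to relabeling) to input row
    order.
    """
    if m.shape[0] < 2:
        raise ValueError("clustering needs >= 2 rows")
    m = m.loc[sorted(m.index, key=str)]
    D = correlation_distance_matrix(m)
    Z = linkage(squareform(D, checks=False), method="average")
    order = [str(m.index[i]) for i in leaves_list(Z)]
    return ClusterResult(ids=[str(i) for i in m.index], linkage_matrix=Z,
                         leaf_order=order)
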