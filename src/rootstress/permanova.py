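"""Permutational multivariate analysis of variance on trait matrices.

The total sum of squares of an n-point configuration equals the sum of
squared pairwise distances divided by n; grouping partitions it into a
within-group part (per-group squared distances divided by group size) and
a between-group remainder.  The pseudo-F statistic

    F = (SS_between / (k-1)) / (SS_within / (N-k))

is referred to its permutation distribution under random reassignment of
the group labels, with the observed statistic included in the reference
set so p >= 1/(n_permutations+1).  In one Euclidean dimension this
reduces exactly to the classical one-way ANOVA F — a property the test
suite uses as a cross-module oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "standardize_and_distance",
    "permanova",
    "pairwise_permanova",
    "fdr_bh",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids and a metric tag."""

    values: np.ndarray
    ids: tuple[str, ...]
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ValueError("ids/matrix size mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PermanovaResult:
    df_treatment: int
    df_residual: int
    df_total: int
    ss_treatment: float
    ss_residual: float
    ss_total: float
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int


def standardize_and_distance(wide: pd.DataFrame,
                             metric: str = "euclidean") -> DistanceMatrix:
    """Z-score each trait column and compute pairwise distances.

    Zero-variance columns carry no information after scaling and are
    dropped with a warning.  Non-numeric columns (e.g. a ``treatment``
    label column) are ignored.
    """
    num = wide.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("missing cells in trait matrix")
    if len(num) < 2:
        raise ValueError("need at least two samples")
    sds = num.std(ddof=1)
    dead = list(sds.index[sds == 0])
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}", stacklevel=2)
        num = num.drop(columns=dead)
        sds = sds.drop(index=dead)
    z = (num - num.mean()) / sds
    d = squareform(pdist(z.to_numpy(), metric=metric))
    return DistanceMatrix(values=d, ids=tuple(str(i) for i in wide.index),
                          metric=metric)


def _ss_parts(d2: np.ndarray, groups: np.ndarray,
              labels: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared distances and a label vector."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_within, ss_total


def permanova(d: DistanceMatrix, groups, n_permutations: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Overall one-factor permutation test on a distance matrix.

    Labels are permuted freely (no strata); the permutation stream is
    fully determined by ``seed``.
    """
    groups = np.asarray(groups)
    if len(groups) != len(d):
        raise ValueError("groups/ids length mismatch")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two samples")
    n = len(d)
    k = len(labels)
    df_a, df_w = k - 1, n - k
    d2 = d.values ** 2

    ss_within, ss_total = _ss_parts(d2, groups, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / df_a) / (ss_within / df_w)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        ss_w, _ = _ss_parts(d2, perm, labels)
        f_perm = ((ss_total - ss_w) / df_a) / (ss_w / df_w)
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)

    return PermanovaResult(
        df_treatment=df_a, df_residual=df_w, df_total=n - 1,
        ss_treatment=float(ss_between), ss_residual=float(ss_within),
        ss_total=float(ss_total), r2=float(ss_between / ss_total),
        pseudo_f=float(f_obs), p=float(p), n_permutations=n_permutations,
    )


def pairwise_permanova(d: DistanceMatrix, groups, n_permutations: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """One PERMANOVA per group pair with Benjamini–Hochberg adjustment.

    Each pair's test restricts the distance matrix to that pair's
    samples; adjusted p-values control the FDR across all pairs.
    """
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))  # first-appearance order
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(labels, 2):
        idx = np.flatnonzero((groups == a) | (groups == b))
        sub = DistanceMatrix(values=d.values[np.ix_(idx, idx)],
                             ids=tuple(d.ids[i] for i in idx), metric=d.metric)
        res = permanova(sub, groups[idx], n_permutations=n_permutations,
                        seed=int(rng.integers(2 ** 31)))
        rows.append({"pair": f"{a} vs {b}", "pseudo_F": res.pseudo_f,
                     "R2": res.r2, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = fdr_bh(out["p"].to_numpy())
    return out


def fdr_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
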