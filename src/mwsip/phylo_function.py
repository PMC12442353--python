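"""Phylogenetic conservation of carbon-cycling traits.

Correlates pairwise phylogenetic (cophenetic) distance with pairwise
functional distance among incorporator taxa.  Functional profiles combine
substrate indicators, day of label detection, and degree of ¹³C
assimilation; columns are range-scaled to [0, 1] and compared with the
modified Gower ("altGower") distance.  Significance of the Spearman rank
correlation between the two distance matrices uses a Mantel-style
permutation of taxon labels, since distance pairs are not independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .exceptions import AnalysisError, DomainError, InvalidDesignError


def scale_traits(profiles: pd.DataFrame) -> pd.DataFrame:
    """Range-scale each numeric column to [0, 1]; constant columns map to 0."""
    if profiles.shape[0] < 2:
        raise InvalidDesignError("need at least 2 taxa")
    arr = profiles.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise DomainError("trait values must be finite")
    lo = arr.min(axis=0)
    span = arr.max(axis=0) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(scaled, index=profiles.index, columns=profiles.columns)


def modified_gower_distance(x, y) -> float:
    """Modified Gower ("altGower") distance between two scaled profiles.

    Mean absolute difference over the columns where the two values are not
    both zero; identically-zero profiles are at distance 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("profiles must have the same length")
    used = ~((x == 0) & (y == 0))
    if not used.any():
        return 0.0
    return float(np.abs(x[used] - y[used]).mean())


def functional_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Full modified-Gower distance matrix over scaled trait profiles."""
    arr = profiles.to_numpy(dtype=float)
    n = arr.shape[0]
    diff = np.abs(arr[:, None, :] - arr[None, :, :])
    used = ~((arr[:, None, :] == 0) & (arr[None, :, :] == 0))
    nz = used.sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(nz > 0, (diff * used).sum(axis=2) / np.maximum(nz, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def cophenetic_distance(tree: TreeNode, taxa) -> pd.DataFrame:
    """Tip-to-tip path-length (cophenetic) distances for the given taxa."""
    taxa = list(taxa)
    tips = {t.name for t in tree.tips()}
    for taxon in taxa:
        if taxon not in tips:
            raise AnalysisError(f"tip missing from tree: {taxon!r}")
    dm = tree.tip_tip_distances(endpoints=taxa)
    frame = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    return frame.loc[taxa, taxa]


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def distance_correlation(
    d_phylo: pd.DataFrame,
    d_func: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Spearman correlation of two distance matrices with a Mantel permutation p.

    Rho is computed over lower-triangle pairs; the two-sided p-value comes
    from permuting the taxon labels of the functional matrix ``n_perm``
    times and counting permuted \\|rho\\| ≥ observed \\|rho\\| (add-one
    correction).  Deterministic under ``seed``.
    """
    ids = list(d_phylo.index)
    if set(ids) != set(d_func.index):
        raise InvalidDesignError("distance matrices must cover the same taxa")
    if len(ids) < 4:
        raise InvalidDesignError("need at least 4 taxa")
    if n_perm < 99:
        raise InvalidDesignError("n_perm must be at least 99")
    dp = d_phylo.loc[ids, ids].to_numpy(dtype=float)
    df = d_func.loc[ids, ids].to_numpy(dtype=float)
    for name, d in (("phylogenetic", dp), ("functional", df)):
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise DomainError(f"{name} matrix is not a valid distance matrix")

    x = _lower_triangle(dp)
    rho = stats.spearmanr(x, _lower_triangle(df)).statistic
    rx = stats.rankdata(x)

    rng = np.random.default_rng(seed)
    n = len(ids)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rperm = stats.rankdata(_lower_triangle(df[np.ix_(perm, perm)]))
        rho_p = np.corrcoef(rx, rperm)[0, 1]
        if abs(rho_p) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {"spearman_rho": float(rho), "permutation_p": float(p), "n_perm": n_perm}
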