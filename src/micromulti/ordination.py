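"""Principal coordinate analysis and PERMANOVA on dissimilarity matrices.

PCoA uses Gower double-centering of -d^2/2 followed by a symmetric
eigendecomposition; axes with negative eigenvalues (non-Euclidean input) are
reported and dropped, with no correction applied. PERMANOVA (ADONIS-style)
partitions distance-based sums of squares between and within groups into a
pseudo-F whose significance comes from permuting the group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = ["PcoaResult", "pcoa", "PermanovaResult", "permanova"]


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    prop_explained: np.ndarray  # over positive eigenvalues, sums to 1
    n_negative_eigenvalues: int


def pcoa(dist: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical metric multidimensional scaling of a dissimilarity matrix."""
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > eps * max(abs(eigvals[0]), 1.0)
    n_negative = int((eigvals < -eps * max(abs(eigvals[0]), 1.0)).sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids), columns=axes),
        eigenvalues=eigvals,
        prop_explained=lam / lam.sum() if lam.size else lam,
        n_negative_eigenvalues=n_negative,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int | None
    null_values: np.ndarray = field(repr=False)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer group codes.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums (1/n_g) of within-group
    squared distances; SS_between is the difference.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g > 1:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        f = np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    strata=None,
) -> PermanovaResult:
    """One-way PERMANOVA with a label-permutation p-value.

    ``groups`` maps each sample id to its group (a mapping or a pandas
    Series); the permutation scheme is an unrestricted label shuffle unless
    ``strata`` is given, in which case labels are shuffled within each
    stratum only. One-sided (greater) p with the plus-one correction.
    """
    ids = list(dist.ids)
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    labels = pd.Series([groups[i] for i in ids], index=ids)
    levels = sorted(labels.unique())
    n_groups = len(levels)
    n = len(ids)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if n_groups >= n:
        raise ValueError("need more samples than groups")
    codes = np.array([levels.index(v) for v in labels])

    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)

    rng = np.random.default_rng(seed)
    if strata is not None:
        if isinstance(strata, pd.Series):
            strata = strata.to_dict()
        svec = np.array([strata[i] for i in ids])
        blocks = [np.flatnonzero(svec == s) for s in pd.unique(svec)]
    null = np.empty(n_perm)
    for t in range(n_perm):
        if strata is None:
            perm_codes = codes[rng.permutation(n)]
        else:
            perm_codes = codes.copy()
            for blk in blocks:
                perm_codes[blk] = codes[blk[rng.permutation(len(blk))]]
        null[t] = _pseudo_f(d2, perm_codes, n_groups)[0]
    p = (1.0 + float((null >= f_obs).sum())) / (n_perm + 1.0)
    return PermanovaResult(
        pseudo_F=f_obs,
        r_squared=r2,
        p_value=p,
        df_between=n_groups - 1,
        df_within=n - n_groups,
        n_permutations=n_perm,
        seed=seed,
        null_values=null,
    )
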