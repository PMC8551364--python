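"""Alpha/beta diversity, distance matrices, ordination and PERMANOVA.

Distances follow standard microbiome practice: Bray–Curtis on the raw
abundance values, and the square root of the Jensen–Shannon divergence
(base-2 logs, pseudocount-smoothed proportions) — a bounded metric — for
enterotyping.  Ordination is classical PCoA (double-centred squared
distances) and centred PCA; PERMANOVA uses Anderson's pseudo-F with seeded
label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult
from .tables import AbundanceTable


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric_name: str  # bray_curtis | jsd_root | euclidean...

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("nonzero diagonal")
        self.values = v

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)],
                              self.metric_name)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # n_samples x k
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    method: str
    negative_eigenvalues: np.ndarray | None = None


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon_index(values) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ on renormalised proportions.

    Natural log, matching the vegan default; divide by ln 2 for bits.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no Shannon index")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(values) -> int:
    """Number of features with nonzero abundance."""
    return int((np.asarray(values, dtype=float) > 0).sum())


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    rows = [{"sample_id": sid,
             "shannon": shannon_index(table.data[sid].to_numpy()),
             "richness": observed_richness(table.data[sid].to_numpy())}
            for sid in table.sample_ids]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on raw values."""
    x = table.values().T  # samples x features
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        num = np.abs(x[i + 1:] - x[i]).sum(axis=1)
        den = (x[i + 1:] + x[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        if (den == 0).any():
            warnings.warn("pair of all-zero samples: Bray-Curtis set to 0")
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DistanceMatrix(table.sample_ids, d, "bray_curtis")


def _smoothed_proportions(x: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount <= 0 and (x == 0).any():
        raise ValueError("nonpositive pseudocount with zero cells")
    x = np.where(x > 0, x, pseudocount)
    return x / x.sum(axis=1, keepdims=True)


def jsd_distance_matrix(table: AbundanceTable, pseudocount: float = 1e-6) -> DistanceMatrix:
    """Root Jensen–Shannon divergence distance, base-2 logs, range [0, 1].

    Zero cells are replaced by the pseudocount before renormalisation; the
    square root of the base-2 JSD is a bounded metric.
    """
    x = table.values().T
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    from scipy.special import xlogy
    p = _smoothed_proportions(x, pseudocount)
    # JSD(p,q) = H(m) - (H(p)+H(q))/2 with base-2 entropies, m = (p+q)/2;
    # xlogy treats underflowed zero cells as zero contributions
    ln2 = np.log(2.0)
    h = -xlogy(p, p).sum(axis=1) / ln2
    n = p.shape[0]
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        m = 0.5 * (p[i + 1:] + p[i])
        hm = -xlogy(m, m).sum(axis=1) / ln2
        jsd = hm - 0.5 * (h[i + 1:] + h[i])
        jsd = np.clip(jsd, 0.0, 1.0)
        d[i, i + 1:] = np.sqrt(jsd)
        d[i + 1:, i] = d[i, i + 1:]
    return DistanceMatrix(table.sample_ids, d, "jsd_root")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def pcoa_embed(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns axes
    for the positive eigenvalues only; negative eigenvalues are reported
    separately and excluded from the proportions explained.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    neg = evals[evals < -tol]
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {n_pos} axes")
        k = n_pos
    lam = evals[:k]
    coords = evecs[:, :k] * np.sqrt(lam)
    coords = _fix_signs(coords)
    pos_sum = evals[pos].sum()
    prop = lam / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(dm.sample_ids, coords, lam, prop, "PCoA",
                            negative_eigenvalues=neg)


def pca_embed(table: AbundanceTable, k: int = 2) -> OrdinationResult:
    """Centred (not scaled) PCA of samples in feature space."""
    x = table.values().T  # samples x features
    n, p = x.shape
    if k > min(n, p):
        raise ValueError("k exceeds min(n_samples, n_features)")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("constant feature matrix has no principal axes")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    evals = s ** 2 / (n - 1)
    coords = _fix_signs(u[:, :k] * s[:k])
    prop = evals[:k] / evals.sum()
    return OrdinationResult(table.sample_ids, coords, evals[:k], prop, "PCA")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    k = len(uniq)
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 9999,
              seed: int = 0) -> TestResult:
    """Permutational multivariate ANOVA (Anderson's pseudo-F).

    The pseudo-F partitions the total sum of squared distances into between-
    and within-group parts; the p-value is (1 + #{F_perm ≥ F_obs}) /
    (1 + n_permutations) under seeded label permutations.  The distance
    matrix is computed once; only labels are shuffled.
    """
    labels = np.asarray(list(grouping))
    if labels.size != len(dm.sample_ids):
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.values ** 2
    f_obs = _permanova_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    work = labels.copy()
    ge = 0
    for _ in range(n_permutations):
        rng.shuffle(work)
        if _permanova_f(d2, work, uniq) >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return TestResult(float(f_obs), float(p), "permanova",
                      tuple(int(c) for c in counts), 0)
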