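"""Distance-based enterotyping of genus profiles.

The classic recipe: root-JSD distances between genus relative-abundance
profiles, PAM (k-medoids, BUILD + SWAP) clustering for each candidate k, the
Calinski–Harabasz index to pick k, dominant-genus labels per cluster, and a
Fisher exact contingency test of enterotype frequency between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .diversity import DistanceMatrix, jsd_distance_matrix, pca_embed
from .metadata import Cohort
from .stats import TestResult, fisher_exact_2x2, fisher_exact_rxc_mc
from .tables import AbundanceTable


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------

#: exact enumeration is used whenever the medoid search space is this small
_EXACT_MEDOID_LIMIT = 300


def pam_cluster(dm: DistanceMatrix | np.ndarray, k: int, seed: int = 0):
    """Partitioning around medoids (k-medoids).

    For tiny instances (at most ``_EXACT_MEDOID_LIMIT`` candidate medoid
    sets) the global optimum is found by enumeration; otherwise BUILD
    initialisation (greedy cost-minimising medoids) followed by
    best-improvement SWAP until no improving exchange exists — the classic
    heuristic, which can stop in a local optimum on adversarial instances.
    Fully deterministic for a given distance matrix — cost ties are broken
    by lowest sample index (the seed argument exists for interface symmetry
    and future stochastic variants).

    Returns (assignment array, medoid indices, total cost).
    """
    from math import comb
    d = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_samples, got k={k}, n={n}")

    if comb(n, k) <= _EXACT_MEDOID_LIMIT:
        from itertools import combinations
        best_cost, best_meds = np.inf, None
        for meds in combinations(range(n), k):
            cost = float(d[np.asarray(meds)].min(axis=0).sum())
            if cost < best_cost - 1e-12:
                best_cost, best_meds = cost, meds
        medoids = sorted(best_meds)
        assignment = np.argmin(d[np.asarray(medoids)], axis=0)
        return assignment, medoids, best_cost

    # BUILD
    medoids: list[int] = [int(np.argmin(d.sum(axis=1)))]
    dist_to_nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        best_gain, best_c = -np.inf, -1
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(dist_to_nearest - d[c], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)
        dist_to_nearest = np.minimum(dist_to_nearest, d[best_c])

    def total_cost(meds: list[int]) -> float:
        return float(d[np.asarray(meds)].min(axis=0).sum())

    cost = total_cost(medoids)
    # SWAP: best-improvement, lowest-index tie-break
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = total_cost(others + [h])
                if new_cost < best[0] - 1e-12:
                    best = (new_cost, mi, h)
        if best[1] is not None:
            cost, mi, h = best
            medoids[mi] = h
            improved = True
    medoids = sorted(medoids)
    assignment = np.argmin(d[np.asarray(medoids)], axis=0)
    return assignment, medoids, total_cost(medoids)


def calinski_harabasz(dm: DistanceMatrix | np.ndarray, assignment,
                      medoids=None) -> float:
    """Distance-based Calinski–Harabasz index.

    Dispersions are computed from pairwise squared distances, which need no
    centroid and reduce exactly to the classic variance-based index when
    the distances are Euclidean: T = Σ_{i<j} d²ᵢⱼ/n,
    W = Σ_clusters Σ_{i<j∈cluster} d²ᵢⱼ/n_cluster, B = T − W,
    CH = [B/(k−1)] / [W/(n−k)].  Under random labels on structureless data
    CH is near 1, like an ANOVA F ratio.
    """
    d = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    labels = np.asarray(assignment)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("Calinski-Harabasz undefined for a single cluster")
    d2 = d ** 2
    t = float(d2[np.triu_indices(n, 1)].sum()) / n
    w = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        w += float(sub[np.triu_indices(len(idx), 1)].sum()) / len(idx)
    b = max(t - w, 0.0)
    if w == 0.0:
        return np.inf
    return (b / (k - 1)) / (w / (n - k))


# ---------------------------------------------------------------------------
# enterotype assignment
# ---------------------------------------------------------------------------

@dataclass
class EnterotypeResult:
    sample_ids: list[str]
    assignment: np.ndarray
    chosen_k: int
    ch_curve: dict[int, float]
    medoids: list[int]
    dominant_genus: dict[int, str]
    pca_coordinates: np.ndarray
    distance: DistanceMatrix

    def labels(self) -> pd.Series:
        names = [self.dominant_genus[int(c)] for c in self.assignment]
        return pd.Series(names, index=self.sample_ids, name="enterotype")


def _genus_short_name(feature_id: str) -> str:
    tail = feature_id.split("|")[-1]
    return tail if tail.startswith("g__") else f"g__{tail}"


def enterotype_assign(genus_table: AbundanceTable,
                      k_candidates=range(2, 11),
                      config: AnalysisConfig | None = None) -> EnterotypeResult:
    """Cluster genus profiles into enterotypes.

    Root-JSD distances → PAM for each candidate k (capped at n/3) → CH per
    k → chosen k = argmax CH.  Clusters are labelled by the genus with the
    highest mean relative abundance among their members.
    """
    config = config or AnalysisConfig()
    n = genus_table.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to enterotype")
    dm = jsd_distance_matrix(genus_table, pseudocount=config.pseudocount)
    k_max = max(2, n // 3)
    ks = [k for k in k_candidates if 2 <= k <= min(k_max, n - 1)]
    if not ks:
        ks = [2]
    ch_curve: dict[int, float] = {}
    results = {}
    for k in ks:
        assignment, medoids, _ = pam_cluster(dm, k, seed=config.rng_seed)
        ch_curve[k] = calinski_harabasz(dm, assignment)
        results[k] = (assignment, medoids)
    chosen_k = max(ks, key=lambda k: (ch_curve[k], -k))
    assignment, medoids = results[chosen_k]

    dominant: dict[int, str] = {}
    data = genus_table.data
    for c in range(chosen_k):
        members = [genus_table.sample_ids[i] for i in np.flatnonzero(assignment == c)]
        mean_abund = data[members].mean(axis=1)
        dominant[c] = _genus_short_name(str(mean_abund.idxmax()))

    pca = pca_embed(genus_table, k=2)
    return EnterotypeResult(genus_table.sample_ids, assignment, chosen_k,
                            ch_curve, medoids, dominant, pca.coordinates, dm)


def enterotype_contingency_test(result: EnterotypeResult, cohort: Cohort,
                                seed: int = 0) -> tuple[TestResult, pd.DataFrame]:
    """Group × enterotype counts and a Fisher exact test.

    For two clusters this is the classic 2×2 Fisher exact test; for more, a
    seeded Monte-Carlo generalisation conditioned on the margins.
    """
    groups = cohort.df.loc[result.sample_ids, "group"]
    labels = result.labels()
    counts = pd.crosstab(groups, labels)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty group in contingency table")
    if counts.shape == (2, 2):
        res = fisher_exact_2x2(counts.to_numpy())
    else:
        res = fisher_exact_rxc_mc(counts.to_numpy(), seed=seed)
    return res, counts
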