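"""Reporter-score enrichment of KEGG pathways from KO-level comparisons.

Each KO (gene-family) is tested between groups with the Wilcoxon rank-sum
test; its p-value becomes a z-score via the inverse normal, signed by the
direction of change.  A pathway's raw score is the mean of its member KO
z-scores scaled by √k, and is background-corrected against the mean and
standard deviation of equally sized random KO sets so that |corrected
score| > 1.65 (one-sided normal 0.05) flags a coordinately shifted pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import AnalysisConfig
from .metadata import Cohort
from .stats import TestResult, wilcoxon_rank_sum
from .tables import AbundanceTable

log = logging.getLogger(__name__)

_P_CLIP = 1e-15


def ko_level_pvalues(ko_table: AbundanceTable, cohort: Cohort,
                     group_pair: tuple[str, str] = ("RA", "HC"),
                     timepoint: str | None = "M0",
                     sample_sets=None) -> pd.DataFrame:
    """Wilcoxon rank-sum p-value and direction per KO."""
    g1, g2 = group_pair
    if sample_sets is not None:
        s1, s2 = (list(s) for s in sample_sets)
    else:
        s1 = cohort.samples(group=g1, timepoint=timepoint)
        s2 = cohort.samples(group=g2, timepoint=timepoint)
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError(f"need >= 3 samples per group, got {len(s1)}/{len(s2)}")
    x = ko_table.data[s1].to_numpy(dtype=float)
    y = ko_table.data[s2].to_numpy(dtype=float)
    rows = []
    for i, ko in enumerate(ko_table.feature_ids):
        res = wilcoxon_rank_sum(x[i], y[i], mode="auto")
        d = res.direction
        if d == 0:
            d = int(np.sign(x[i].mean() - y[i].mean()))
        rows.append({"ko": ko, "p_value": res.p_value, "direction": d})
    return pd.DataFrame(rows)


def corrected_reporter_scores(ko_results: pd.DataFrame,
                              kegg_map: dict[str, list[str]],
                              config: AnalysisConfig | None = None,
                              n_background_draws: int = 1000,
                              seed: int | None = None,
                              signed: bool = True) -> pd.DataFrame:
    """Background-corrected reporter score per pathway.

    z_ko = Φ⁻¹(1 − p) (signed by direction when ``signed``); the pathway raw
    score Σz/√k is centred and scaled by the mean/sd of raw scores of
    ``n_background_draws`` random size-k sets of mapped KOs (drawn without
    replacement, seeded, cached per k).
    """
    config = config or AnalysisConfig()
    if seed is None:
        seed = config.rng_seed
    if n_background_draws < 100:
        raise ValueError("n_background_draws must be >= 100")
    z_by_ko: dict[str, float] = {}
    for row in ko_results.itertuples(index=False):
        p = min(max(row.p_value, _P_CLIP), 1 - _P_CLIP)
        z = norm.ppf(1 - p)
        if signed:
            z *= (row.direction if row.direction != 0 else 1)
        z_by_ko[row.ko] = float(z)

    mapped = sorted(set(ko for kos in kegg_map.values() for ko in kos) & set(z_by_ko))
    if not mapped:
        raise ValueError("no mapped KO has a p-value")
    z_pool = np.array([z_by_ko[k] for k in mapped])
    rng = np.random.default_rng(seed)
    bg_cache: dict[int, tuple[float, float]] = {}

    def background(k: int) -> tuple[float, float]:
        if k not in bg_cache:
            draws = np.empty(n_background_draws)
            for i in range(n_background_draws):
                idx = rng.choice(len(z_pool), size=k, replace=False)
                draws[i] = z_pool[idx].sum() / np.sqrt(k)
            sd = draws.std(ddof=1)
            bg_cache[k] = (float(draws.mean()), float(sd if sd > 0 else 1.0))
        return bg_cache[k]

    rows = []
    for pathway in sorted(kegg_map):
        kos = [k for k in kegg_map[pathway] if k in z_by_ko]
        if not kos:
            log.info("pathway %s has no mapped KO with a p-value; skipped", pathway)
            continue
        k = len(kos)
        raw = sum(z_by_ko[ko] for ko in kos) / np.sqrt(k)
        mu, sd = background(min(k, len(z_pool)))
        corrected = (raw - mu) / sd
        rows.append({
            "pathway_id": pathway, "n_kos": k, "raw_z": raw,
            "corrected_score": corrected,
            "direction": "up_in_group1" if corrected >= 0 else "down_in_group1",
            "significant": abs(corrected) > config.reporter_threshold,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.reindex(out["corrected_score"].abs()
                          .sort_values(ascending=False, kind="mergesort").index)
        out = out.reset_index(drop=True)
    return out
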