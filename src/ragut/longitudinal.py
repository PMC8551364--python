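"""Treatment-time analyses within and across arms.

Per-arm Jonckheere–Terpstra trend scans over the ordered sampling visits,
rank-sum comparisons of clinical indices at each post-baseline visit against
baseline, cross-arm rank-sum comparisons per visit, and the restoration
rule: a species is called restored when it differed from healthy controls at
baseline and shows a significant treatment-time trend in the opposite
direction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .metadata import Cohort, TIMEPOINTS
from .stats import bh_fdr, jonckheere_terpstra, wilcoxon_rank_sum
from .tables import AbundanceTable

log = logging.getLogger(__name__)


def _arm_timepoint_groups(table: AbundanceTable, cohort: Cohort, arm: str,
                          timepoints=TIMEPOINTS):
    groups = []
    used = []
    for tp in timepoints:
        sids = cohort.samples(arm=arm, timepoint=tp)
        if sids:
            groups.append(sids)
            used.append(tp)
    return groups, used


def trend_scan(table: AbundanceTable, cohort: Cohort, arm: str,
               config: AnalysisConfig | None = None,
               mode: str = "normal") -> pd.DataFrame:
    """Jonckheere–Terpstra trend per feature across ordered visits in an arm.

    Visits are treated as independent ordered groups, as the unpaired usage
    of the test implies; the two-sided p doubles the smaller one-sided tail.
    """
    config = config or AnalysisConfig()
    sample_groups, used_tps = _arm_timepoint_groups(table, cohort, arm)
    if len(sample_groups) < 3:
        raise ValueError(f"arm {arm!r} has samples at fewer than 3 timepoints")
    mats = [table.data[sids].to_numpy(dtype=float) for sids in sample_groups]
    rows = []
    for i, fid in enumerate(table.feature_ids):
        vals = [m[i] for m in mats]
        if all((v == 0).all() for v in vals):
            continue
        res = jonckheere_terpstra(vals, mode=mode, alternative="two_sided",
                                  n_permutations=config.n_permutations,
                                  seed=config.rng_seed)
        rows.append({
            "feature_id": fid, "arm": arm, "statistic": res.statistic,
            "p_value": res.p_value,
            "trend_direction": "increasing" if res.direction >= 0 else "decreasing",
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["p_value"] < config.alpha
        out = out[["feature_id", "arm", "statistic", "p_value", "q_value",
                   "trend_direction", "significant"]]
    return out


def _stars(p: float, alpha: float = 0.05) -> str:
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def clinical_timepoint_tests(cohort: Cohort, arm: str, index: str,
                             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Rank-sum of each post-baseline visit vs baseline for one index in one arm."""
    config = config or AnalysisConfig()
    base_ids = cohort.samples(arm=arm, timepoint="M0")
    base = cohort.index_values(index, base_ids).dropna()
    if len(base) < 3:
        raise ValueError(f"fewer than 3 baseline values for {index} in arm {arm}")
    rows = []
    for tp in TIMEPOINTS[1:]:
        ids = cohort.samples(arm=arm, timepoint=tp)
        vals = cohort.index_values(index, ids).dropna()
        if len(vals) < 3:
            log.info("timepoint %s has <3 non-missing %s values; skipped", tp, index)
            continue
        res = wilcoxon_rank_sum(vals.to_numpy(), base.to_numpy(), mode="auto")
        rows.append({"index": index, "arm": arm, "timepoint": tp,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "stars": _stars(res.p_value, config.alpha)})
    return pd.DataFrame(rows, columns=["index", "arm", "timepoint",
                                       "statistic", "p_value", "stars"])


def cross_arm_tests(table: AbundanceTable, cohort: Cohort, timepoint: str,
                    config: AnalysisConfig | None = None,
                    arms: tuple[str, str] = ("HQT", "LEF")) -> pd.DataFrame:
    """Per-feature rank-sum between the two treatment arms at one visit."""
    config = config or AnalysisConfig()
    s1 = cohort.samples(arm=arms[0], timepoint=timepoint)
    s2 = cohort.samples(arm=arms[1], timepoint=timepoint)
    if not s1 or not s2:
        raise ValueError(f"both arms must be sampled at {timepoint}")
    from .differential import differential_features
    return differential_features(table, cohort, group_pair=arms, config=config,
                                 sample_sets=(s1, s2))


def restoration_flags(baseline_diff: pd.DataFrame, trend: pd.DataFrame,
                      arm: str) -> pd.DataFrame:
    """Flag features restored under treatment.

    Restored ⟺ significantly different from healthy controls at baseline AND
    a significant treatment-time trend in the opposite direction (an
    RA-enriched feature must trend downward, a depleted feature upward).
    Deterministic given its two inputs; no additional randomness.
    """
    trend_by_fid = trend.set_index("feature_id")
    rows = []
    for row in baseline_diff.itertuples(index=False):
        fid = row.feature_id
        baseline_dir = row.direction  # e.g. RA_enriched / HC_enriched
        restored = False
        trend_dir = ""
        if fid in trend_by_fid.index:
            t = trend_by_fid.loc[fid]
            trend_dir = t["trend_direction"]
            if bool(row.significant) and bool(t["significant"]):
                enriched_in_patients = baseline_dir.endswith("RA_enriched") or \
                    baseline_dir == "RA_enriched"
                restored = (enriched_in_patients and trend_dir == "decreasing") or \
                    (not enriched_in_patients and trend_dir == "increasing")
        rows.append({"feature_id": fid, "arm": arm,
                     "baseline_direction": baseline_dir,
                     "trend_direction": trend_dir, "restored": restored})
    return pd.DataFrame(rows)
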