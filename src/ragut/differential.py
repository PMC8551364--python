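"""Differential abundance between groups and enrichment-set summaries.

One Wilcoxon rank-sum test per feature at baseline, a Benjamini–Hochberg
q-value across features within a level, and a direction call from the group
mean relative abundance (medians of rare taxa are frequently zero).  The
significance gate is the raw p-value at alpha, matching the study design;
q-values are reported alongside for reuse at an FDR gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import OriginRecord
from .metadata import Cohort
from .stats import bh_fdr, wilcoxon_rank_sum
from .tables import AbundanceTable, parse_lineage

log = logging.getLogger(__name__)


def _prevalence_filter(data: pd.DataFrame, min_fraction: float) -> pd.DataFrame:
    if min_fraction <= 0:
        return data
    prevalence = (data > 0).mean(axis=1)
    return data.loc[prevalence >= min_fraction]


def differential_features(table: AbundanceTable, cohort: Cohort,
                          group_pair: tuple[str, str] = ("RA", "HC"),
                          config: AnalysisConfig | None = None,
                          timepoint: str | None = "M0",
                          sample_sets: tuple[list[str], list[str]] | None = None,
                          ) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon scan.

    Groups are compared at one timepoint (baseline by default); pass
    ``sample_sets`` to override the sample selection entirely (used by the
    cross-arm comparisons).  Returns one row per tested feature with p, BH q,
    group means, direction and the significance call at raw p < alpha.
    """
    config = config or AnalysisConfig()
    g1, g2 = group_pair
    if sample_sets is not None:
        s1, s2 = (list(s) for s in sample_sets)
    else:
        s1 = cohort.samples(group=g1, timepoint=timepoint)
        s2 = cohort.samples(group=g2, timepoint=timepoint)
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError(f"need >= 3 samples per group, got {len(s1)}/{len(s2)}")
    data = table.data[s1 + s2]
    nonzero = data.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("skipping %d all-zero features", int((~nonzero).sum()))
    data = _prevalence_filter(data.loc[nonzero], config.prevalence_min)

    rows = []
    x_all = data[s1].to_numpy(dtype=float)
    y_all = data[s2].to_numpy(dtype=float)
    for i, fid in enumerate(data.index):
        res = wilcoxon_rank_sum(x_all[i], y_all[i], mode="auto")
        m1, m2 = float(x_all[i].mean()), float(y_all[i].mean())
        rows.append({
            "feature_id": fid, "level": table.level,
            "mean_group1": m1, "mean_group2": m2,
            "p_value": res.p_value,
            "direction": f"{g1}_enriched" if m1 > m2 else f"{g2}_enriched",
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["p_value"] < config.alpha
        out = out[["feature_id", "level", "mean_group1", "mean_group2",
                   "p_value", "q_value", "direction", "significant"]]
    else:
        out = pd.DataFrame(columns=["feature_id", "level", "mean_group1",
                                    "mean_group2", "p_value", "q_value",
                                    "direction", "significant"])
    return out


def pathway_differential(table: AbundanceTable, cohort: Cohort,
                         config: AnalysisConfig | None = None,
                         group_pair: tuple[str, str] = ("RA", "HC"),
                         timepoint: str | None = "M0") -> pd.DataFrame:
    """Differential scan over community pathway abundances.

    Same machinery as the taxonomic scan; directions read as up/down
    regulated in the first group of the pair.
    """
    return differential_features(table, cohort, group_pair=group_pair,
                                 config=config, timepoint=timepoint)


# ---------------------------------------------------------------------------
# enrichment-set composition summaries
# ---------------------------------------------------------------------------

def enrichment_phylum_summary(diff: pd.DataFrame,
                              lineage_map: dict | None = None) -> pd.DataFrame:
    """Phylum composition of each enriched species set.

    Percent = count / set size × 100 (2 d.p. semantics preserved by the
    writer).  Species without a resolvable lineage count as "unclassified".
    """
    rows = []
    sig = diff[diff["significant"]] if len(diff) else diff
    for set_label, sub in (sig.groupby("direction") if len(sig) else ()):
        total = len(sub)
        phyla = []
        for fid in sub["feature_id"]:
            try:
                lin = lineage_map[fid] if lineage_map else parse_lineage(fid)
                phyla.append(lin.name("phylum") or "unclassified")
            except Exception:
                phyla.append("unclassified")
        counts = pd.Series(phyla).value_counts()
        for stratum, count in counts.sort_values(ascending=False).items():
            rows.append({"set_label": set_label, "stratum": stratum,
                         "count": int(count),
                         "percent": round(100.0 * count / total, 2),
                         "denominator": "set_size"})
    return pd.DataFrame(rows, columns=["set_label", "stratum", "count",
                                       "percent", "denominator"])


def enrichment_origin_summary(diff: pd.DataFrame,
                              origin_records: list[OriginRecord],
                              species_name=None) -> pd.DataFrame:
    """Origin (oral/gut/other) composition of each enriched species set.

    Reported against two denominators, since either full-set or known-origin
    fractions may be of interest: ``set_size`` (all enriched species) and
    ``known_origin`` (species with an oral or gut call only).
    """
    origin_by_species = {r.species: r.origin for r in origin_records}
    if species_name is None:
        def species_name(fid):
            try:
                return parse_lineage(fid).name("species") or fid
            except Exception:
                return fid
    rows = []
    sig = diff[diff["significant"]] if len(diff) else diff
    for set_label, sub in (sig.groupby("direction") if len(sig) else ()):
        total = len(sub)
        origins = [origin_by_species.get(species_name(fid), "other_unknown")
                   for fid in sub["feature_id"]]
        counts = pd.Series(origins).value_counts()
        known = int(counts.get("oral", 0) + counts.get("gut", 0))
        for stratum in ("oral", "gut", "other_unknown"):
            c = int(counts.get(stratum, 0))
            rows.append({"set_label": set_label, "stratum": stratum, "count": c,
                         "percent": round(100.0 * c / total, 2) if total else np.nan,
                         "denominator": "set_size"})
            if stratum != "other_unknown":
                rows.append({"set_label": set_label, "stratum": stratum, "count": c,
                             "percent": round(100.0 * c / known, 2) if known else np.nan,
                             "denominator": "known_origin"})
    return pd.DataFrame(rows, columns=["set_label", "stratum", "count",
                                       "percent", "denominator"])
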