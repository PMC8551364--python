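"""Three-way association assembly: clinical indices × species × pathways.

Spearman correlations are computed block-wise (clinical–species,
clinical–pathway, species–pathway) on the pooled baseline samples, BH-
corrected within each block, and assembled into a triangle: species and
pathways are retained only when they carry at least one significant edge to
a clinical index, and species–pathway edges are restricted to retained
nodes.  Nodes are annotated with their differential-enrichment direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .metadata import CLINICAL_INDICES, Cohort
from .stats import bh_fdr, spearman_rho
from .tables import AbundanceTable

log = logging.getLogger(__name__)

#: clinical indices entering the association triangle by default
DEFAULT_TRIANGLE_INDICES = ("ESR", "CRP", "RF", "anti_CCP", "AST")


def clinical_matrix(cohort: Cohort, sample_ids,
                    indices=DEFAULT_TRIANGLE_INDICES) -> pd.DataFrame:
    """Indices × samples matrix of clinical values (NaN = missing)."""
    return pd.DataFrame(
        {sid: [cohort.df.loc[sid, ix] for ix in indices] for sid in sample_ids},
        index=list(indices), dtype=float)


def correlation_block(a: pd.DataFrame, b: pd.DataFrame, side: str,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """All-pairs Spearman correlations between the rows of two matrices.

    Matrices are features × samples over a shared sample set; missing values
    are dropped pairwise; q-values are BH within this block only.  Edges are
    significant at q < alpha.
    """
    config = config or AnalysisConfig()
    shared = [s for s in a.columns if s in set(b.columns)]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    av = a[shared].to_numpy(dtype=float)
    bv = b[shared].to_numpy(dtype=float)
    rows = []
    for i, a_id in enumerate(a.index):
        for j, b_id in enumerate(b.index):
            res = spearman_rho(av[i], bv[j])
            if not res.valid:
                log.info("degenerate pair (%s, %s) skipped", a_id, b_id)
                continue
            rows.append({"side": side, "a_id": a_id, "b_id": b_id,
                         "rho": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows, columns=["side", "a_id", "b_id", "rho", "p_value"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["sign"] = np.sign(out["rho"]).astype(int)
        out["significant"] = out["q_value"] < config.alpha
    else:
        for col, dtype in (("q_value", float), ("sign", int), ("significant", bool)):
            out[col] = pd.Series(dtype=dtype)
    return out


@dataclass
class TriangleResult:
    species: list[str]
    pathways: list[str]
    clinical_indices: list[str]
    edges: pd.DataFrame
    annotations: dict[str, str] = field(default_factory=dict)


def assemble_triangle(clin_species: pd.DataFrame, clin_pathway: pd.DataFrame,
                      species_pathway: pd.DataFrame,
                      diff_species: pd.DataFrame | None = None,
                      diff_pathways: pd.DataFrame | None = None) -> TriangleResult:
    """Assemble the clinical/species/pathway triangle from its three blocks.

    Clinical blocks must have the clinical index as ``a_id``.  A species or
    pathway is retained iff it has at least one significant clinical edge;
    the species–pathway block is then restricted to retained nodes.
    """
    sig_cs = clin_species[clin_species["significant"]]
    sig_cp = clin_pathway[clin_pathway["significant"]]
    species = sorted(sig_cs["b_id"].unique())
    pathways = sorted(sig_cp["b_id"].unique())
    indices = sorted(set(sig_cs["a_id"]) | set(sig_cp["a_id"]))

    sp = species_pathway[species_pathway["significant"]
                         & species_pathway["a_id"].isin(species)
                         & species_pathway["b_id"].isin(pathways)]
    edges = pd.concat([sig_cs, sig_cp, sp], ignore_index=True)

    annotations: dict[str, str] = {}
    for diff in (diff_species, diff_pathways):
        if diff is None or not len(diff):
            continue
        for row in diff.itertuples(index=False):
            if bool(row.significant):
                annotations[row.feature_id] = row.direction
    return TriangleResult(species, pathways, indices, edges, annotations)


def triangle_records(tri: TriangleResult) -> pd.DataFrame:
    """Long-format edge table for the 'triangle' result schema."""
    rows = []
    for row in tri.edges.itertuples(index=False):
        rows.append({
            "side": row.side, "a_id": row.a_id, "b_id": row.b_id,
            "rho": row.rho, "p_value": row.p_value, "q_value": row.q_value,
            "sign": int(row.sign),
            "a_annotation": tri.annotations.get(row.a_id, "none"),
            "b_annotation": tri.annotations.get(row.b_id, "none"),
        })
    return pd.DataFrame(rows, columns=["side", "a_id", "b_id", "rho", "p_value",
                                       "q_value", "sign", "a_annotation",
                                       "b_annotation"])


def export_triangle_table(tri: TriangleResult, path) -> None:
    from .io import write_result_table
    write_result_table(triangle_records(tri), path, "triangle")
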