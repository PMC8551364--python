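"""End-to-end orchestration: every stage from one config, one output tree.

``run_all`` executes validate → diversity → differential → reporter →
longitudinal → triangle → enterotype → select-features over either real
input files or a freshly simulated cohort, writes every result as TSV and a
``manifest.json`` tying each output to its stage and seed.  The manifest
contains no timestamps, so two runs with the same seed produce
byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .differential import (differential_features, enrichment_origin_summary,
                           enrichment_phylum_summary, pathway_differential)
from .diversity import (alpha_diversity_table, bray_curtis_matrix, pcoa_embed,
                        permanova)
from .enterotype import enterotype_assign, enterotype_contingency_test
from .io import (read_clinical_table, read_gene_family_table, read_kegg_map,
                 read_origin_table, read_pathway_table, read_taxonomic_profile,
                 write_abundance_table, write_clinical_table,
                 write_distance_matrix, write_kegg_map, write_origin_table,
                 write_result_table)
from .longitudinal import (clinical_timepoint_tests, cross_arm_tests,
                           restoration_flags, trend_scan)
from .metadata import CLINICAL_INDICES, Cohort
from .reporter import corrected_reporter_scores, ko_level_pvalues
from .selection import run_feature_selection
from .simulate import SimulationDesign, SyntheticCohort, simulate_cohort
from .tables import AbundanceTable, extract_rank_table
from .triangle import (DEFAULT_TRIANGLE_INDICES, assemble_triangle,
                       clinical_matrix, correlation_block, triangle_records)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def record(self, stage: str, seed: int, outputs: list[str]) -> None:
        self.stages.append({"stage": stage, "seed": seed,
                            "outputs": sorted(outputs)})
        self.outputs.extend(sorted(outputs))

    def write(self, path: Path) -> None:
        payload = {"config": self.config, "input_checksums": self.input_checksums,
                   "stages": self.stages, "outputs": self.outputs}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineInputs:
    cohort: Cohort
    species: AbundanceTable
    pathways: AbundanceTable
    kos: AbundanceTable
    kegg_map: dict[str, list[str]]
    origin_records: list


def write_simulated_inputs(sc: SyntheticCohort, out_dir: Path) -> list[str]:
    """Write a simulated cohort in the dialects the readers consume."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(sc.species, out_dir / "species_profile.tsv", "#lineage")
    write_abundance_table(sc.pathways, out_dir / "pathway_abundance.tsv", "#pathway")
    write_abundance_table(sc.kos, out_dir / "gene_families.tsv", "#gene_family")
    write_kegg_map(sc.kegg_map, out_dir / "kegg_map.tsv")
    write_clinical_table(sc.cohort, out_dir / "clinical.tsv")
    write_origin_table(sc.origin_records, out_dir / "origin.tsv")
    gt = sc.ground_truth
    rows = ([{"item": "spiked_up", "value": f} for f in gt.spiked_up]
            + [{"item": "spiked_down", "value": f} for f in gt.spiked_down]
            + [{"item": f"enterotype:{s}", "value": e}
               for s, e in sorted(gt.enterotype.items())]
            + [{"item": f"positive_pathway_up", "value": p}
               for p in gt.positive_up_pathways]
            + [{"item": f"positive_pathway_down", "value": p}
               for p in gt.positive_down_pathways])
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    return [f.name for f in sorted(out_dir.glob("*.tsv"))]


def load_inputs(paths: dict[str, str]) -> PipelineInputs:
    cohort = read_clinical_table(paths["clinical"])
    species = read_taxonomic_profile(paths["species"], "species")
    pathways = read_pathway_table(paths["pathways"])
    kos = read_gene_family_table(paths["kos"])
    kegg_map = read_kegg_map(paths["kegg_map"])
    origin = read_origin_table(paths["origin"]) if "origin" in paths else []
    return PipelineInputs(cohort, species, pathways, kos, kegg_map, origin)


def validate_inputs(inputs: PipelineInputs) -> pd.DataFrame:
    """Cross-check tables against metadata and return the cohort summary."""
    meta_ids = set(inputs.cohort.sample_ids)
    for name, table in (("species", inputs.species), ("pathways", inputs.pathways),
                        ("kos", inputs.kos)):
        missing = meta_ids - set(table.sample_ids)
        if missing:
            raise ValueError(f"{name} table lacks samples {sorted(missing)[:5]}")
    mapped = set(k for kos in inputs.kegg_map.values() for k in kos)
    if not mapped & set(inputs.kos.feature_ids):
        raise ValueError("KEGG map shares no KO with the gene-family table")
    return inputs.cohort.counts()


def run_all(out_dir: str | Path,
            config: AnalysisConfig | None = None,
            design: SimulationDesign | None = None,
            inputs: PipelineInputs | None = None,
            simulate: bool = False,
            selection_opts: dict | None = None) -> RunManifest:
    """Run every analysis stage and write all results under ``out_dir``.

    With ``simulate=True`` the inputs are generated first (written under
    ``out_dir/inputs``); otherwise ``inputs`` must be supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()
    design = design or SimulationDesign(rng_seed=config.rng_seed)
    selection_opts = dict(selection_opts or {})
    selection_opts.setdefault("max_features_scanned", 10)
    selection_opts.setdefault("n_trees", 100)

    manifest = RunManifest(config={"analysis": config.to_dict(),
                                   "simulation": design.to_dict() if simulate else None},
                           input_checksums={})
    if simulate:
        sc = simulate_cohort(design)
        in_dir = out / "inputs"
        written = write_simulated_inputs(sc, in_dir)
        manifest.record("simulate", design.rng_seed,
                        [f"inputs/{w}" for w in written])
        inputs = PipelineInputs(sc.cohort, sc.species, sc.pathways, sc.kos,
                                sc.kegg_map, sc.origin_records)
        for w in written:
            manifest.input_checksums[f"inputs/{w}"] = _checksum(in_dir / w)
    if inputs is None:
        raise ValueError("either pass inputs or set simulate=True")

    def _stage(name: str, fn):
        log.info("stage %s", name)
        try:
            files = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, config.rng_seed, files)

    _stage("validate", lambda: _do_validate(inputs, out))
    _stage("diversity", lambda: _do_diversity(inputs, config, out))
    _stage("differential", lambda: _do_differential(inputs, config, out))
    _stage("reporter", lambda: _do_reporter(inputs, config, out))
    _stage("longitudinal", lambda: _do_longitudinal(inputs, config, out))
    _stage("triangle", lambda: _do_triangle(inputs, config, out))
    _stage("enterotype", lambda: _do_enterotype(inputs, config, out))
    _stage("select_features", lambda: _do_selection(inputs, config, out,
                                                    selection_opts))
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage bodies
# ---------------------------------------------------------------------------

def _do_validate(inputs: PipelineInputs, out: Path) -> list[str]:
    summary = validate_inputs(inputs)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    return ["cohort_summary.tsv"]

def _do_diversity(inputs, config, out: Path) -> list[str]:
    files = []
    for name, table in (("species", inputs.species), ("gene_family", inputs.kos)):
        alpha = alpha_diversity_table(table)
        write_result_table(alpha, out / f"alpha_{name}.tsv", "alpha")
        files.append(f"alpha_{name}.tsv")
    bc = bray_curtis_matrix(inputs.kos)
    write_distance_matrix(bc.sample_ids, bc.values, out / "bray_curtis_gene_family.tsv")
    files.append("bray_curtis_gene_family.tsv")
    base = inputs.cohort.baseline_samples()
    bc_base = bc.submatrix(base)
    ord_res = pcoa_embed(bc_base, k=2)
    coords = pd.DataFrame(ord_res.coordinates, columns=["PCo1", "PCo2"])
    coords.insert(0, "sample_id", ord_res.sample_ids)
    coords.to_csv(out / "pcoa_gene_family.tsv", sep="\t", index=False,
                  float_format="%.6g")
    files.append("pcoa_gene_family.tsv")
    groups = inputs.cohort.df.loc[base, "group"]
    perm = permanova(bc_base, groups, n_permutations=config.n_permutations,
                     seed=config.rng_seed)
    pd.DataFrame([{"metric": "bray_curtis", "level": "gene_family",
                   "pseudo_F": perm.statistic, "p_value": perm.p_value,
                   "n_permutations": config.n_permutations}]).to_csv(
        out / "permanova.tsv", sep="\t", index=False, float_format="%.6g")
    files.append("permanova.tsv")
    return files

def _do_differential(inputs, config, out: Path) -> list[str]:
    files = []
    diff_sp = differential_features(inputs.species, inputs.cohort, config=config)
    write_result_table(diff_sp, out / "differential_species.tsv", "differential")
    files.append("differential_species.tsv")
    for rank in ("genus", "family", "order", "class", "phylum"):
        table = extract_rank_table(inputs.species, rank)
        diff = differential_features(table, inputs.cohort, config=config)
        write_result_table(diff, out / f"differential_{rank}.tsv", "differential")
        files.append(f"differential_{rank}.tsv")
    diff_pw = pathway_differential(inputs.pathways, inputs.cohort, config=config)
    write_result_table(diff_pw, out / "differential_pathways.tsv", "differential")
    files.append("differential_pathways.tsv")
    phylum_summary = enrichment_phylum_summary(diff_sp)
    write_result_table(phylum_summary, out / "enrichment_phylum.tsv", "enrichment")
    files.append("enrichment_phylum.tsv")
    if inputs.origin_records:
        origin_summary = enrichment_origin_summary(diff_sp, inputs.origin_records)
        write_result_table(origin_summary, out / "enrichment_origin.tsv", "enrichment")
        files.append("enrichment_origin.tsv")
    return files

def _do_reporter(inputs, config, out: Path) -> list[str]:
    kop = ko_level_pvalues(inputs.kos, inputs.cohort)
    rep = corrected_reporter_scores(kop, inputs.kegg_map, config=config,
                                    seed=config.rng_seed)
    write_result_table(rep, out / "reporter_results.tsv", "reporter")
    return ["reporter_results.tsv"]

def _do_longitudinal(inputs, config, out: Path) -> list[str]:
    files = []
    diff_base = differential_features(inputs.species, inputs.cohort, config=config)
    for arm in ("HQT", "LEF"):
        tr = trend_scan(inputs.species, inputs.cohort, arm, config=config)
        write_result_table(tr, out / f"trend_{arm}.tsv", "trend")
        files.append(f"trend_{arm}.tsv")
        tr_pw = trend_scan(inputs.pathways, inputs.cohort, arm, config=config)
        write_result_table(tr_pw, out / f"trend_pathways_{arm}.tsv", "trend")
        files.append(f"trend_pathways_{arm}.tsv")
        flags = restoration_flags(diff_base, tr, arm)
        flags.to_csv(out / f"restoration_{arm}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        files.append(f"restoration_{arm}.tsv")
        rows = []
        for index in CLINICAL_INDICES:
            if inputs.cohort.df.loc[inputs.cohort.samples(arm=arm), index].notna().sum() >= 6:
                rows.append(clinical_timepoint_tests(inputs.cohort, arm, index,
                                                     config=config))
        if rows:
            write_result_table(pd.concat(rows, ignore_index=True),
                               out / f"clinical_timepoints_{arm}.tsv", "timepoint")
            files.append(f"clinical_timepoints_{arm}.tsv")
    for tp in ("M0", "M1", "M3", "M6"):
        try:
            cross = cross_arm_tests(inputs.species, inputs.cohort, tp, config=config)
        except ValueError:
            continue
        write_result_table(cross, out / f"cross_arm_{tp}.tsv", "differential")
        files.append(f"cross_arm_{tp}.tsv")
    return files

def _do_triangle(inputs, config, out: Path) -> list[str]:
    base = inputs.cohort.baseline_samples()
    clin = clinical_matrix(inputs.cohort, base, DEFAULT_TRIANGLE_INDICES)
    sp = inputs.species.data[base]
    pw = inputs.pathways.data[base]
    cs = correlation_block(clin, sp, "clinical_species", config)
    cp = correlation_block(clin, pw, "clinical_pathway", config)
    spw = correlation_block(sp, pw, "species_pathway", config)
    diff_sp = differential_features(inputs.species, inputs.cohort, config=config)
    diff_pw = pathway_differential(inputs.pathways, inputs.cohort, config=config)
    tri = assemble_triangle(cs, cp, spw, diff_sp, diff_pw)
    write_result_table(triangle_records(tri), out / "triangle.tsv", "triangle")
    return ["triangle.tsv"]

def _do_enterotype(inputs, config, out: Path) -> list[str]:
    genus = extract_rank_table(inputs.species, "genus")
    et = enterotype_assign(genus, config=config)
    labels = et.labels()
    write_result_table(
        pd.DataFrame({"sample_id": et.sample_ids,
                      "cluster": et.assignment.astype(int),
                      "dominant_genus": labels.to_numpy()}),
        out / "enterotype_assignments.tsv", "enterotype")
    write_result_table(
        pd.DataFrame({"k": list(et.ch_curve), "ch": list(et.ch_curve.values())}),
        out / "enterotype_ch_curve.tsv", "ch_curve")
    res, counts = enterotype_contingency_test(et, inputs.cohort,
                                              seed=config.rng_seed)
    counts_out = counts.reset_index()
    counts_out["fisher_p"] = res.p_value
    counts_out.to_csv(out / "enterotype_contingency.tsv", sep="\t", index=False,
                      float_format="%.6g")
    coords = pd.DataFrame(et.pca_coordinates, columns=["PC1", "PC2"])
    coords.insert(0, "sample_id", et.sample_ids)
    coords.to_csv(out / "enterotype_pca.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return ["enterotype_assignments.tsv", "enterotype_ch_curve.tsv",
            "enterotype_contingency.tsv", "enterotype_pca.tsv"]

def _do_selection(inputs, config, out: Path, opts: dict) -> list[str]:
    base = inputs.cohort.baseline_samples()
    table = inputs.species.select_samples(base)
    labels = inputs.cohort.df.loc[base, "group"]
    sel = run_feature_selection(table, labels, seed=config.rng_seed, **opts)
    write_result_table(
        pd.DataFrame({"rank": np.arange(1, len(sel.ranked_features) + 1),
                      "feature_id": sel.ranked_features,
                      "importance": np.nan}),
        out / "selection_ranking.tsv", "selection")
    curve = pd.DataFrame({"n_features": np.arange(1, len(sel.averaged_error) + 1),
                          "avg_error": sel.averaged_error})
    curve.to_csv(out / "selection_error_curve.tsv", sep="\t", index=False,
                 float_format="%.6g")
    pd.DataFrame({"feature_id": sel.optimal_set}).assign(
        cutoff=sel.cutoff, optimal_size=sel.optimal_size).to_csv(
        out / "selection_optimal_set.tsv", sep="\t", index=False,
        float_format="%.6g")
    return ["selection_ranking.tsv", "selection_error_curve.tsv",
            "selection_optimal_set.tsv"]
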