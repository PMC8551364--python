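"""Seeded synthetic cohorts with known ground truth.

The generator emulates the design of a two-arm longitudinal treatment study
of the rheumatoid-arthritis gut microbiome: 22 healthy controls sampled once
and 22 patients sampled at M0/M1/M3/M6 under two treatment arms (13 + 9); a
mixture of Bacteroides- and Prevotella-dominant enterotypes; a set of
disease-enriched and disease-depleted species spiked multiplicatively at
baseline and pulled back toward the healthy state at an arm-specific
restoration rate; KO/pathway tables driven linearly by species abundances;
and clinical indices coupled to a latent disease-activity score built from
the spiked species.

Species abundances follow a log-normal compositional model (archetype mean
+ per-subject offset + per-sample genus-block effect + residual noise),
with the spike applied before closure to 100 per sample.  True differential
status is defined pre-closure; closure-induced spillover is accepted.

Each generation stage draws from its own RNG stream derived from the master
seed by a fixed offset, so regenerating one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import OriginRecord
from .metadata import Cohort, TIMEPOINT_MONTHS, TIMEPOINTS
from .tables import AbundanceTable

_PHYLA_CYCLE = ("Firmicutes", "Proteobacteria", "Actinobacteria",
                "Bacteroidetes", "Fusobacteria")


@dataclass
class SimulationDesign:
    n_hc: int = 22
    n_ra: int = 22
    n_hqt: int = 13
    n_lef: int = 9
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_species: int = 200
    n_genera: int = 40
    n_pathways: int = 60
    n_kos: int = 600
    enterotype_fraction_prevotella: float = 0.2
    n_spiked_up: int = 37
    n_spiked_down: int = 21
    effect_fold: float = 4.0
    #: fraction of the baseline spike removed per month of treatment
    restoration_rate_hqt: float = 0.15
    restoration_rate_lef: float = 0.04
    noise_sd: float = 0.5
    subject_sd: float = 0.3
    genus_block_sd: float = 0.3
    #: log-scale boost of the dominant genus in each enterotype archetype
    dominance_log: float = 4.0
    ko_noise_sd: float = 0.3
    p_oral_up: float = 0.6
    p_gut_down: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hqt + self.n_lef != self.n_ra:
            raise ValueError("n_hqt + n_lef must equal n_ra")
        for name in ("n_hc", "n_ra", "n_hqt", "n_lef", "n_species", "n_genera",
                     "n_pathways", "n_kos"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.n_spiked_up + self.n_spiked_down >= self.n_species:
            raise ValueError("too many spiked species")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d


@dataclass
class GroundTruth:
    spiked_up: list[str]
    spiked_down: list[str]
    enterotype: dict[str, str]            # subject -> Bacteroides|Prevotella
    contribution: pd.DataFrame | None     # KO x species weights
    positive_up_pathways: list[str] = field(default_factory=list)
    positive_down_pathways: list[str] = field(default_factory=list)
    clinical_couplings: dict = field(default_factory=dict)
    restoration_rates: dict[str, float] = field(default_factory=dict)

    @property
    def positive_pathways(self) -> list[str]:
        return self.positive_up_pathways + self.positive_down_pathways


def _stage_rng(design: SimulationDesign, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.rng_seed, stage]))


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

def generate_cohort_design(design: SimulationDesign) -> Cohort:
    """Subjects, arms and sampling visits: HC once at M0, RA at every visit."""
    rows = []
    for i in range(design.n_hc):
        subj = f"HC{i + 1:02d}"
        rows.append({"sample_id": f"{subj}_M0", "subject_id": subj,
                     "group": "HC", "arm": "none", "timepoint": "M0"})
    for i in range(design.n_ra):
        subj = f"RA{i + 1:02d}"
        arm = "HQT" if i < design.n_hqt else "LEF"
        for tp in design.timepoints:
            rows.append({"sample_id": f"{subj}_{tp}", "subject_id": subj,
                         "group": "RA", "arm": arm, "timepoint": tp})
    df = pd.DataFrame(rows).set_index("sample_id")
    return Cohort(df)


# ---------------------------------------------------------------------------
# species profiles
# ---------------------------------------------------------------------------

def _species_catalog(design: SimulationDesign) -> pd.DataFrame:
    """Fixed genus/phylum layout: genus 1 = Bacteroides, genus 2 = Prevotella."""
    genera = ["Bacteroides", "Prevotella"]
    genera += [f"Genus{i + 1:02d}" for i in range(design.n_genera - 2)]
    phyla = {"Bacteroides": "Bacteroidetes", "Prevotella": "Bacteroidetes"}
    for i, g in enumerate(genera[2:]):
        phyla[g] = _PHYLA_CYCLE[i % len(_PHYLA_CYCLE)]
    rows = []
    for s in range(design.n_species):
        g = genera[s % design.n_genera]
        p = phyla[g]
        species = f"{g}_sp{s + 1:03d}"
        lineage = (f"k__Bacteria|p__{p}|c__{p}ia|o__{p}ales"
                   f"|f__{g}aceae|g__{g}|s__{species}")
        rows.append({"lineage": lineage, "species": species, "genus": g,
                     "phylum": p, "genus_index": s % design.n_genera})
    return pd.DataFrame(rows)


def simulate_species_profiles(design: SimulationDesign, cohort: Cohort
                              ) -> tuple[AbundanceTable, GroundTruth]:
    """Species relative-abundance table (percent, closed to 100) + ground truth."""
    rng = _stage_rng(design, 1)
    catalog = _species_catalog(design)
    n_sp = design.n_species

    base_log = rng.normal(0.0, 1.2, size=n_sp)
    # spiked species drawn outside the two enterotype-defining genera
    eligible = catalog.index[~catalog["genus"].isin(["Bacteroides", "Prevotella"])]
    spiked = rng.choice(eligible, size=design.n_spiked_up + design.n_spiked_down,
                        replace=False)
    up_idx = np.sort(spiked[: design.n_spiked_up])
    down_idx = np.sort(spiked[design.n_spiked_up:])

    subjects = cohort.df["subject_id"].unique()
    prevotella = {
        s: bool(rng.random() < design.enterotype_fraction_prevotella)
        for s in subjects
    }
    subject_offsets = {s: rng.normal(0.0, design.subject_sd, size=n_sp)
                       for s in subjects}

    genus_idx = catalog["genus_index"].to_numpy()
    is_bacteroides = (catalog["genus"] == "Bacteroides").to_numpy()
    is_prevotella = (catalog["genus"] == "Prevotella").to_numpy()
    log_fold = np.log(design.effect_fold)
    rates = {"HQT": design.restoration_rate_hqt,
             "LEF": design.restoration_rate_lef, "none": 0.0}

    cols = {}
    for sid in cohort.sample_ids:
        meta = cohort.df.loc[sid]
        subj = meta["subject_id"]
        log_a = base_log + subject_offsets[subj]
        if prevotella[subj]:
            log_a = log_a + design.dominance_log * is_prevotella + 1.0 * is_bacteroides
        else:
            log_a = log_a + design.dominance_log * is_bacteroides + 1.0 * is_prevotella
        block = rng.normal(0.0, design.genus_block_sd, size=design.n_genera)
        log_a = log_a + block[genus_idx]
        log_a = log_a + rng.normal(0.0, design.noise_sd, size=n_sp)
        if meta["group"] == "RA":
            months = TIMEPOINT_MONTHS[meta["timepoint"]]
            remaining = max(0.0, 1.0 - rates[meta["arm"]] * months)
            log_a[up_idx] += log_fold * remaining
            log_a[down_idx] -= log_fold * remaining
        raw = np.exp(log_a)
        cols[sid] = 100.0 * raw / raw.sum()

    data = pd.DataFrame(cols, index=catalog["lineage"].to_numpy())
    data.index.name = "lineage"
    table = AbundanceTable(data, "species")
    gt = GroundTruth(
        spiked_up=[catalog.loc[i, "lineage"] for i in up_idx],
        spiked_down=[catalog.loc[i, "lineage"] for i in down_idx],
        enterotype={s: ("Prevotella" if prevotella[s] else "Bacteroides")
                    for s in subjects},
        contribution=None,
        restoration_rates={"HQT": design.restoration_rate_hqt,
                           "LEF": design.restoration_rate_lef},
    )
    return table, gt


# ---------------------------------------------------------------------------
# functional profiles
# ---------------------------------------------------------------------------

def simulate_functional_profiles(species_table: AbundanceTable, gt: GroundTruth,
                                 design: SimulationDesign
                                 ) -> tuple[AbundanceTable, AbundanceTable,
                                            dict[str, list[str]]]:
    """KO and pathway tables driven by species abundances, plus the KO map.

    Each KO is a weighted sum of one or two species' abundances times
    log-normal noise; a designated subset of pathways draws at least 70% of
    its KOs from spiked species, giving the reporter stage known positives.
    Pathway abundances are the sums of member-KO abundances.
    """
    rng = _stage_rng(design, 2)
    lineages = species_table.feature_ids
    idx_of = {fid: i for i, fid in enumerate(lineages)}
    up = [idx_of[f] for f in gt.spiked_up]
    down = [idx_of[f] for f in gt.spiked_down]
    background = [i for i in range(len(lineages))
                  if i not in set(up) | set(down)]

    kos_per_pw = max(1, design.n_kos // design.n_pathways)
    n_pos_up = max(1, design.n_pathways // 10)
    n_pos_down = max(1, design.n_pathways // 20)
    pathways = [f"PWY{i + 1:04d}" for i in range(design.n_pathways)]
    pos_up = pathways[:n_pos_up]
    pos_down = pathways[n_pos_up:n_pos_up + n_pos_down]

    contribution = np.zeros((design.n_kos, len(lineages)))
    kegg_map: dict[str, list[str]] = {pw: [] for pw in pathways}
    ko_names = [f"K{i + 1:05d}" for i in range(design.n_kos)]

    ko = 0
    for p, pw in enumerate(pathways):
        n_here = kos_per_pw if p < design.n_pathways - 1 else design.n_kos - ko
        for j in range(n_here):
            if pw in pos_up and j < int(np.ceil(0.8 * n_here)):
                sp = up[ko % len(up)]
            elif pw in pos_down and j < int(np.ceil(0.8 * n_here)):
                sp = down[ko % len(down)]
            else:
                sp = background[int(rng.integers(len(background)))]
            contribution[ko, sp] = np.exp(rng.normal(0.0, 0.25))
            if rng.random() < 0.3:  # a secondary contributing species
                sp2 = background[int(rng.integers(len(background)))]
                contribution[ko, sp2] += 0.3 * np.exp(rng.normal(0.0, 0.25))
            kegg_map[pw].append(ko_names[ko])
            ko += 1
    # a sprinkling of KOs shared between adjacent pathways (map need not
    # partition the KO universe)
    for p in range(0, design.n_pathways - 1, 7):
        kegg_map[pathways[p + 1]].append(kegg_map[pathways[p]][0])

    x = species_table.values()
    ko_values = contribution @ x
    noise = np.exp(rng.normal(0.0, design.ko_noise_sd, size=ko_values.shape))
    ko_values = ko_values * noise
    ko_df = pd.DataFrame(ko_values, index=ko_names,
                         columns=species_table.sample_ids)
    ko_df.index.name = "gene_family"
    ko_table = AbundanceTable(ko_df, "gene_family")

    pw_values = np.stack([
        ko_df.loc[sorted(set(kegg_map[pw]))].sum(axis=0).to_numpy()
        for pw in pathways])
    pw_df = pd.DataFrame(pw_values,
                         index=[f"{pw}: synthetic pathway {pw[3:]}" for pw in pathways],
                         columns=species_table.sample_ids)
    pw_df.index.name = "pathway"
    pw_table = AbundanceTable(pw_df, "pathway")

    gt.contribution = pd.DataFrame(contribution, index=ko_names, columns=lineages)
    gt.positive_up_pathways = pos_up
    gt.positive_down_pathways = pos_down
    return pw_table, ko_table, kegg_map


# ---------------------------------------------------------------------------
# clinical indices
# ---------------------------------------------------------------------------

#: (baseline level, coupling to disease activity, noise sd, floor,
#:  extra per-month treatment response by arm, RA-only)
DEFAULT_COUPLINGS: dict[str, dict] = {
    "ESR":      dict(base=22.0, slope=13.0, noise=8.0, floor=1.0,
                     arm_response={"HQT": 2.5, "LEF": 0.0}, ra_only=False),
    "CRP":      dict(base=1.2, slope=8.0, noise=4.0, floor=0.1,
                     arm_response={"HQT": 0.0, "LEF": 1.5}, ra_only=False),
    "RF":       dict(base=7.5, slope=70.0, noise=40.0, floor=1.0,
                     arm_response={"HQT": 6.0, "LEF": 8.0}, ra_only=False),
    "anti_CCP": dict(base=0.6, slope=37.0, noise=20.0, floor=0.1,
                     arm_response={"HQT": 0.0, "LEF": 0.0}, ra_only=False),
    "AST":      dict(base=20.5, slope=-2.0, noise=2.5, floor=5.0,
                     arm_response={"HQT": 0.0, "LEF": 0.0}, ra_only=False),
    "DAS28_CRP": dict(base=2.0, slope=1.3, noise=0.5, floor=0.5,
                      arm_response={"HQT": 0.15, "LEF": 0.15}, ra_only=True),
    "JSS":      dict(base=1.0, slope=2.5, noise=1.5, floor=0.0,
                     arm_response={"HQT": 0.5, "LEF": 0.3}, ra_only=True),
    "JTS":      dict(base=1.0, slope=3.0, noise=1.5, floor=0.0,
                     arm_response={"HQT": 0.5, "LEF": 0.3}, ra_only=True),
    "MS":       dict(base=5.0, slope=20.0, noise=10.0, floor=0.0,
                     arm_response={"HQT": 4.0, "LEF": 2.5}, ra_only=True),
    "VAS_P":    dict(base=1.0, slope=2.0, noise=1.0, floor=0.0,
                     arm_response={"HQT": 0.4, "LEF": 0.3}, ra_only=True),
    "VAS_D":    dict(base=1.0, slope=2.0, noise=1.0, floor=0.0,
                     arm_response={"HQT": 0.3, "LEF": 0.4}, ra_only=True),
    "HAQ":      dict(base=0.3, slope=0.6, noise=0.3, floor=0.0,
                     arm_response={"HQT": 0.0, "LEF": 0.08}, ra_only=True),
}


def disease_activity(species_table: AbundanceTable, gt: GroundTruth,
                     pseudocount: float = 1e-6) -> pd.Series:
    """Latent activity per sample: mean log abundance of disease-enriched
    species minus mean log abundance of disease-depleted species."""
    data = species_table.data
    up = np.log(data.loc[gt.spiked_up] + pseudocount).mean(axis=0)
    down = np.log(data.loc[gt.spiked_down] + pseudocount).mean(axis=0)
    return up - down


def simulate_clinical_indices(cohort: Cohort, species_table: AbundanceTable,
                              gt: GroundTruth, design: SimulationDesign,
                              couplings: dict | None = None) -> Cohort:
    """Fill clinical indices from the latent disease-activity score.

    Inflammation markers rise with activity, AST falls; the score itself
    decays as species restore under treatment, and each index additionally
    responds at an arm-specific per-month rate (emulating the observed
    pattern of ESR responding under one arm and CRP under the other).
    """
    rng = _stage_rng(design, 3)
    couplings = couplings if couplings is not None else DEFAULT_COUPLINGS
    d = disease_activity(species_table, gt)
    hc_ids = cohort.samples(group="HC")
    d_centred = d - d.loc[hc_ids].mean()

    df = cohort.df.copy()
    for index, cpl in couplings.items():
        vals = []
        for sid in cohort.sample_ids:
            meta = df.loc[sid]
            if cpl.get("ra_only") and meta["group"] == "HC":
                vals.append(np.nan)
                continue
            months = TIMEPOINT_MONTHS[meta["timepoint"]]
            v = cpl["base"] + cpl["slope"] * d_centred[sid]
            if meta["arm"] in cpl["arm_response"]:
                v -= cpl["arm_response"][meta["arm"]] * months
            v += rng.normal(0.0, cpl["noise"])
            vals.append(max(cpl["floor"], v))
        df[index] = vals
    gt.clinical_couplings = couplings
    return Cohort(df)


# ---------------------------------------------------------------------------
# origin metadata
# ---------------------------------------------------------------------------

def simulate_origin_metadata(gt: GroundTruth, design: SimulationDesign,
                             all_species: list[str] | None = None
                             ) -> list[OriginRecord]:
    """IMG-style isolation metadata: disease-enriched species are mostly of
    oral origin, depleted species mostly gut residents, the rest other."""
    rng = _stage_rng(design, 4)

    def short(lineage: str) -> str:
        return lineage.split("|")[-1].removeprefix("s__")

    records = []
    seen = set()
    for lin in gt.spiked_up:
        if rng.random() < design.p_oral_up:
            rec = OriginRecord(short(lin), "Homo sapiens", "saliva", "oral")
        else:
            rec = OriginRecord(short(lin), "Homo sapiens", "skin", "other_unknown")
        records.append(rec)
        seen.add(lin)
    for lin in gt.spiked_down:
        if rng.random() < design.p_gut_down:
            rec = OriginRecord(short(lin), "Homo sapiens", "Feces, healthy adult", "gut")
        else:
            rec = OriginRecord(short(lin), "Homo sapiens", "skin", "other_unknown")
        records.append(rec)
        seen.add(lin)
    for lin in all_species or []:
        if lin not in seen:
            records.append(OriginRecord(short(lin), "environmental sample",
                                        "soil", "other_unknown"))
    return records


# ---------------------------------------------------------------------------
# one-call cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    design: SimulationDesign
    cohort: Cohort
    species: AbundanceTable
    pathways: AbundanceTable
    kos: AbundanceTable
    kegg_map: dict[str, list[str]]
    origin_records: list[OriginRecord]
    ground_truth: GroundTruth


def simulate_cohort(design: SimulationDesign | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate the full synthetic study: metadata, species/KO/pathway tables,
    KO map, origin metadata and the ground-truth record."""
    design = design or SimulationDesign()
    if seed is not None:
        design = SimulationDesign(**{**design.to_dict(), "rng_seed": seed,
                                     "timepoints": tuple(design.timepoints)})
    cohort = generate_cohort_design(design)
    species, gt = simulate_species_profiles(design, cohort)
    pathways, kos, kegg_map = simulate_functional_profiles(species, gt, design)
    cohort = simulate_clinical_indices(cohort, species, gt, design)
    origin = simulate_origin_metadata(gt, design, all_species=species.feature_ids)
    return SyntheticCohort(design, cohort, species, pathways, kos, kegg_map,
                           origin, gt)
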