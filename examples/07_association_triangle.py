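"""Three-way association triangle: clinical indices, species, pathways.

Spearman correlations are computed block-wise on the pooled baseline
samples and BH-corrected within each block; species and pathways are
retained only if they carry a significant edge to a clinical index.
"""

from ragut import (SimulationDesign, assemble_triangle, clinical_matrix,
                   correlation_block, differential_features,
                   pathway_differential, simulate_cohort)
from ragut.triangle import DEFAULT_TRIANGLE_INDICES, triangle_records

sc = simulate_cohort(SimulationDesign(rng_seed=1))
base = sc.cohort.baseline_samples()

clin = clinical_matrix(sc.cohort, base, DEFAULT_TRIANGLE_INDICES)
species = sc.species.data[base]
pathways = sc.pathways.data[base]

cs = correlation_block(clin, species, "clinical_species")
cp = correlation_block(clin, pathways, "clinical_pathway")
sp = correlation_block(species, pathways, "species_pathway")

tri = assemble_triangle(cs, cp, sp,
                        diff_species=differential_features(sc.species, sc.cohort),
                        diff_pathways=pathway_differential(sc.pathways, sc.cohort))
print(f"retained: {len(tri.species)} species, {len(tri.pathways)} pathways, "
      f"{len(tri.clinical_indices)} clinical indices, {len(tri.edges)} edges")
recs = triangle_records(tri)
print(recs.head(8).to_string(index=False))

# Edge signs follow the planted couplings: disease-enriched species correlate
# positively with inflammation markers (ESR/CRP/RF/anti-CCP) and negatively
# with AST; node annotations carry the differential-enrichment direction.
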