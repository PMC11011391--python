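"""Mutation featurization: catalogues, signature exposures, gene-set burden.

Classifies single worked variants into the SBS96/DBS78/ID83 schemes, builds
per-sample catalogues from a simulated cohort, attributes the SBS96 catalogue
to reference signatures by non-negative least squares, and aggregates the
binary gene-mutation matrix over gene sets.
"""

import tempfile

from multisurv import formats, mutfeat
from multisurv.formats import VariantRecord
from multisurv.simulate import CohortSpec, generate_cohort

# -- single-variant classification --------------------------------------------
v = VariantRecord(sample_id="S1", chrom="chr1", pos=10, ref="T", alt="C")
print("T>C in context GTT ->", mutfeat.classify_sbs96(v, "GTT"))
w = VariantRecord(sample_id="S1", chrom="chr1", pos=10, ref="GT", alt="TC")
print("doublet GT>TC      ->", mutfeat.classify_dbs78(w), "(canonical strand)")
d = VariantRecord(sample_id="S1", chrom="chr1", pos=10, ref="AT", alt="A")
print("del of T in TTTT   ->", mutfeat.classify_id83(d, "CCCCCCA", "TTTCCCCCC"))
print()

# -- cohort-level featurization ------------------------------------------------
spec = CohortSpec(n_samples=60, n_genes=30, planted_pathway_size=10, n_gene_sets=4,
                  genes_per_set=6, n_probes=10, n_mirna=5, seed=7)
with tempfile.TemporaryDirectory() as outdir:
    paths, truth = generate_cohort(spec, outdir)
    variants = formats.read_maf(paths["maf"])
    catalogues = mutfeat.build_catalogues(variants, str(paths["reference"]))
    for name, cat in catalogues.items():
        print(f"{name}: {cat.counts.shape[1]} categories, "
              f"{int(cat.counts.values.sum())} classified variants")
    signatures = formats.read_signatures(paths["signatures"])
    exposures = mutfeat.fit_signatures(catalogues["SBS96"], signatures)
    print("mean reconstruction error (counts):",
          round(float(exposures.reconstruction_error.mean()), 2))
    gene_models = formats.read_bed_genes(paths["genes"])
    gene_sets = formats.read_gmt(paths["gene_sets"])
    gmat = mutfeat.gene_mutation_matrix(variants, gene_models)
    smat = mutfeat.geneset_aggregate(gmat, gene_sets, mode="sum")
    burden = smat.values[truth.planted_gene_set]
    print(f"{truth.planted_gene_set}: mutated in {(burden > 0).sum()} of "
          f"{len(burden)} samples (per-sample burden = mutated member genes)")
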