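"""Generate a small synthetic multiomics cohort and inspect its ground truth.

The generator emits every file the pipeline reads (reference FASTA, gene BED,
GMT gene sets, reference signatures, MAF-like variants, SEG copy-number
segments, count and beta matrices, clinical table) plus a truth object naming
the planted survival signal.
"""

import tempfile
from collections import Counter

from multisurv.simulate import CohortSpec, generate_cohort

spec = CohortSpec(n_samples=80, n_genes=40, planted_pathway_size=12, n_gene_sets=5,
                  genes_per_set=8, n_probes=30, n_mirna=10, seed=42)

with tempfile.TemporaryDirectory() as outdir:
    paths, truth = generate_cohort(spec, outdir)
    print("emitted files:")
    for key, path in paths.items():
        print(f"  {key:12s} {path.name if hasattr(path, 'name') else path}")
    print()
    counts = Counter(truth.class_labels.values())
    print(f"cohort: {counts['survivor']} survivors, {counts['nonsurvivor']} nonsurvivors")
    print(f"planted pathway ({truth.planted_gene_set}): {len(truth.planted_genes)} genes,"
          " mutated mutually exclusively with class-dependent probability")
    print(f"planted differential mRNA genes: {truth.planted_de_genes}")
    print(f"planted differential methylation probes: {truth.planted_probes}")
    print(f"planted CNV deletion region: {truth.planted_cnv_region}")
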