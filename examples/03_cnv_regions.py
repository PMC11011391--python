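"""Multi-sample CNV aggregation: shared altered regions and gene-level values.

Segments from different samples rarely coincide, so the partitioner splits the
genome at the union of all breakpoints, keeps intervals altered in >= 2
samples, and merges neighbours whose per-sample profiles agree in >= 90% of
samples.  Values are on the log2(CN/2) scale (0 = diploid).
"""

from multisurv.cnvfeat import gene_cn_matrix, partition_segments
from multisurv.formats import CnvSegment, GeneModel

segments = [
    CnvSegment("P1", "chr1", 100, 5000, -1.0),   # deletion
    CnvSegment("P2", "chr1", 2000, 8000, -1.0),  # overlapping deletion
    CnvSegment("P3", "chr1", 2000, 8000, 1.0),   # amplification, same span
    CnvSegment("P1", "chr2", 100, 900, 0.585),   # private gain: no shared support
]

partition = partition_segments(segments, frac_overlap=0.9)
print("shared altered regions (>=2 samples):")
print(partition.values.T.round(3))
print()
genes = [GeneModel("GENE_A", "chr1", 2500, 3500), GeneModel("GENE_B", "chr2", 200, 400)]
gm = gene_cn_matrix(partition, genes)
print("gene-level copy-number values (largest-overlap region wins):")
print(gm.values.round(3))
print("GENE_B overlaps no shared altered region, so every sample is neutral (0).")
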