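"""Synthetic multiomics cohort with planted, parameterized survival signal.

Generates everything the pipeline reads — a small reference genome, gene
models, gene sets, reference mutational signatures, and the five omics layers
plus a clinical table — for a cohort dichotomized into survivors and
nonsurvivors.  The planted effects mirror the structure the analysis is built
to detect:

* a mutually exclusive pathway: mutated samples carry exactly one mutation in
  a planted gene set, with a class-dependent total probability, so the signal
  is invisible gene by gene but strong after gene-set aggregation;
* negative-binomial mRNA counts with planted log2 fold changes between the
  classes; miRNA counts carry no planted signal;
* Beta-distributed methylation with planted mean shifts;
* piecewise-constant CNV segment means on the log2(CN/2) scale with one
  class-biased deleted region;
* survival times: nonsurvivors die uniformly within the 2-year horizon,
  survivors have follow-up beyond it, and a configurable fraction of extra
  early-censored cases exercises the exclusion logic.

All randomness flows from a single seed through spawned substreams, so the
same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from multisurv import formats
from multisurv.formats import (
    ClinicalRecord,
    CnvSegment,
    GeneModel,
    GeneSetCollection,
    VariantRecord,
    VitalStatus,
)
from multisurv.labels import NONSURVIVOR, SURVIVOR
from multisurv.mutfeat import sbs96_categories


class ConfigurationError(ValueError):
    pass


# log2(CN/2); homozygous deletions floored at CN=0.25 to keep the value finite
_CN_MEANS = {0: -3.0, 1: -1.0, 3: math.log2(1.5), 4: 1.0}


@dataclasses.dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults mirror the study's shape
    (267 cases, 2:1 survivor imbalance) at desk-scale feature counts."""

    n_samples: int = 267
    fraction_nonsurvivor: float = 89 / 267
    n_genes: int = 100
    n_gene_sets: int = 10
    genes_per_set: int = 10
    n_probes: int = 100
    n_mirna: int = 30
    planted_pathway_size: int = 30
    mutual_exclusivity: bool = True
    mutation_rate_background: float = 0.005
    pathway_mutation_prob_by_class: tuple[float, float] = (0.62, 0.28)  # (nonsurv, surv)
    de_gene_count: int = 6
    de_log2_fold_change: float = 1.5
    nb_dispersion: float = 0.15
    methyl_diff_probe_count: int = 6
    methyl_beta_shift: float = 0.2
    cnv_segments_per_sample: int = 6
    cnv_planted_prob_by_class: tuple[float, float] = (0.5, 0.25)
    censored_fraction: float = 0.1
    n_signatures: int = 4
    n_chromosomes: int = 4
    gene_length: int = 300
    intergenic_gap: int = 200
    chromosome_length: int | None = None  # None: auto-sized to fit the genes
    seed: int = 0

    def __post_init__(self):
        probs = [self.fraction_nonsurvivor, self.mutation_rate_background,
                 *self.pathway_mutation_prob_by_class, *self.cnv_planted_prob_by_class,
                 self.censored_fraction]
        if not all(0 <= p <= 1 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if not 0 < self.fraction_nonsurvivor < 1:
            raise ConfigurationError("fraction_nonsurvivor must be in (0, 1)")
        for name in ("n_samples", "n_genes", "n_gene_sets", "genes_per_set", "n_probes",
                     "n_mirna", "planted_pathway_size", "cnv_segments_per_sample",
                     "n_signatures", "n_chromosomes", "gene_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.planted_pathway_size > self.n_genes:
            raise ConfigurationError("planted pathway larger than the gene catalogue")
        if self.de_gene_count + self.planted_pathway_size > self.n_genes:
            raise ConfigurationError("planted features exceed generated features")
        if self.methyl_diff_probe_count > self.n_probes:
            raise ConfigurationError("planted probes exceed generated probes")

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """A cohort whose omics layers carry no class signal at all."""
        base = dict(
            pathway_mutation_prob_by_class=(0.4, 0.4),
            cnv_planted_prob_by_class=(0.3, 0.3),
            de_log2_fold_change=0.0,
            methyl_beta_shift=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class CohortTruth:
    planted_gene_set: str
    planted_genes: list[str]
    planted_de_genes: list[str]
    planted_probes: list[str]
    planted_cnv_region: tuple[str, int, int]
    planted_cnv_genes: list[str]
    class_labels: dict[str, str]  # sample -> survivor / nonsurvivor

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_cnv_region"] = list(d["planted_cnv_region"])
        Path(path).write_text(json.dumps(d, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        d["planted_cnv_region"] = tuple(d["planted_cnv_region"])
        return CohortTruth(**d)


@dataclasses.dataclass
class Fixtures:
    genome: dict[str, str]  # chrom -> sequence
    gene_models: list[GeneModel]
    gene_sets: GeneSetCollection
    signatures: pd.DataFrame  # 96 x n_signatures, columns sum to 1
    planted_set_name: str
    planted_genes: list[str]


PLANTED_SET = "PLANTED_PATHWAY"


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_fixtures(spec: CohortSpec) -> Fixtures:
    """Reference genome, gene models, gene sets and reference signatures."""
    rng = _spawn(spec.seed, 8)[0]
    per_chrom = math.ceil(spec.n_genes / spec.n_chromosomes)
    needed = per_chrom * (spec.gene_length + spec.intergenic_gap) + spec.intergenic_gap
    chrom_len = spec.chromosome_length or needed
    if chrom_len < needed:
        raise ConfigurationError(
            f"chromosome_length {chrom_len} cannot fit {per_chrom} genes "
            f"of {spec.gene_length} nt with {spec.intergenic_gap} nt gaps ({needed} nt needed)")

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    g = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        genome[chrom] = "".join(rng.choice(list("ACGT"), size=chrom_len))
        pos = spec.intergenic_gap + 1
        for _ in range(per_chrom):
            if g >= spec.n_genes:
                break
            g += 1
            models.append(GeneModel(gene=f"GENE{g:04d}", chrom=chrom,
                                    start=pos, end=pos + spec.gene_length - 1))
            pos += spec.gene_length + spec.intergenic_gap

    genes = [m.gene for m in models]
    planted = sorted(map(str, rng.choice(genes, size=spec.planted_pathway_size, replace=False)))
    sets = {PLANTED_SET: list(planted)}
    for s in range(spec.n_gene_sets - 1):
        members = rng.choice(genes, size=min(spec.genes_per_set, len(genes)), replace=False)
        sets[f"SET{s + 1:03d}"] = sorted(map(str, members))

    cats = sbs96_categories()
    sig = rng.dirichlet(np.full(len(cats), 0.1), size=spec.n_signatures).T
    signatures = pd.DataFrame(sig, index=cats,
                              columns=[f"SBS_SYN{k + 1}" for k in range(spec.n_signatures)])
    return Fixtures(genome=genome, gene_models=models, gene_sets=GeneSetCollection(sets),
                    signatures=signatures, planted_set_name=PLANTED_SET,
                    planted_genes=list(planted))


def write_fixtures(fix: Fixtures, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in fix.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    bed = outdir / "genes.bed"
    formats.write_bed_genes(fix.gene_models, bed)
    gmt = outdir / "gene_sets.gmt"
    formats.write_gmt(fix.gene_sets, gmt)
    sig = outdir / "signatures_sbs96.tsv"
    formats.write_matrix(fix.signatures, sig, index_label="category")
    return {"reference": fasta, "genes": bed, "gene_sets": gmt, "signatures": sig}


# ---------------------------------------------------------------------------
# omics layers
# ---------------------------------------------------------------------------

def _random_snv(rng, genome, chrom, pos, sample, gene, classification) -> VariantRecord:
    ref = genome[chrom][pos - 1]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return VariantRecord(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                         gene=gene, effect=formats.effect_from_classification(classification),
                         variant_classification=classification)


def _mutations(spec: CohortSpec, fix: Fixtures, samples, is_nonsurv, rng
               ) -> list[VariantRecord]:
    variants: list[VariantRecord] = []
    genes = fix.gene_models
    planted_idx = [i for i, m in enumerate(genes) if m.gene in set(fix.planted_genes)]
    background_idx = [i for i in range(len(genes)) if i not in set(planted_idx)]
    p_ns, p_s = spec.pathway_mutation_prob_by_class
    k = len(planted_idx)
    for sample, ns in zip(samples, is_nonsurv):
        # background: class-independent Bernoulli per non-pathway gene (pathway
        # genes receive only the planted, mutually exclusive events)
        for i in np.array(background_idx)[rng.random(len(background_idx))
                                          < spec.mutation_rate_background]:
            m = genes[i]
            pos = int(rng.integers(m.start, m.end + 1))
            cls = "Missense_Mutation" if rng.random() < 0.75 else "Silent"
            variants.append(_random_snv(rng, fix.genome, m.chrom, pos, sample, m.gene, cls))
        # planted pathway, mutually exclusive by default
        p = p_ns if ns else p_s
        if spec.mutual_exclusivity:
            if rng.random() < p:
                m = genes[planted_idx[int(rng.integers(k))]]
                pos = int(rng.integers(m.start, m.end + 1))
                variants.append(_random_snv(rng, fix.genome, m.chrom, pos, sample,
                                            m.gene, "Missense_Mutation"))
        else:
            for i in planted_idx:
                if rng.random() < p / k:
                    m = genes[i]
                    pos = int(rng.integers(m.start, m.end + 1))
                    variants.append(_random_snv(rng, fix.genome, m.chrom, pos, sample,
                                                m.gene, "Missense_Mutation"))
        # class-independent indels and doublets to exercise the ID/DBS catalogues
        chroms = list(fix.genome)
        for _ in range(rng.poisson(1.5)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = fix.genome[chrom]
            pos = int(rng.integers(50, len(seq) - 50))
            anchor = seq[pos - 1]
            length = int(rng.integers(1, 5))
            if rng.random() < 0.5:  # deletion of the next `length` bases
                ref = seq[pos - 1:pos - 1 + 1 + length]
                alt = anchor
            else:  # insertion after the anchor
                ref = anchor
                alt = anchor + "".join(rng.choice(list("ACGT"), size=length))
            variants.append(VariantRecord(sample_id=sample, chrom=chrom, pos=pos,
                                          ref=ref, alt=alt))
        for _ in range(rng.poisson(0.8)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = fix.genome[chrom]
            pos = int(rng.integers(50, len(seq) - 50))
            ref = seq[pos - 1:pos + 1]
            alt = "".join(rng.choice([b for b in "ACGT" if b != r]) for r in ref)
            variants.append(VariantRecord(sample_id=sample, chrom=chrom, pos=pos,
                                          ref=ref, alt=alt))
    return variants


def _cnv(spec: CohortSpec, fix: Fixtures, samples, is_nonsurv, rng,
         planted_region, chrom_len) -> list[CnvSegment]:
    segments: list[CnvSegment] = []
    chroms = list(fix.genome)
    cn_choices, cn_probs = np.array([0, 1, 3, 4]), np.array([0.05, 0.4, 0.4, 0.15])
    p_ns, p_s = spec.cnv_planted_prob_by_class
    for sample, ns in zip(samples, is_nonsurv):
        for _ in range(spec.cnv_segments_per_sample):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(500, 3000))
            start = int(rng.integers(1, max(2, chrom_len - length)))
            cn = int(rng.choice(cn_choices, p=cn_probs))
            segments.append(CnvSegment(sample_id=sample, chrom=chrom, start=start,
                                       end=start + length - 1,
                                       segment_mean=_CN_MEANS[cn]))
        if rng.random() < (p_ns if ns else p_s):
            chrom, start, end = planted_region
            segments.append(CnvSegment(sample_id=sample, chrom=chrom, start=start,
                                       end=end, segment_mean=_CN_MEANS[1]))
    return segments


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + mu^2 * dispersion (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _counts(rng, feature_ids, samples, is_nonsurv, de_features, lfc, dispersion,
            base_log_mean=np.log(300), base_log_sd=1.0) -> pd.DataFrame:
    means = np.exp(rng.normal(base_log_mean, base_log_sd, size=len(feature_ids)))
    means = np.maximum(means, 5.0)
    de_mask = np.isin(feature_ids, de_features)
    out = np.empty((len(feature_ids), len(samples)), dtype=int)
    for j, ns in enumerate(is_nonsurv):
        mu = means.copy()
        if ns and lfc != 0:
            mu[de_mask] *= 2.0 ** lfc
        out[:, j] = _nb_draw(rng, mu, dispersion)
    return pd.DataFrame(out, index=feature_ids, columns=samples)


def _methylation(spec, rng, probe_ids, samples, is_nonsurv, planted) -> pd.DataFrame:
    base = rng.uniform(0.15, 0.85, size=len(probe_ids))
    conc = 30.0
    planted_mask = np.isin(probe_ids, planted)
    shift = np.where(base < 0.5, spec.methyl_beta_shift, -spec.methyl_beta_shift)
    out = np.empty((len(probe_ids), len(samples)))
    for j, ns in enumerate(is_nonsurv):
        m = base.copy()
        if ns:
            m[planted_mask] = np.clip(m[planted_mask] + shift[planted_mask], 0.02, 0.98)
        out[:, j] = rng.beta(m * conc, (1 - m) * conc)
    return pd.DataFrame(out, index=probe_ids, columns=samples)


def _clinical(spec, rng, samples, is_nonsurv, censored_ids, horizon=730
              ) -> list[ClinicalRecord]:
    records = []
    for sample, ns in zip(samples, is_nonsurv):
        if ns:
            records.append(ClinicalRecord(sample, int(rng.integers(30, horizon)),
                                          VitalStatus.DEAD, True))
        elif rng.random() < 0.3:  # survivor who died later
            records.append(ClinicalRecord(sample, int(rng.integers(horizon, 2500)),
                                          VitalStatus.DEAD, rng.random() < 0.8))
        else:
            records.append(ClinicalRecord(sample, int(rng.integers(horizon, 2500)),
                                          VitalStatus.ALIVE, None))
    for sample in censored_ids:
        records.append(ClinicalRecord(sample, int(rng.integers(30, horizon)),
                                      VitalStatus.ALIVE, None))
    return records


def generate_cohort(spec: CohortSpec, outdir: str | Path,
                    fixtures: Fixtures | None = None
                    ) -> tuple[dict[str, Path], CohortTruth]:
    """Generate the full file bundle; returns (paths, ground truth).

    Emits exactly the formats :mod:`multisurv.formats` reads, plus
    ``truth.json`` and a ``manifest.json`` listing every path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fix = fixtures or generate_fixtures(spec)
    paths = write_fixtures(fix, outdir)

    rngs = _spawn(spec.seed, 8)
    rng_lab, rng_mut, rng_cnv, rng_mrna, rng_mirna, rng_meth, rng_clin = rngs[1:]

    n_ns = round(spec.fraction_nonsurvivor * spec.n_samples)
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    is_nonsurv = np.zeros(spec.n_samples, dtype=bool)
    is_nonsurv[rng_lab.choice(spec.n_samples, size=n_ns, replace=False)] = True
    n_cens = round(spec.censored_fraction * spec.n_samples)
    censored_ids = [f"C{i + 1:04d}" for i in range(n_cens)]
    all_samples = samples + censored_ids
    all_ns = np.concatenate([is_nonsurv, np.zeros(n_cens, dtype=bool)])

    genes = [m.gene for m in fix.gene_models]
    non_pathway = [g for g in genes if g not in set(fix.planted_genes)]
    de_genes = sorted(map(str, rng_mrna.choice(non_pathway, size=spec.de_gene_count,
                                           replace=False)))
    probes = [f"cg{i + 1:07d}" for i in range(spec.n_probes)]
    planted_probes = sorted(map(str, rng_meth.choice(
        probes, size=spec.methyl_diff_probe_count, replace=False)))
    mirnas = [f"MIR{i + 1:04d}" for i in range(spec.n_mirna)]

    # planted CNV region: a run of three consecutive non-pathway, non-DE genes
    chrom_len = len(next(iter(fix.genome.values())))
    cand = [m for m in fix.gene_models
            if m.gene not in set(fix.planted_genes) and m.gene not in set(de_genes)]
    anchor = cand[int(rng_cnv.integers(max(1, len(cand) - 2)))]
    region_genes = [m for m in fix.gene_models
                    if m.chrom == anchor.chrom and anchor.start <= m.start
                    <= anchor.start + 3 * (spec.gene_length + spec.intergenic_gap)][:3]
    planted_region = (anchor.chrom, region_genes[0].start, region_genes[-1].end)

    variants = _mutations(spec, fix, all_samples, all_ns, rng_mut)
    segments = _cnv(spec, fix, all_samples, all_ns, rng_cnv, planted_region, chrom_len)
    mrna = _counts(rng_mrna, np.array(genes), all_samples, all_ns, de_genes,
                   spec.de_log2_fold_change, spec.nb_dispersion)
    mirna = _counts(rng_mirna, np.array(mirnas), all_samples, all_ns, [], 0.0,
                    spec.nb_dispersion)
    meth = _methylation(spec, rng_meth, np.array(probes), all_samples, all_ns,
                        planted_probes)
    clinical = _clinical(spec, rng_clin, samples, is_nonsurv, censored_ids)

    paths["maf"] = outdir / "somatic.maf.tsv"
    formats.write_maf(variants, paths["maf"])
    paths["seg"] = outdir / "cnv.seg.tsv"
    formats.write_seg(segments, paths["seg"])
    paths["mrna"] = outdir / "mrna_counts.tsv"
    formats.write_matrix(mrna, paths["mrna"], index_label="gene")
    paths["mirna"] = outdir / "mirna_counts.tsv"
    formats.write_matrix(mirna, paths["mirna"], index_label="mirna")
    paths["methylation"] = outdir / "methylation_beta.tsv"
    formats.write_matrix(meth, paths["methylation"], index_label="probe")
    paths["clinical"] = outdir / "clinical.tsv"
    formats.write_clinical(clinical, paths["clinical"])

    truth = CohortTruth(
        planted_gene_set=fix.planted_set_name,
        planted_genes=list(fix.planted_genes),
        planted_de_genes=list(de_genes),
        planted_probes=list(planted_probes),
        planted_cnv_region=planted_region,
        planted_cnv_genes=[m.gene for m in region_genes],
        class_labels={s: (NONSURVIVOR if ns else SURVIVOR)
                      for s, ns in zip(samples, is_nonsurv)},
    )
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({k: str(v) for k, v in paths.items()}, indent=1))
    paths["manifest"] = manifest
    return paths, truth


# ---------------------------------------------------------------------------
# signature-driven variant drawing (for catalogue/fitting validation)
# ---------------------------------------------------------------------------

def draw_signature_variants(
    genome: dict[str, str],
    signature: pd.Series,
    n: int,
    sample_id: str,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Draw ``n`` SNVs whose SBS96 categories follow ``signature``.

    Positions are sampled (with replacement) from pyrimidine-centered sites in
    the genome whose trinucleotide context matches the drawn category.
    """
    sites: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(1, len(seq) - 1):
            if seq[i] in "CT":
                sites.setdefault(seq[i - 1:i + 2], []).append((chrom, i + 1))
    counts = rng.multinomial(n, signature.to_numpy() / signature.sum())
    variants = []
    for cat, k in zip(signature.index, counts):
        if k == 0:
            continue
        five, ref, alt, three = cat[0], cat[2], cat[4], cat[6]
        pool = sites.get(five + ref + three)
        if not pool:
            raise ValueError(f"no genomic site with context {five}{ref}{three}")
        for _ in range(int(k)):
            chrom, pos = pool[int(rng.integers(len(pool)))]
            variants.append(VariantRecord(sample_id=sample_id, chrom=chrom, pos=pos,
                                          ref=ref, alt=alt))
    return variants
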