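"""Mutation-derived featurization.

Implements the three fixed mutation-catalogue schemes used for mutational-
signature analysis — SBS96 (single-base substitutions in trinucleotide
context, pyrimidine-reference convention), DBS78 (doublet substitutions,
canonical-strand convention) and ID83 (small indels stratified by length,
repeat context and flanking microhomology, COSMIC-style bins) — plus
non-negative least-squares attribution of catalogues to reference signatures,
the binary gene x sample mutation matrix, and gene-set aggregation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from multisurv.formats import FeatureMatrix, GeneModel, GeneSetCollection, VariantRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NOT_APPLICABLE = None  # classifier return for a variant outside the scheme


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# category schemes
# ---------------------------------------------------------------------------

def sbs96_categories() -> list[str]:
    """The 96 trinucleotide-context substitution categories, COSMIC order."""
    cats = []
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"):
        for five in "ACGT":
            for three in "ACGT":
                cats.append(f"{five}[{sub}]{three}")
    return cats


_CANONICAL_DOUBLETS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def dbs78_categories() -> list[str]:
    """The 78 canonical doublet-substitution categories.

    Both bases change; a doublet and its reverse complement are the same
    event, represented on the strand whose reference doublet is canonical
    (for palindromic references, by the lexicographically smaller alt).
    """
    cats = []
    for ref in _CANONICAL_DOUBLETS:
        palindromic = revcomp(ref) == ref
        for a1 in "ACGT":
            if a1 == ref[0]:
                continue
            for a2 in "ACGT":
                if a2 == ref[1]:
                    continue
                alt = a1 + a2
                if palindromic and revcomp(alt) < alt:
                    continue  # the reverse-complement representative is kept
                cats.append(f"{ref}>{alt}")
    return cats


def id83_categories() -> list[str]:
    """The 83 indel categories: 1-bp indels by homopolymer length, longer
    indels by repeat-unit count, deletions additionally by microhomology."""
    cats = []
    for base in ("C", "T"):
        cats += [f"1:Del:{base}:{n}" for n in range(1, 7)]  # run incl. deleted base, 6 = 6+
    for base in ("C", "T"):
        cats += [f"1:Ins:{base}:{n}" for n in range(0, 6)]  # pre-existing run, 5 = 5+
    for length in (2, 3, 4, 5):  # 5 = 5+
        cats += [f"{length}:Del:R:{n}" for n in range(1, 7)]  # units incl. deleted copy
    for length in (2, 3, 4, 5):
        cats += [f"{length}:Ins:R:{n}" for n in range(0, 6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        cats += [f"{length}:Del:M:{n}" for n in range(1, max_mh + 1)]
    return cats


SCHEMES = {"SBS96": sbs96_categories, "DBS78": dbs78_categories, "ID83": id83_categories}

_DBS78_SET = frozenset(dbs78_categories())


@dataclasses.dataclass
class MutationCatalogue:
    """Per-sample counts over one of the fixed category schemes."""

    scheme: str
    counts: pd.DataFrame  # samples x categories

    def __post_init__(self):
        expected = SCHEMES[self.scheme]()
        if list(self.counts.columns) != expected:
            raise ValueError(f"{self.scheme} catalogue must carry the full fixed "
                             f"category list ({len(expected)} categories, in order)")

    @property
    def category_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_feature_matrix(self) -> FeatureMatrix:
        values = self.counts.copy()
        values.columns = [f"{self.scheme}:{c}" for c in values.columns]
        return FeatureMatrix(values, omics="mutation", method="mut_stats")

    def to_tsv(self, path: str | Path) -> None:
        self.counts.T.to_csv(path, sep="\t", index_label="category")


@dataclasses.dataclass
class SignatureExposure:
    exposures: pd.DataFrame  # samples x signatures, non-negative
    reconstruction_error: pd.Series  # per sample, Euclidean norm

    def to_feature_matrix(self, prefix: str = "") -> FeatureMatrix:
        values = self.exposures.copy()
        if prefix:
            values.columns = [f"{prefix}:{c}" for c in values.columns]
        return FeatureMatrix(values, omics="mutation", method="signature")


# ---------------------------------------------------------------------------
# per-variant classifiers
# ---------------------------------------------------------------------------

def classify_sbs96(variant: VariantRecord, context: str) -> str | None:
    """Classify a single-base substitution given its 3-nt reference context.

    Purine-reference variants are reverse-complemented (variant and context)
    so the reference base is a pyrimidine.  Returns None for non-SNVs and for
    contexts containing non-ACGT characters.
    """
    if not variant.is_snv:
        return NOT_APPLICABLE
    context = context.upper()
    if len(context) != 3 or not set(context) <= set("ACGT"):
        return NOT_APPLICABLE
    if context[1] != variant.ref:
        raise ValueError(f"context {context!r} does not center on ref {variant.ref!r}")
    ref, alt = variant.ref, variant.alt
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def classify_dbs78(variant: VariantRecord) -> str | None:
    """Map a doublet substitution to its canonical-strand category (78 ids)."""
    if len(variant.ref) != 2 or len(variant.alt) != 2:
        return NOT_APPLICABLE
    ref, alt = variant.ref, variant.alt
    if ref[0] == alt[0] or ref[1] == alt[1]:
        return NOT_APPLICABLE  # only one base changes: an SNV written as a doublet
    for r, a in ((ref, alt), (revcomp(ref), revcomp(alt))):
        cat = f"{r}>{a}"
        if cat in _DBS78_SET:
            return cat
    raise AssertionError("unreachable: every true doublet has a canonical strand")


def _count_flank_copies(unit: str, left_flank: str, right_flank: str) -> tuple[int, int]:
    """Copies of ``unit`` tiling outward from the event on each side."""
    k = len(unit)
    right = 0
    while right_flank[right * k:(right + 1) * k] == unit:
        right += 1
    left = 0
    n = len(left_flank)
    while n >= (left + 1) * k and left_flank[n - (left + 1) * k:n - left * k] == unit:
        left += 1
    return left, right


def _microhomology_length(deleted: str, left_flank: str, right_flank: str) -> int:
    mh_right = 0
    for i in range(1, len(deleted)):
        if right_flank[:i] == deleted[:i]:
            mh_right = i
        else:
            break
    mh_left = 0
    for i in range(1, len(deleted)):
        if left_flank[-i:] == deleted[-i:]:
            mh_left = i
        else:
            break
    return max(mh_right, mh_left)


def classify_id83(variant: VariantRecord, left_flank: str, right_flank: str) -> str | None:
    """Classify an anchored indel against its reference flanks.

    ``left_flank`` is the reference immediately 5' of the deleted/inserted
    sequence (including the anchor base); ``right_flank`` is the reference
    immediately 3' of it.  Flanks shorter than 6 repeat units raise, as the
    6+/5+ bins could not be resolved.
    """
    if not variant.is_indel:
        return NOT_APPLICABLE
    ref, alt = variant.ref, variant.alt
    if ref[0] != alt[0]:
        return NOT_APPLICABLE  # not anchored; cannot orient the event
    left_flank, right_flank = left_flank.upper(), right_flank.upper()
    if len(ref) > len(alt):
        seq, kind = ref[len(alt):], "Del"
        if len(alt) > 1:
            return NOT_APPLICABLE  # complex indel
    else:
        seq, kind = alt[len(ref):], "Ins"
        if len(ref) > 1:
            return NOT_APPLICABLE
    need = 6 * len(seq)
    if len(right_flank) < need or len(left_flank) < min(need, 1):
        raise ValueError("flank too short to resolve repeat bins")

    if len(seq) == 1:
        base = seq if seq in "CT" else revcomp(seq)
        left, right = _count_flank_copies(seq, left_flank, right_flank)
        if kind == "Del":
            run = 1 + left + right  # run length including the deleted base
            return f"1:Del:{base}:{min(run, 6)}"
        run = left + right  # pre-existing homopolymer at the insertion point
        return f"1:Ins:{base}:{min(run, 5)}"

    length = min(len(seq), 5)
    left, right = _count_flank_copies(seq, left_flank, right_flank)
    units = left + right
    if kind == "Ins":
        return f"{length}:Ins:R:{min(units, 5)}"
    if units >= 1:  # deleted copy plus at least one more in the reference
        return f"{length}:Del:R:{min(1 + units, 6)}"
    mh = _microhomology_length(seq, left_flank, right_flank)
    if mh >= 1:
        max_mh = 5 if length >= 5 else length - 1
        return f"{length}:Del:M:{min(mh, max_mh)}"
    return f"{length}:Del:R:1"


# ---------------------------------------------------------------------------
# catalogue construction
# ---------------------------------------------------------------------------

def _get_reference(reference):
    if isinstance(reference, (str, Path)):
        import pyfaidx

        return pyfaidx.Fasta(str(reference))
    return reference


def build_catalogues(
    variants: Sequence[VariantRecord],
    reference,
    samples: Sequence[str] | None = None,
) -> dict[str, MutationCatalogue]:
    """Build the SBS96, DBS78 and ID83 catalogues from variants + reference FASTA.

    Each variant contributes to exactly one scheme (or to none, when it is a
    multi-nucleotide substitution longer than 2 or cannot be classified);
    unclassifiable variants are logged and skipped.  ``reference`` is a FASTA
    path or a pyfaidx.Fasta-like mapping of chrom -> indexable sequence.
    """
    ref = _get_reference(reference)
    if samples is None:
        samples = sorted({v.sample_id for v in variants})
    else:
        samples = list(samples)
    frames = {
        name: pd.DataFrame(0, index=samples, columns=fn(), dtype=int)
        for name, fn in SCHEMES.items()
    }
    skipped = 0
    for v in variants:
        if v.sample_id not in frames["SBS96"].index:
            continue
        try:
            cat, scheme = _classify_against_reference(v, ref)
        except (ValueError, KeyError, IndexError) as exc:
            logger.warning("unclassifiable variant %s:%s %s>%s (%s)",
                           v.chrom, v.pos, v.ref, v.alt, exc)
            skipped += 1
            continue
        if cat is NOT_APPLICABLE:
            skipped += 1
            continue
        frames[scheme].loc[v.sample_id, cat] += 1
    if skipped:
        logger.info("skipped %d variants outside the SBS/DBS/ID schemes", skipped)
    return {name: MutationCatalogue(scheme=name, counts=df) for name, df in frames.items()}


def _classify_against_reference(v: VariantRecord, ref) -> tuple[str | None, str]:
    chrom = ref[v.chrom]
    if v.is_snv:
        ctx = str(chrom[v.pos - 2:v.pos + 1]).upper()
        return classify_sbs96(v, ctx), "SBS96"
    if len(v.ref) == 2 and len(v.alt) == 2:
        return classify_dbs78(v), "DBS78"
    if v.is_indel:
        indel_len = abs(len(v.ref) - len(v.alt))
        window = 6 * indel_len + 6
        anchor_end = v.pos  # 1-based position of anchor base
        left = str(chrom[max(0, anchor_end - window):anchor_end]).upper()
        if len(v.ref) > len(v.alt):  # deletion: deleted seq occupies pos+1 .. pos+L
            right_start = v.pos + indel_len
        else:  # insertion between anchor and next base
            right_start = v.pos
        right = str(chrom[right_start:right_start + window]).upper()
        return classify_id83(v, left, right), "ID83"
    return NOT_APPLICABLE, "SBS96"  # longer multi-nucleotide substitution: skipped


# ---------------------------------------------------------------------------
# signature fitting
# ---------------------------------------------------------------------------

def fit_signatures(catalogue: MutationCatalogue, reference_signatures: pd.DataFrame) -> SignatureExposure:
    """Attribute each sample's catalogue to reference signatures by NNLS.

    ``reference_signatures`` is categories x signatures with columns summing
    to 1 and must use the catalogue's category ordering.  Exposures are the
    non-negative least-squares solution per sample; the reported
    reconstruction error is the Euclidean residual norm.
    """
    if list(reference_signatures.index) != catalogue.category_ids:
        raise ValueError("signature matrix categories do not match the catalogue scheme")
    S = reference_signatures.to_numpy(dtype=float)
    exposures = np.zeros((catalogue.counts.shape[0], S.shape[1]))
    errors = np.zeros(catalogue.counts.shape[0])
    for i, row in enumerate(catalogue.counts.to_numpy(dtype=float)):
        exposures[i], errors[i] = nnls(S, row)
    return SignatureExposure(
        exposures=pd.DataFrame(exposures, index=catalogue.counts.index,
                               columns=reference_signatures.columns),
        reconstruction_error=pd.Series(errors, index=catalogue.counts.index, name="rss"),
    )


# ---------------------------------------------------------------------------
# gene- and gene-set-level matrices
# ---------------------------------------------------------------------------

def gene_mutation_matrix(
    variants: Sequence[VariantRecord],
    gene_models: Sequence[GeneModel],
    protein_altering_only: bool = True,
    samples: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Binary samples x genes matrix: 1 if the gene carries a qualifying mutation.

    Gene resolution uses the variant's ``gene`` annotation when present and
    falls back to coordinate overlap with the gene models.  Variants mapping
    to no gene are counted in a discard log.
    """
    if samples is None:
        samples = sorted({v.sample_id for v in variants})
    genes = [g.gene for g in gene_models]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    values = pd.DataFrame(0.0, index=list(samples), columns=genes)
    known = set(genes)
    unmapped = 0
    for v in variants:
        if v.sample_id not in values.index:
            continue
        if protein_altering_only and v.effect.value != "protein_altering":
            continue
        gene = v.gene if v.gene in known else ""
        if not gene:
            span_end = v.pos + max(len(v.ref) - 1, 0)
            for g in by_chrom.get(v.chrom, ()):
                if g.start <= span_end and v.pos <= g.end:
                    gene = g.gene
                    break
        if not gene:
            unmapped += 1
            continue
        values.loc[v.sample_id, gene] = 1.0
    if unmapped:
        logger.info("%d variants mapped to no gene model and were discarded", unmapped)
    return FeatureMatrix(values, omics="mutation", method="gene")


def geneset_aggregate(
    matrix: FeatureMatrix,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    mode: str = "sum",
) -> FeatureMatrix:
    """Collapse per-gene features to one feature per gene set.

    ``mode="sum"`` (mutation matrices: number of altered member genes) or
    ``mode="mean"`` (CNV matrices: average signed segment mean).  Genes absent
    from the matrix are skipped and logged; sets with no resolvable gene are
    dropped with a warning.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    items = sets.items() if hasattr(sets, "items") else sets
    columns = {}
    have = set(matrix.feature_ids)
    for name, genes in items:
        present = [g for g in genes if g in have]
        missing = len(genes) - len(present)
        if missing:
            logger.debug("gene set %s: %d member genes absent from the matrix", name, missing)
        if not present:
            logger.warning("gene set %s has no resolvable genes; dropped", name)
            continue
        block = matrix.values[present]
        columns[name] = block.sum(axis=1) if mode == "sum" else block.mean(axis=1)
    values = pd.DataFrame(columns, index=matrix.values.index)
    omics = matrix.provenance["omics"].iloc[0] if len(matrix.provenance) else "mutation"
    return FeatureMatrix(values, omics=omics, method="gene_set")
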