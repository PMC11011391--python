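"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions
-----------
* Coordinates are 1-based and inclusive everywhere inside the package, matching
  MAF and SEG files.  BED input (0-based, half-open) is converted on read.
* Indels are represented VCF-style with an anchor base, so ``ref`` and ``alt``
  are always non-empty ACGT strings (a MAF-like file using this convention is
  what :mod:`multisurv.simulate` emits; true MAF ``-`` alleles are normalized on
  read when an anchor can be recovered is *not* attempted — such rows error).
* Missing values in matrices are NaN and are propagated, never silently imputed.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_DNA = frozenset("ACGT")

#: MAF Variant_Classification values mapped to the ``protein_altering`` effect.
PROTEIN_ALTERING_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

SYNONYMOUS_CLASSES = frozenset({"Silent", "Synonymous"})


class FormatError(ValueError):
    """Malformed input file; carries the 1-based line number when row-level."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Effect(str, enum.Enum):
    PROTEIN_ALTERING = "protein_altering"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DEAD = "dead"


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One somatic alteration event in one sample (SNV, DBS or anchored indel)."""

    sample_id: str
    chrom: str
    pos: int  # 1-based position of the first ref base
    ref: str
    alt: str
    gene: str = ""
    effect: Effect = Effect.OTHER
    variant_classification: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _DNA.issuperset(allele):
                raise ValueError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref})")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_dbs(self) -> bool:
        return (
            len(self.ref) == 2
            and len(self.alt) == 2
            and self.ref[0] != self.alt[0]
            and self.ref[1] != self.alt[1]
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclasses.dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment with its mean on the log2(CN/2) scale (0 = diploid)."""

    sample_id: str
    chrom: str
    start: int
    end: int  # inclusive
    segment_mean: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if not np.isfinite(self.segment_mean):
            raise ValueError("segment_mean must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int  # inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


@dataclasses.dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    days_to_last_contact_or_death: int
    vital_status: VitalStatus
    cause_of_death_cancer: bool | None = None

    def __post_init__(self):
        if self.days_to_last_contact_or_death < 0:
            raise ValueError("days must be non-negative")


class GeneSetCollection:
    """Ordered mapping of gene-set name -> member gene symbols (GMT semantics)."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        cleaned: dict[str, list[str]] = {}
        for name, genes in sets.items():
            members = list(dict.fromkeys(genes))  # dedupe, keep order
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = members
        self._sets = cleaned

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def items(self):
        return self._sets.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets


class FeatureMatrix:
    """Samples x features numeric matrix with per-feature provenance.

    Wraps a :class:`pandas.DataFrame` (index = sample ids, columns = feature
    ids) plus a provenance frame (index = feature ids, columns ``omics`` and
    ``method``).  Missing values are NaN.
    """

    OMICS = ("mutation", "cnv", "mrna", "mirna", "methylation")
    METHODS = ("region_overlap", "gene", "gene_set", "mut_stats", "signature", "pca", "raw")

    def __init__(self, values: pd.DataFrame, omics: str | pd.Series, method: str | pd.Series):
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        self.values = values.astype(float)
        prov = pd.DataFrame(index=values.columns)
        prov["omics"] = omics
        prov["method"] = method
        bad_omics = set(prov["omics"]) - set(self.OMICS)
        bad_method = set(prov["method"]) - set(self.METHODS)
        if bad_omics or bad_method:
            raise ValueError(f"unknown provenance values: {bad_omics | bad_method}")
        self.provenance = prov

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        features = list(features)
        out = FeatureMatrix.__new__(FeatureMatrix)
        out.values = self.values[features]
        out.provenance = self.provenance.loc[features]
        return out

    @staticmethod
    def concat(matrices: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        """Column-wise combination on the intersection of samples, in order."""
        if not matrices:
            raise ValueError("nothing to concatenate")
        samples = matrices[0].values.index
        for m in matrices[1:]:
            samples = samples.intersection(m.values.index)
        values = pd.concat([m.values.loc[samples] for m in matrices], axis=1)
        out = FeatureMatrix.__new__(FeatureMatrix)
        if values.columns.duplicated().any():
            raise ValueError("duplicate feature ids across matrices")
        out.values = values
        out.provenance = pd.concat([m.provenance for m in matrices], axis=0)
        return out

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write features x samples TSV (first column = feature id) + provenance."""
        self.values.T.to_csv(path, sep="\t", index_label="feature_id")
        if sidecar is not None:
            self.provenance.to_csv(sidecar, sep="\t", index_label="feature_id")

    @staticmethod
    def from_tsv(path: str | Path, sidecar: str | Path | None = None,
                 omics: str = "mrna", method: str = "raw") -> "FeatureMatrix":
        values = read_matrix(path).T
        values.index.name = None
        values.columns.name = None
        if sidecar is not None:
            prov = pd.read_csv(sidecar, sep="\t", index_col="feature_id")
            return FeatureMatrix(values, prov["omics"], prov["method"])
        return FeatureMatrix(values, omics, method)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MAF_COLUMNS = {
    "sample": ("Tumor_Sample_Barcode", "sample", "sample_id"),
    "chrom": ("Chromosome", "chrom", "chromosome"),
    "pos": ("Start_Position", "pos", "position", "Start_position"),
    "ref": ("Reference_Allele", "ref"),
    "alt": ("Tumor_Seq_Allele2", "alt"),
    "gene": ("Hugo_Symbol", "gene"),
    "classification": ("Variant_Classification", "variant_classification"),
}


def _resolve_columns(header: Sequence[str], spec: Mapping[str, tuple],
                     mandatory: Iterable[str]) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    found = {}
    for key, names in spec.items():
        for name in names:
            if name.lower() in lower:
                found[key] = lower[name.lower()]
                break
    missing = [k for k in mandatory if k not in found]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    return found


def effect_from_classification(classification: str) -> Effect:
    if classification in PROTEIN_ALTERING_CLASSES:
        return Effect.PROTEIN_ALTERING
    if classification in SYNONYMOUS_CLASSES:
        return Effect.SYNONYMOUS
    return Effect.OTHER


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a MAF-like tab-separated variant file.

    Requires sample / chromosome / position / ref / alt columns (MAF or plain
    names).  ``effect`` is inferred from a Variant_Classification column when
    present, otherwise ``other``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(df.columns, _MAF_COLUMNS, ("sample", "chrom", "pos", "ref", "alt"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        d = {k: row[v] for k, v in cols.items()}
        classification = str(d.get("classification", "") or "")
        if classification in ("nan", "None"):
            classification = ""
        gene = str(d.get("gene", "") or "")
        if gene in ("nan", "None"):
            gene = ""
        try:
            records.append(
                VariantRecord(
                    sample_id=str(d["sample"]),
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]),
                    ref=str(d["ref"]).upper(),
                    alt=str(d["alt"]).upper(),
                    gene=gene,
                    effect=effect_from_classification(classification),
                    variant_classification=classification,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(str(exc), line=i) from exc
    return records


def write_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "Tumor_Sample_Barcode": r.sample_id,
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref,
            "Tumor_Seq_Allele2": r.alt,
            "Variant_Classification": r.variant_classification,
        }
        for r in records
    ]
    cols = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
            "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_SEG_COLUMNS = {
    "sample": ("ID", "sample", "sample_id", "Sample"),
    "chrom": ("chrom", "chromosome", "Chromosome"),
    "start": ("loc.start", "start", "Start"),
    "end": ("loc.end", "end", "End"),
    "segment_mean": ("seg.mean", "segment_mean", "Segment_Mean"),
}


def read_seg(path: str | Path) -> list[CnvSegment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, _SEG_COLUMNS,
                            ("sample", "chrom", "start", "end", "segment_mean"))
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        d = {k: row[v] for k, v in cols.items()}
        try:
            segments.append(
                CnvSegment(
                    sample_id=str(d["sample"]),
                    chrom=str(d["chrom"]),
                    start=int(d["start"]),
                    end=int(d["end"]),
                    segment_mean=float(d["segment_mean"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(str(exc), line=i) from exc
    return segments


def write_seg(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = [
        {"ID": s.sample_id, "chrom": s.chrom, "loc.start": s.start,
         "loc.end": s.end, "seg.mean": s.segment_mean}
        for s in segments
    ]
    pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end", "seg.mean"]).to_csv(
        path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set name, description (discarded), then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("GMT line needs set name, description and >=1 gene", line=i)
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}", line=i)
            sets[name] = fields[2:]
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive)."""
    models = []
    seen = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError("BED gene line needs chrom, start, end, name", line=i)
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(str(exc), line=i) from exc
            if start0 >= end0:
                raise FormatError(f"empty/negative interval {start0}-{end0}", line=i)
            gene = fields[3]
            if gene in seen:
                raise FormatError(f"duplicate gene {gene!r}", line=i)
            seen.add(gene)
            models.append(GeneModel(gene=gene, chrom=fields[0], start=start0 + 1, end=end0))
    return models


def write_bed_genes(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.gene}\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column = feature id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate feature ids in matrix")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "days_to_last_contact_or_death", "vital_status"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        cause = row.get("cause_of_death_cancer")
        if cause is None or pd.isna(cause) or str(cause) == "":
            cause_val = None
        else:
            cause_val = str(cause).lower() in ("true", "1", "yes")
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row["sample_id"]),
                    days_to_last_contact_or_death=int(row["days_to_last_contact_or_death"]),
                    vital_status=VitalStatus(str(row["vital_status"]).lower()),
                    cause_of_death_cancer=cause_val,
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(str(exc), line=i) from exc
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "days_to_last_contact_or_death": r.days_to_last_contact_or_death,
            "vital_status": r.vital_status.value,
            "cause_of_death_cancer": "" if r.cause_of_death_cancer is None
            else str(r.cause_of_death_cancer).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_signatures(path: str | Path) -> pd.DataFrame:
    """Read a reference-signature matrix (categories x signatures TSV)."""
    df = read_matrix(path)
    if (df.values < 0).any():
        raise FormatError("signature matrix has negative entries")
    return df
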