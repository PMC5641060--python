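"""Domain types and readers/writers for every external format in the pipeline.

Internal coordinate convention is 0-based half-open throughout; BED is read
as-is, GTF (1-based inclusive) is converted at the I/O boundary and converted
back on write.  Missing matrix cells are ``NaN``, never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lncscna")

TUMOR = "tumor"
NORMAL = "normal"


class Biotype(str, Enum):
    LNCRNA = "lncRNA"
    PCG = "PCG"
    TF = "TF"
    MIRNA = "miRNA"


#: default mapping from annotation biotype tokens to the internal vocabulary
#: (GENCODE-style names plus the internal names themselves)
DEFAULT_BIOTYPE_MAP: dict[str, Biotype] = {
    "lncRNA": Biotype.LNCRNA,
    "lincRNA": Biotype.LNCRNA,
    "antisense": Biotype.LNCRNA,
    "processed_transcript": Biotype.LNCRNA,
    "protein_coding": Biotype.PCG,
    "PCG": Biotype.PCG,
    "TF": Biotype.TF,
    "miRNA": Biotype.MIRNA,
}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


class ValidationError(ValueError):
    """Input violates a structural invariant (e.g. beta value outside [0,1])."""


@dataclass(frozen=True)
class GeneRecord:
    """Genomic locus of one feature, 0-based half-open coordinates."""

    gene_id: str
    symbol: str
    biotype: Biotype
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end on - strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class FocalFragment:
    """Recurrently gained or lost genomic region (GISTIC-style focal call)."""

    fragment_id: str
    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.fragment_id}: start must be < end")
        if self.direction not in ("gain", "loss"):
            raise ValidationError(f"{self.fragment_id}: direction must be gain/loss")


MATRIX_ROLES = ("expression", "copy_number", "discrete_cn", "beta")


@dataclass
class OmicsMatrix:
    """Gene x sample numeric matrix with per-sample class labels.

    ``values`` is a float DataFrame (rows = genes, columns = samples) with
    ``NaN`` marking missing cells.  ``sample_class`` maps every column to
    ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    sample_class: pd.Series
    role: str

    def __post_init__(self) -> None:
        if self.role not in MATRIX_ROLES:
            raise ValidationError(f"unknown matrix role {self.role!r}")
        self.values = self.values.astype(float)
        self.sample_class = self.sample_class.reindex(self.values.columns)
        if self.sample_class.isna().any():
            missing = list(self.sample_class.index[self.sample_class.isna()])
            raise ValidationError(f"samples without class label: {missing[:5]}")
        bad = ~self.sample_class.isin([TUMOR, NORMAL])
        if bad.any():
            raise ValidationError("sample_class values must be tumor/normal")
        vals = self.values.to_numpy()
        finite = vals[np.isfinite(vals)]
        if self.role == "beta" and finite.size and (
            finite.min() < 0.0 or finite.max() > 1.0
        ):
            raise ValidationError("beta values must lie in [0, 1]")
        if self.role == "discrete_cn" and finite.size and not np.isin(
            finite, [-2.0, -1.0, 0.0, 1.0, 2.0]
        ).all():
            raise ValidationError("discrete CN values must be in {-2,-1,0,1,2}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, klass: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == klass])

    def subset_genes(self, genes: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(genes)], self.sample_class, self.role)

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values[list(samples)], self.sample_class[list(samples)], self.role
        )


INTERACTION_KINDS = ("miRNA-lncRNA", "miRNA-mRNA", "TF-gene", "drug-miRNA")


@dataclass
class InteractionTable:
    """De-duplicated (source, target) pairs of one interaction kind."""

    pairs: pd.DataFrame  # columns: source_id, target_id, kind, [effect]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValidationError(f"unknown interaction kind {self.kind!r}")
        cols = ["source_id", "target_id", "kind"]
        if "effect" in self.pairs.columns:
            cols.append("effect")
        self.pairs = (
            self.pairs[cols]
            .drop_duplicates(subset=["source_id", "target_id", "kind"])
            .reset_index(drop=True)
        )
        if (self.pairs["kind"] != self.kind).any():
            raise ValidationError("mixed interaction kinds in one table")

    def targets_of(self, source_id: str) -> set[str]:
        sel = self.pairs["source_id"] == source_id
        return set(self.pairs.loc[sel, "target_id"])

    def sources_of(self, target_id: str) -> set[str]:
        sel = self.pairs["target_id"] == target_id
        return set(self.pairs.loc[sel, "source_id"])


@dataclass
class ClinicalTable:
    """Per-sample follow-up time (days) and death indicator."""

    data: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"clinical table needs columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)
        if (self.data["time"] <= 0).any():
            raise ValidationError("survival times must be > 0")
        self.data["event"] = self.data["event"].astype(int)
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0/1")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    dialect: str = "BED",
    biotype_map: Mapping[str, Biotype] | None = None,
) -> list[GeneRecord]:
    """Read gene annotation in BED6(+biotype column) or GENCODE-style GTF.

    BED coordinates are already 0-based half-open; GTF start is shifted by
    -1 on read.  Records whose biotype token is absent from *biotype_map*
    are skipped (a single warning reports the count).
    """
    biotype_map = dict(DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map)
    records: list[GeneRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "BED":
                    if len(fields) < 6:
                        raise ValueError("expected >= 6 tab-separated fields")
                    chrom, start, end, name, _score, strand = fields[:6]
                    token = fields[6] if len(fields) > 6 else ""
                    symbol = name
                    start_i, end_i = int(start), int(end)
                elif dialect == "GTF":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    chrom, _src, feature, start, end, _score, strand = fields[:7]
                    if feature != "gene":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    name = attrs.get("gene_id", "")
                    if not name:
                        raise ValueError("missing gene_id attribute")
                    symbol = attrs.get("gene_name", name)
                    token = attrs.get("gene_type", "")
                    start_i, end_i = int(start) - 1, int(end)
                else:
                    raise ValidationError(f"unknown annotation dialect {dialect!r}")
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if token not in biotype_map:
                skipped += 1
                continue
            records.append(
                GeneRecord(
                    gene_id=name,
                    symbol=symbol,
                    biotype=biotype_map[token],
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                )
            )
    if skipped:
        logger.warning("%s: skipped %d records with unknown biotype", path, skipped)
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate gene_id in annotation")
    return records


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_annotation(
    records: Iterable[GeneRecord], path: str | Path, dialect: str = "BED"
) -> None:
    """Write annotation; inverse of :func:`read_annotation` for both dialects."""
    with open(path, "w") as fh:
        for r in records:
            if dialect == "BED":
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}"
                    f"\t{r.biotype.value}\n"
                )
            elif dialect == "GTF":
                attrs = (
                    f'gene_id "{r.gene_id}"; gene_name "{r.symbol}"; '
                    f'gene_type "{r.biotype.value}";'
                )
                fh.write(
                    f"{r.chrom}\tlncscna\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )
            else:
                raise ValidationError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path, role: str, class_map: Mapping[str, str]
) -> OmicsMatrix:
    """Read a genes x samples TSV; empty cells become NaN (missing), not 0."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    classes = pd.Series({s: class_map[s] for s in df.columns})
    return OmicsMatrix(values=df, sample_class=classes, role=role)


def write_matrix(m: OmicsMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# table I/O (interactions, clinical, fragments, generic edges)
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path, kind: str) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "kind" not in df.columns:
        df["kind"] = kind
    return InteractionTable(pairs=df, kind=kind)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> list[FocalFragment]:
    df = pd.read_csv(path, sep="\t")
    return [
        FocalFragment(
            fragment_id=str(r.fragment_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_fragments(fragments: Iterable[FocalFragment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                "direction": f.direction,
            }
            for f in fragments
        ],
        columns=["fragment_id", "chrom", "start", "end", "direction"],
    ).to_csv(path, sep="\t", index=False)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a typed edge list as TSV; an empty frame yields a header-only file."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
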