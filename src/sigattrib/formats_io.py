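"""Readers/writers for MAF, FASTA, signature catalogs, and matrices.

All downstream modules consume the domain types defined here:
:class:`MutationRecord`, :class:`SignatureCatalog` and
:class:`ReferenceSequence`. File dialects follow common practice: MAF is
tab-separated with the standard column names (Hugo_Symbol, Chromosome,
Start_Position, Reference_Allele, Tumor_Seq_Allele2,
Variant_Classification, Variant_Type, Tumor_Sample_Barcode), coordinates
are 1-based inclusive, insertions carry the position of the base before
the inserted sequence and deletions the first deleted base. Catalog
tables are tab-separated with the channel label in the first column and
one column per signature (COSMIC download layout), dot decimal
separator, UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .channels import SCHEME_CHANNELS, Scheme
from .errors import MafFormatError, SchemeMismatchError, ValidationError

# Classification values participating in the amino-acid-altering subset
# and recognised by the per-gene summary tables.
KNOWN_CLASSIFICATIONS = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Silent",
    "Splice_Site",
    "Translation_Start_Site",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
)

VARIANT_TYPES = ("SNP", "DNP", "INS", "DEL")

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    Coordinates are 1-based inclusive. ``reference_allele`` is ``"-"``
    for insertions and ``alternate_allele`` is ``"-"`` for deletions.
    Unknown ``variant_classification`` strings are preserved verbatim
    (they are simply never part of the amino-acid subset).
    """

    gene_symbol: str
    chromosome: str
    start_position: int
    reference_allele: str
    alternate_allele: str
    variant_classification: str
    variant_type: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.start_position < 1:
            raise ValidationError(
                f"start_position must be >= 1, got {self.start_position}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(
                f"unknown variant_type {self.variant_type!r}"
            )
        ref, alt = self.reference_allele, self.alternate_allele
        if self.variant_type == "SNP":
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise ValidationError(
                    f"SNP requires two distinct single bases, got {ref}>{alt}"
                )
        elif self.variant_type == "DNP":
            if len(ref) != 2 or len(alt) != 2 or ref == alt:
                raise ValidationError(
                    f"DNP requires two distinct doublets, got {ref}>{alt}"
                )
        elif self.variant_type == "INS":
            if ref != "-" or not alt or alt == "-":
                raise ValidationError(
                    f"INS requires reference_allele '-', got {ref}>{alt}"
                )
        elif self.variant_type == "DEL":
            if alt != "-" or not ref or ref == "-":
                raise ValidationError(
                    f"DEL requires alternate_allele '-', got {ref}>{alt}"
                )


@dataclass
class ReferenceSequence:
    """In-memory reference genome: contig name -> uppercase sequence."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )
            self.contigs[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(contigs)

    def base(self, contig: str, position: int) -> str:
        """Single base at a 1-based position."""
        return self.window(contig, position, position)

    def window(self, contig: str, start: int, end: int) -> str:
        """Sequence on [start, end], 1-based inclusive."""
        if contig not in self.contigs:
            raise ValidationError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise ValidationError(
                f"window [{start},{end}] outside contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])


def write_fasta(reference: ReferenceSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in reference.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SignatureCatalog:
    """Named set of signatures, each a probability vector over channels.

    ``matrix`` is signatures x channels; each row sums to 1 (within 1e-6).
    """

    scheme: Scheme
    channel_labels: List[str]
    signature_ids: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = SCHEME_CHANNELS[self.scheme]
        if list(self.channel_labels) != list(expected):
            if set(self.channel_labels) != set(expected):
                raise SchemeMismatchError(
                    f"channel labels do not match scheme {self.scheme.value}"
                )
            order = [list(self.channel_labels).index(c) for c in expected]
            self.matrix = self.matrix[:, order]
            self.channel_labels = list(expected)
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValidationError("signature ids are not unique")
        if self.matrix.shape != (len(self.signature_ids), len(self.channel_labels)):
            raise ValidationError("catalog matrix shape mismatch")
        if np.any(self.matrix < 0):
            raise ValidationError("catalog contains negative entries")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("catalog rows must each sum to 1")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)

    def channels_by_signatures(self) -> np.ndarray:
        """Channels x signatures orientation (for least-squares refits)."""
        return self.matrix.T

    def signature(self, signature_id: str) -> np.ndarray:
        return self.matrix[self.signature_ids.index(signature_id)]


def read_catalog(path: str | Path, scheme: Scheme) -> SignatureCatalog:
    """Read a channel-by-signature TSV into a :class:`SignatureCatalog`.

    Channel order is normalised to the canonical scheme order. Columns
    whose sums deviate from 1 by at most 1e-3 are renormalised; larger
    deviations raise a validation error.
    """
    scheme = Scheme(scheme)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    expected = SCHEME_CHANNELS[scheme]
    if df.shape[0] != len(expected):
        raise SchemeMismatchError(
            f"{path}: {df.shape[0]} channels, scheme {scheme.value} "
            f"requires {len(expected)}"
        )
    labels = [str(x) for x in df.index]
    if set(labels) != set(expected):
        raise SchemeMismatchError(
            f"{path}: channel labels do not match scheme {scheme.value}"
        )
    df = df.loc[expected]
    mat = df.to_numpy(dtype=float).T  # signatures x channels
    if np.any(mat < 0):
        raise ValidationError(f"{path}: negative catalog entries")
    sums = mat.sum(axis=1)
    if np.any(sums <= 0) or np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValidationError(
            f"{path}: signature columns must sum to 1 within 1e-3"
        )
    mat = mat / sums[:, None]
    return SignatureCatalog(
        scheme=scheme,
        channel_labels=list(expected),
        signature_ids=[str(c) for c in df.columns],
        matrix=mat,
    )


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(
        catalog.matrix.T,
        index=pd.Index(catalog.channel_labels, name="Channel"),
        columns=catalog.signature_ids,
    )
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_maf(path: str | Path) -> List[MutationRecord]:
    """Read a MAF file into a list of :class:`MutationRecord`.

    Comment lines starting with ``#`` (e.g. ``#version``) are skipped;
    body row order is preserved. A missing mandatory column raises
    :class:`MafFormatError` naming the column.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"{path}: missing mandatory MAF column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                gene_symbol=getattr(row, "Hugo_Symbol"),
                chromosome=getattr(row, "Chromosome"),
                start_position=int(getattr(row, "Start_Position")),
                reference_allele=getattr(row, "Reference_Allele"),
                alternate_allele=getattr(row, "Tumor_Seq_Allele2"),
                variant_classification=getattr(row, "Variant_Classification"),
                variant_type=getattr(row, "Variant_Type"),
                sample_id=getattr(row, "Tumor_Sample_Barcode"),
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records to a MAF file re-readable by :func:`read_maf`."""
    rows = [
        {
            "Hugo_Symbol": r.gene_symbol,
            "Chromosome": r.chromosome,
            "Start_Position": r.start_position,
            "Reference_Allele": r.reference_allele,
            "Tumor_Seq_Allele2": r.alternate_allele,
            "Variant_Classification": r.variant_classification,
            "Variant_Type": r.variant_type,
            "Tumor_Sample_Barcode": r.sample_id,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=MAF_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_matrix(
    matrix: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    path: str | Path,
    index_name: str = "Channel",
) -> None:
    """Write a labelled matrix as TSV (rows = channels/signatures,
    columns = samples)."""
    df = pd.DataFrame(
        np.asarray(matrix),
        index=pd.Index(row_labels, name=index_name),
        columns=list(col_labels),
    )
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
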