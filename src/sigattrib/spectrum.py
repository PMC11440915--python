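"""Mutation classification and per-sample spectrum construction.

Single-base substitutions are classified into the 96 trinucleotide
channels on the pyrimidine strand: when the mutated reference base is a
purine, the mutation and both flanks are reverse-complemented before
labelling, so each substitution has exactly one channel regardless of
the strand the call is reported on.

Doublet substitutions collapse onto the canonical 78-channel set the
same way; indels are classified into 83 channels by indel length,
repeat context (homopolymer run for 1-bp events, adjacent tandem copies
for longer ones, capped at 5+) and, for non-repetitive deletions,
flanking microhomology (longest overlap between the deleted sequence
and its immediate flanks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

from .channels import (
    CHANNEL_INDEX,
    DBS78_SET,
    PURINES,
    SCHEME_CHANNELS,
    SUBST6_CHANNELS,
    Scheme,
    revcomp,
)
from .errors import ContextUnavailableError, ValidationError
from .formats_io import MutationRecord, ReferenceSequence

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

# Classifications describing single-base changes that alter the protein
# sequence ("AA" subset). Silent and Splice_Site are excluded: a splice
# change does not substitute an amino acid.
AA_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)


@dataclass(frozen=True)
class SubsetRule:
    """Which variant classifications enter an SBS spectrum.

    ``included_classifications = None`` means every SNP is eligible
    (the "ALL" subset); the "AA" subset keeps only amino-acid-altering
    SNPs, so AA is a subset of ALL on any record set.
    """

    name: str
    included_classifications: Optional[FrozenSet[str]] = None

    def includes(self, classification: str) -> bool:
        if self.included_classifications is None:
            return True
        return classification in self.included_classifications


ALL_SUBSET = SubsetRule(name="ALL", included_classifications=None)
AA_SUBSET = SubsetRule(name="AA", included_classifications=AA_CLASSIFICATIONS)

SUBSETS = {"ALL": ALL_SUBSET, "AA": AA_SUBSET}


@dataclass
class SampleSpectrum:
    """Per-sample integer counts over a channel scheme."""

    sample_id: str
    scheme: Scheme
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        self.counts = np.asarray(self.counts)
        expected = len(SCHEME_CHANNELS[self.scheme])
        if self.counts.shape != (expected,):
            raise ValidationError(
                f"spectrum for {self.sample_id!r} has {self.counts.shape} "
                f"counts, scheme {self.scheme.value} requires {expected}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("spectrum counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: cannot normalise empty spectrum"
            )
        return self.counts / total


def extract_context(
    reference: ReferenceSequence, chromosome: str, position: int
) -> str:
    """Trinucleotide context centered on a 1-based position.

    Raises :class:`ContextUnavailableError` when a flank falls outside
    the contig or the window contains an N.
    """
    if chromosome not in reference.contigs:
        raise ValidationError(f"unknown contig {chromosome!r}")
    length = reference.length(chromosome)
    if position < 2 or position > length - 1:
        raise ContextUnavailableError(
            f"{chromosome}:{position}: flank outside contig"
        )
    tri = reference.window(chromosome, position - 1, position + 1)
    if "N" in tri:
        raise ContextUnavailableError(f"{chromosome}:{position}: N in context")
    return tri


def classify_sbs(reference_allele: str, alternate_allele: str, context: str) -> str:
    """SBS96 channel label ``5'[REF>ALT]3'`` on the pyrimidine strand."""
    ref, alt = reference_allele, alternate_allele
    if ref not in _BASES or alt not in _BASES:
        raise ValidationError(f"invalid substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError("reference and alternate alleles are equal")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValidationError(f"invalid trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValidationError(
            f"context middle base {context[1]} != reference allele {ref}"
        )
    if ref in PURINES:
        context = revcomp(context)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def classify_dbs(reference_doublet: str, alternate_doublet: str) -> str:
    """DBS78 channel for a doublet substitution where both bases change."""
    ref, alt = reference_doublet, alternate_doublet
    if len(ref) != 2 or len(alt) != 2 or not (set(ref) | set(alt)) <= _BASES:
        raise ValidationError(f"invalid doublet substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError("doublet alternate equals reference")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValidationError(
            f"{ref}>{alt}: both doublet positions must change"
        )
    label = f"{ref}>{alt}"
    if label in DBS78_SET:
        return label
    label = f"{revcomp(ref)}>{revcomp(alt)}"
    if label not in DBS78_SET:  # pragma: no cover - exhaustivity guard
        raise ValidationError(f"no canonical channel for {ref}>{alt}")
    return label


def _run_length(seq: str, start: int, base: str, step: int) -> int:
    """Length of the run of ``base`` in ``seq`` walking from ``start``."""
    n = 0
    i = start
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def _tandem_copies(seq: str, left_end: int, right_start: int, unit: str) -> int:
    """Adjacent exact tandem copies of ``unit`` left of ``left_end``
    (exclusive) and starting at ``right_start``."""
    L = len(unit)
    n = 0
    i = right_start
    while seq[i : i + L] == unit:
        n += 1
        i += L
    i = left_end - L
    while i >= 0 and seq[i : i + L] == unit:
        n += 1
        i -= L
    return n


def _microhomology(seq: str, left_end: int, right_start: int, unit: str) -> int:
    """Longest overlap between a deleted sequence and its flanks: the
    longest proper prefix of ``unit`` matching the right flank, or proper
    suffix matching the left flank."""
    L = len(unit)
    right = seq[right_start : right_start + L - 1]
    mh_right = 0
    for j in range(1, len(right) + 1):
        if unit[:j] == right[:j]:
            mh_right = j
        else:
            break
    left = seq[max(0, left_end - (L - 1)) : left_end]
    mh_left = 0
    for j in range(1, len(left) + 1):
        if unit[L - j :] == left[len(left) - j :]:
            mh_left = j
        else:
            break
    return max(mh_right, mh_left)


def _cap(value: int, cap: int = 5) -> str:
    return f"{cap}+" if value >= cap else str(value)


def classify_indel(record: MutationRecord, reference: ReferenceSequence) -> str:
    """ID83 channel label for an insertion or deletion record."""
    if record.variant_type not in ("INS", "DEL"):
        raise ValidationError(
            f"classify_indel requires INS/DEL, got {record.variant_type}"
        )
    is_del = record.variant_type == "DEL"
    unit = record.reference_allele if is_del else record.alternate_allele
    if "N" in unit:
        raise ContextUnavailableError(
            f"{record.chromosome}:{record.start_position}: N in indel sequence"
        )
    if not set(unit) <= _BASES:
        raise ValidationError(f"invalid indel sequence {unit!r}")
    if record.chromosome not in reference.contigs:
        raise ValidationError(f"unknown contig {record.chromosome!r}")
    seq = reference.contigs[record.chromosome]
    L = len(unit)
    p = record.start_position - 1  # 0-based
    if is_del:
        if seq[p : p + L] != unit:
            raise ValidationError(
                f"{record.chromosome}:{record.start_position}: reference "
                f"mismatch for deletion of {unit!r}"
            )
        left_end, right_start = p, p + L
    else:
        # insertion after the base at start_position
        left_end, right_start = p + 1, p + 1
    op = "DEL" if is_del else "INS"

    if L == 1:
        base = unit
        copies = _run_length(seq, left_end - 1, base, -1) + _run_length(
            seq, right_start, base, +1
        )
        if base in PURINES:
            base = revcomp(base)
        return f"{op}.{base}.1.{_cap(copies)}"

    len_cat = _cap(L, 5)
    copies = _tandem_copies(seq, left_end, right_start, unit)
    if is_del and copies == 0:
        mh = _microhomology(seq, left_end, right_start, unit)
        if mh >= 1:
            cap = {2: 1, 3: 2, 4: 3}.get(L, 5)
            mh_cat = _cap(min(mh, cap), 5) if L >= 5 else str(min(mh, cap))
            return f"DEL.M.{len_cat}.{mh_cat}"
    return f"{op}.R.{len_cat}.{_cap(copies)}"


def _sbs_channel_for_record(
    record: MutationRecord, reference: ReferenceSequence
) -> str:
    context = extract_context(reference, record.chromosome, record.start_position)
    if context[1] != record.reference_allele:
        raise ValidationError(
            f"{record.chromosome}:{record.start_position}: reference base "
            f"{context[1]} does not match MAF allele {record.reference_allele}"
        )
    return classify_sbs(record.reference_allele, record.alternate_allele, context)


_SCHEME_VARIANT_TYPES = {
    Scheme.SBS96: ("SNP",),
    Scheme.SUBST6: ("SNP",),
    Scheme.DBS78: ("DNP",),
    Scheme.ID83: ("INS", "DEL"),
}


def build_spectra(
    records: Iterable[MutationRecord],
    reference: ReferenceSequence,
    scheme: Scheme,
    subset: SubsetRule = ALL_SUBSET,
) -> List[SampleSpectrum]:
    """Build one spectrum per distinct sample.

    Each eligible record contributes exactly one count to exactly one
    channel; records whose context is unavailable (contig edge, N) are
    skipped with a logged warning. The subset rule applies to the
    SNP-based schemes only. Spectra are returned sorted by sample id.
    """
    scheme = Scheme(scheme)
    index = CHANNEL_INDEX[scheme]
    eligible_types = _SCHEME_VARIANT_TYPES[scheme]
    counts: Dict[str, np.ndarray] = {}
    n_skipped = 0
    for record in records:
        if record.sample_id not in counts:
            counts[record.sample_id] = np.zeros(len(index), dtype=int)
        if record.variant_type not in eligible_types:
            continue
        if scheme in (Scheme.SBS96, Scheme.SUBST6) and not subset.includes(
            record.variant_classification
        ):
            continue
        try:
            if scheme in (Scheme.SBS96, Scheme.SUBST6):
                label = _sbs_channel_for_record(record, reference)
                if scheme is Scheme.SUBST6:
                    label = label[2:5]  # e.g. A[C>T]G -> C>T
            elif scheme is Scheme.DBS78:
                label = classify_dbs(record.reference_allele, record.alternate_allele)
            else:
                label = classify_indel(record, reference)
        except ContextUnavailableError as exc:
            n_skipped += 1
            logger.warning("skipping record: %s", exc)
            continue
        counts[record.sample_id][index[label]] += 1
    if n_skipped:
        logger.warning("%d records skipped (context unavailable)", n_skipped)
    return [
        SampleSpectrum(sample_id=sid, scheme=scheme, counts=counts[sid])
        for sid in sorted(counts)
    ]


@dataclass
class SubstitutionSummary:
    """Cohort six-class substitution fractions and Ti/Tv split."""

    fractions: Dict[str, float]
    ti: float
    tv: float


def summarize_substitutions(spectra: Iterable[SampleSpectrum]) -> SubstitutionSummary:
    """Six-class fractions plus transition/transversion fractions.

    Transitions are C>T and T>C (pyrimidine-strand labels); Tv = 1 - Ti.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValidationError("summarize_substitutions requires spectra")
    totals = np.zeros(6)
    for sp in spectra:
        if sp.scheme is Scheme.SBS96:
            per_class = sp.counts.reshape(6, 16).sum(axis=1)
        elif sp.scheme is Scheme.SUBST6:
            per_class = sp.counts
        else:
            raise ValidationError("substitution summary requires SBS96/SUBST6")
        totals += per_class
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("all spectra empty: fractions undefined")
    fractions = {c: float(t / grand) for c, t in zip(SUBST6_CHANNELS, totals)}
    ti = fractions["C>T"] + fractions["T>C"]
    return SubstitutionSummary(fractions=fractions, ti=ti, tv=1.0 - ti)


def spectra_matrix(spectra: List[SampleSpectrum]) -> Tuple[np.ndarray, List[str]]:
    """Stack spectra as a samples x channels count matrix."""
    if not spectra:
        raise ValidationError("no spectra given")
    schemes = {sp.scheme for sp in spectra}
    if len(schemes) != 1:
        raise ValidationError("spectra mix channel schemes")
    X = np.stack([sp.counts for sp in spectra])
    return X, [sp.sample_id for sp in spectra]
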