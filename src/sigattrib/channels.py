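"""Canonical channel schemes for mutation spectra.

Four schemes are defined, each with a fixed channel order used by every
matrix in the package:

* ``SBS96``  — single-base substitutions in trinucleotide context,
  pyrimidine-strand collapsed: six substitution types x 16 flanking
  contexts, written ``5'[REF>ALT]3'``.
* ``DBS78``  — doublet-base substitutions where both positions change,
  reverse-complement collapsed onto the 78 canonical ``REF>ALT`` doublets.
* ``ID83``   — small insertions/deletions classified by length (1, 2, 3,
  4, 5+), repeat context (homopolymer run or tandem-repeat copies, capped
  at 5+) and, for non-repetitive deletions, flanking microhomology.
* ``SUBST6`` — the six-class substitution summary (C>A ... T>G).
"""

from __future__ import annotations

from enum import Enum

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class Scheme(str, Enum):
    SBS96 = "SBS96"
    DBS78 = "DBS78"
    ID83 = "ID83"
    SUBST6 = "SUBST6"


SUBST6_CHANNELS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

# COSMIC ordering: grouped by substitution type, then 5' flank, then 3' flank.
SBS96_CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBST6_CHANNELS
    for five in "ACGT"
    for three in "ACGT"
]

# Canonical doublet channels: reference doublets and their admissible
# alternates after reverse-complement collapsing (both bases substituted).
# For each raw (ref, alt) exactly one of the two strand presentations
# appears below.
_DBS78_ALTS = {
    "AC": ["CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "AT": ["CA", "CC", "CG", "GA", "GC", "TA"],
    "CC": ["AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "CG": ["AT", "GC", "GT", "TA", "TC", "TT"],
    "CT": ["AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"],
    "GC": ["AA", "AG", "AT", "CA", "CG", "TA"],
    "TA": ["AT", "CG", "CT", "GC", "GG", "GT"],
    "TC": ["AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"],
    "TG": ["AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"],
    "TT": ["AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"],
}

DBS78_CHANNELS = [
    f"{ref}>{alt}" for ref in sorted(_DBS78_ALTS) for alt in _DBS78_ALTS[ref]
]
DBS78_SET = frozenset(DBS78_CHANNELS)

_REPEAT_BINS = ["0", "1", "2", "3", "4", "5+"]
_LEN_BINS = ["2", "3", "4", "5+"]

# Microhomology bins per deletion-length category: microhomology length is
# strictly shorter than the deleted sequence, capped at 5+.
_MH_BINS = {"2": ["1"], "3": ["1", "2"], "4": ["1", "2", "3"],
            "5+": ["1", "2", "3", "4", "5+"]}

ID83_CHANNELS = (
    [f"DEL.{b}.1.{r}" for b in ("C", "T") for r in _REPEAT_BINS]
    + [f"INS.{b}.1.{r}" for b in ("C", "T") for r in _REPEAT_BINS]
    + [f"DEL.R.{ln}.{r}" for ln in _LEN_BINS for r in _REPEAT_BINS]
    + [f"INS.R.{ln}.{r}" for ln in _LEN_BINS for r in _REPEAT_BINS]
    + [f"DEL.M.{ln}.{m}" for ln in _LEN_BINS for m in _MH_BINS[ln]]
)

SCHEME_CHANNELS = {
    Scheme.SBS96: SBS96_CHANNELS,
    Scheme.DBS78: DBS78_CHANNELS,
    Scheme.ID83: ID83_CHANNELS,
    Scheme.SUBST6: SUBST6_CHANNELS,
}

CHANNEL_INDEX = {
    scheme: {label: i for i, label in enumerate(labels)}
    for scheme, labels in SCHEME_CHANNELS.items()
}


def n_channels(scheme: Scheme) -> int:
    return len(SCHEME_CHANNELS[Scheme(scheme)])
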