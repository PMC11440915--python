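"""Shared fixtures: synthetic catalogs, references, and a designed
exhaustive indel case set covering all 83 ID channels."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pytest

from sigattrib.channels import SBS96_CHANNELS, Scheme
from sigattrib.formats_io import (
    MutationRecord,
    ReferenceSequence,
    SignatureCatalog,
)
from sigattrib.synthetic_data import simulate_catalog, simulate_reference


@pytest.fixture(scope="session")
def sep_catalog() -> SignatureCatalog:
    """Five well-separated synthetic SBS96 signatures."""
    return simulate_catalog(5, seed=101, well_separated=True)


@pytest.fixture(scope="session")
def sim_reference() -> ReferenceSequence:
    """20 kb random reference; every trinucleotide context present."""
    return simulate_reference(20_000, seed=11)


@pytest.fixture(scope="session")
def designed_pair_catalog() -> SignatureCatalog:
    """Two signatures with disjoint 8-channel supports (maximally
    separable; their 50/50 mixture is still non-uniform)."""
    a = np.zeros(96)
    a[:8] = 1 / 8
    b = np.zeros(96)
    b[48:56] = 1 / 8
    return SignatureCatalog(
        scheme=Scheme.SBS96,
        channel_labels=list(SBS96_CHANNELS),
        signature_ids=["SigA", "SigB"],
        matrix=np.stack([a, b]),
    )


def _del_record(contig_seq: str, start: int, seq: str) -> Tuple[ReferenceSequence, MutationRecord]:
    ref = ReferenceSequence({"c": contig_seq})
    rec = MutationRecord(
        gene_symbol="G", chromosome="c", start_position=start,
        reference_allele=seq, alternate_allele="-",
        variant_classification="Frame_Shift_Del", variant_type="DEL",
        sample_id="s",
    )
    return ref, rec


def _ins_record(contig_seq: str, start: int, seq: str) -> Tuple[ReferenceSequence, MutationRecord]:
    ref = ReferenceSequence({"c": contig_seq})
    rec = MutationRecord(
        gene_symbol="G", chromosome="c", start_position=start,
        reference_allele="-", alternate_allele=seq,
        variant_classification="Frame_Shift_Ins", variant_type="INS",
        sample_id="s",
    )
    return ref, rec


def build_id83_cases() -> List[Tuple[str, ReferenceSequence, MutationRecord]]:
    """One (expected label, reference, record) triple per ID83 channel.

    Constructed so each case hits exactly one channel: homopolymer runs
    of controlled length for 1-bp events, exact tandem copies for
    longer ones, and right-flank prefix overlaps for the microhomology
    deletions (flanks are chosen so no unintended repeat or homology
    arises).
    """
    cases = []
    units = {2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTA", 6: "ACGTAC"}
    # 1-bp deletions/insertions: r extra copies beside the event base
    for base in "CT":
        for r in range(6):
            label_r = "5+" if r >= 5 else str(r)
            run = base * (r + 1)
            cases.append(
                (f"DEL.{base}.1.{label_r}",)
                + _del_record("GG" + run + "AA", 3, base)
            )
            cases.append(
                (f"INS.{base}.1.{label_r}",)
                + _ins_record("GG" + base * r + "AA", 2 + r, base)
            )
    # multi-bp repeats: r adjacent tandem copies besides the event unit.
    # Flanks avoid the unit's terminal bases so no microhomology arises
    # in the zero-repeat deletion cases.
    for L, len_cat in ((2, "2"), (3, "3"), (4, "4"), (5, "5+")):
        unit = units[L]
        left = "GG" if unit[-1] != "G" else "TT"
        for r in range(6):
            label_r = "5+" if r >= 5 else str(r)
            cases.append(
                (f"DEL.R.{len_cat}.{label_r}",)
                + _del_record(left + unit * (r + 1) + "GG", 3, unit)
            )
            cases.append(
                (f"INS.R.{len_cat}.{label_r}",)
                + _ins_record(left + unit * r + "GG", 2 + r * L, unit)
            )
    # microhomology deletions: right flank repeats the first m unit bases
    mh_plan = {2: [1], 3: [1, 2], 4: [1, 2, 3], 5: [1, 2, 3, 4], 6: [5]}
    for L, mhs in mh_plan.items():
        unit = units[L]
        left = "GG" if unit[-1] != "G" else "TT"
        len_cat = "5+" if L >= 5 else str(L)
        for m in mhs:
            mh_cat = "5+" if m >= 5 else str(m)
            filler = "T" if unit[m] != "T" else "G"
            contig = left + unit + unit[:m] + filler + "GG"
            cases.append(
                (f"DEL.M.{len_cat}.{mh_cat}",) + _del_record(contig, 3, unit)
            )
    return cases


@pytest.fixture(scope="session")
def id83_cases():
    return build_id83_cases()
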