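"""Cohort-level summaries and two-group frequency comparisons.

Per-gene alteration tables count each classification of alteration, the
total, and the number of distinct altered samples per gene. Mutation
burden is alterations per megabase of targeted sequence. Group
frequency differences in signature presence are tested with a pooled
two-sided two-proportion z test (no continuity correction), which is
the uncorrected chi-square test on the 2x2 table; Fisher's exact test
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .errors import ParameterError, ValidationError
from .formats_io import KNOWN_CLASSIFICATIONS, MutationRecord


@dataclass
class GeneAlterationSummary:
    gene_symbol: str
    classification_counts: Dict[str, int]
    total_alterations: int
    altered_samples: int
    frequency: float  # altered_samples / cohort_size, rounded to 3 decimals


def gene_alteration_summary(
    records: Sequence[MutationRecord], cohort_size: int
) -> List[GeneAlterationSummary]:
    """Per-gene alteration counts over a cohort.

    Genes are sorted by alteration frequency ascending (ties by gene
    symbol); genes absent from the records are omitted. ``frequency``
    is rounded to 3 decimals for report output.
    """
    distinct_samples = {r.sample_id for r in records}
    if cohort_size < len(distinct_samples):
        raise ValidationError(
            f"cohort_size {cohort_size} < {len(distinct_samples)} distinct "
            "samples in records"
        )
    per_gene: Dict[str, List[MutationRecord]] = {}
    for r in records:
        per_gene.setdefault(r.gene_symbol, []).append(r)
    out = []
    for gene, recs in per_gene.items():
        counts = {c: 0 for c in KNOWN_CLASSIFICATIONS}
        for r in recs:
            counts[r.variant_classification] = (
                counts.get(r.variant_classification, 0) + 1
            )
        samples = len({r.sample_id for r in recs})
        out.append(
            GeneAlterationSummary(
                gene_symbol=gene,
                classification_counts=counts,
                total_alterations=len(recs),
                altered_samples=samples,
                frequency=round(samples / cohort_size, 3),
            )
        )
    out.sort(key=lambda g: (g.frequency, g.gene_symbol))
    return out


def gene_summary_frame(summaries: Iterable[GeneAlterationSummary]) -> pd.DataFrame:
    """Tabular view of per-gene summaries (one row per gene)."""
    rows = []
    for g in summaries:
        row = {"Gene": g.gene_symbol}
        row.update(g.classification_counts)
        row["Total_alterations"] = g.total_alterations
        row["Altered_samples"] = g.altered_samples
        row["Frequency"] = g.frequency
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BurdenSummary:
    per_sample: Dict[str, float]
    mean: float


def mutation_burden(
    records: Sequence[MutationRecord],
    target_size_mb: float,
    sample_ids: Optional[Sequence[str]] = None,
) -> BurdenSummary:
    """Alterations per megabase per sample, and the cohort mean.

    ``sample_ids`` may list samples with zero alterations so they enter
    the denominator with burden 0.
    """
    if target_size_mb <= 0:
        raise ParameterError("target_size_mb must be positive")
    counts: Dict[str, int] = {}
    if sample_ids is not None:
        counts = {s: 0 for s in sample_ids}
    for r in records:
        counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    per_sample = {s: c / target_size_mb for s, c in sorted(counts.items())}
    mean = float(np.mean(list(per_sample.values()))) if per_sample else 0.0
    return BurdenSummary(per_sample=per_sample, mean=mean)


def two_proportion_test(
    count1: int, size1: int, count2: int, size2: int
) -> Tuple[float, float]:
    """Pooled two-sided two-proportion z test without continuity
    correction: ``p = 2 * (1 - Phi(|z|))``.

    Returns ``(z, p)``. Equal proportions (including both groups empty
    of events) give ``z=0, p=1``.
    """
    if size1 <= 0 and size2 <= 0:
        raise ValidationError("both group sizes are zero")
    if size1 <= 0 or size2 <= 0:
        raise ValidationError("group sizes must be positive")
    if not (0 <= count1 <= size1 and 0 <= count2 <= size2):
        raise ValidationError("counts must lie in [0, size]")
    pooled = (count1 + count2) / (size1 + size2)
    if pooled in (0.0, 1.0) or count1 * size2 == count2 * size1:
        return 0.0, 1.0
    z, p = proportions_ztest([count1, count2], [size1, size2])
    return float(z), float(p)


def fisher_exact_test(
    count1: int, size1: int, count2: int, size2: int
) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on the same 2x2 table; returns the
    odds ratio and p-value."""
    table = [[count1, size1 - count1], [count2, size2 - count2]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class GroupComparison:
    signature_id: str
    count1: int
    size1: int
    count2: int
    size2: int
    z: float
    p_value: float

    @property
    def frequency1(self) -> float:
        return self.count1 / self.size1

    @property
    def frequency2(self) -> float:
        return self.count2 / self.size2


def compare_group_frequencies(
    presence_group1: pd.DataFrame,
    presence_group2: pd.DataFrame,
    test: str = "pooled_z",
) -> List[GroupComparison]:
    """Per-signature presence-frequency comparison between two groups.

    Each input is a samples x signatures boolean table; the signature
    sets must agree. Signatures absent from both groups are reported
    with ``z=0, p=1``.
    """
    sigs1, sigs2 = set(presence_group1.columns), set(presence_group2.columns)
    if sigs1 != sigs2:
        raise ValidationError("presence tables have different signature sets")
    if test not in ("pooled_z", "fisher"):
        raise ParameterError(f"unknown test {test!r}")
    n1, n2 = len(presence_group1), len(presence_group2)
    out = []
    for sig in presence_group1.columns:
        c1 = int(presence_group1[sig].astype(bool).sum())
        c2 = int(presence_group2[sig].astype(bool).sum())
        if test == "pooled_z":
            z, p = two_proportion_test(c1, n1, c2, n2)
        else:
            z, p = fisher_exact_test(c1, n1, c2, n2)
        out.append(GroupComparison(sig, c1, n1, c2, n2, z, p))
    out.sort(key=lambda g: (g.p_value, g.signature_id))
    return out
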