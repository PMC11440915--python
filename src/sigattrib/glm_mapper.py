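"""Per-case GLM mapping of spectra onto a reference signature catalog.

For every case, each catalog signature is regressed on the case's
normalised 96-channel spectrum with an ordinary linear model (identity
link, intercept included): the signature's channel probabilities are the
response and the case's channel proportions the single predictor. The
two-sided p-value of the slope is thresholded at ``alpha`` (default
1e-6, i.e. -log10 P > 6); every signature passing the threshold is
reported as significant and the one with the smallest p-value is the
case's best signature. Cases with no significant signature are labelled
``NoMapping`` and can be clustered separately on their trinucleotide
spectra.

The regression orientation above follows the as-written formula
(signature as response); the transposed orientation (spectrum as
response) is available via :class:`MapperConfig.orientation`. For a
simple regression with an intercept the slope t-test is symmetric in
the two variables, so both orientations give identical p-values; the
switch is kept for explicitness.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .channels import Scheme
from .errors import ParameterError, ValidationError
from .formats_io import SignatureCatalog
from .spectrum import SampleSpectrum

logger = logging.getLogger(__name__)

NO_MAPPING = "NoMapping"


@dataclass
class MapperConfig:
    """Thresholds for the per-case signature mapper.

    alpha: slope p-value threshold; the default 1e-6 corresponds to
        requiring -log10 P > 6.
    min_mutations: minimum spectrum total to attempt mapping; below it
        the case is NoMapping.
    orientation: "signature_on_spectrum" regresses the signature on the
        case spectrum (as-written default); "spectrum_on_signature" is
        the transpose.
    """

    alpha: float = 1e-6
    min_mutations: int = 1
    orientation: str = "signature_on_spectrum"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.orientation not in (
            "signature_on_spectrum",
            "spectrum_on_signature",
        ):
            raise ParameterError(f"unknown orientation {self.orientation!r}")


@dataclass
class CohortAssignment:
    """GLM mapping result for one case."""

    sample_id: str
    p_values: Dict[str, float]
    significant: Set[str]
    best: str

    def __post_init__(self) -> None:
        for sig, p in self.p_values.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"p-value for {sig} outside [0,1]: {p}")
        if self.significant and self.best == NO_MAPPING:
            raise ValidationError("best=NoMapping with nonempty significant set")
        if not self.significant and self.best != NO_MAPPING:
            raise ValidationError("best set while significant set is empty")


def _slope_pvalue(y: np.ndarray, x: np.ndarray) -> float:
    """Two-sided p-value of the slope in an OLS fit of y on [1, x]."""
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    p = float(res.pvalues[1])
    if math.isnan(p):
        return 1.0
    return p


def map_case(
    spectrum: SampleSpectrum,
    catalog: SignatureCatalog,
    config: MapperConfig = MapperConfig(),
) -> CohortAssignment:
    """Map one case's SBS96 spectrum onto the catalog.

    A spectrum below ``min_mutations`` or with a zero-variance predictor
    (empty or perfectly uniform) has an undefined slope test: every
    p-value is recorded as 1 and the case is NoMapping. Ties in the best
    p-value are broken by catalog order (first wins).
    """
    if catalog.scheme is not Scheme.SBS96:
        raise ValidationError("map_case requires an SBS96 catalog")
    if spectrum.scheme is not Scheme.SBS96:
        raise ValidationError("map_case requires an SBS96 spectrum")
    total = spectrum.total
    if total < max(config.min_mutations, 1):
        p_values = {s: 1.0 for s in catalog.signature_ids}
        return CohortAssignment(spectrum.sample_id, p_values, set(), NO_MAPPING)
    x = spectrum.counts / total
    if np.all(x == x[0]):
        p_values = {s: 1.0 for s in catalog.signature_ids}
        return CohortAssignment(spectrum.sample_id, p_values, set(), NO_MAPPING)
    p_values: Dict[str, float] = {}
    for sig_id, sig_row in zip(catalog.signature_ids, catalog.matrix):
        if config.orientation == "signature_on_spectrum":
            p_values[sig_id] = _slope_pvalue(sig_row, x)
        else:
            p_values[sig_id] = _slope_pvalue(x, sig_row)
    significant = {s for s, p in p_values.items() if p < config.alpha}
    if not significant:
        return CohortAssignment(spectrum.sample_id, p_values, set(), NO_MAPPING)
    best = None
    best_p = None
    for sig_id in catalog.signature_ids:  # catalog order breaks ties
        if sig_id in significant:
            p = p_values[sig_id]
            if best_p is None or p < best_p:
                best, best_p = sig_id, p
    return CohortAssignment(spectrum.sample_id, p_values, significant, best)


def map_cohort(
    spectra: Iterable[SampleSpectrum],
    catalog: SignatureCatalog,
    config: MapperConfig = MapperConfig(),
) -> List[CohortAssignment]:
    """Map every case; deterministic given inputs."""
    assignments = []
    for sp in spectra:
        a = map_case(sp, catalog, config)
        if a.best == NO_MAPPING:
            logger.info("case %s: NoMapping", sp.sample_id)
        assignments.append(a)
    return assignments


def rank_signatures(
    assignments: Sequence[CohortAssignment], mode: str = "all_significant"
) -> pd.DataFrame:
    """Signature frequency table across the cohort.

    ``all_significant`` counts each signature once per case in which it
    is significant; the denominator is the number of mapped cases (cases
    with at least one significant signature). ``best_only`` counts each
    case's single best signature over all cases, with NoMapping as its
    own row. Frequencies are rounded to 2 decimals for report output.
    """
    if mode == "all_significant":
        mapped = [a for a in assignments if a.significant]
        denom = len(mapped)
        counter = Counter(sig for a in mapped for sig in a.significant)
        rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    elif mode == "best_only":
        denom = len(assignments)
        counter = Counter(a.best for a in assignments)
        named = sorted(
            ((s, c) for s, c in counter.items() if s != NO_MAPPING),
            key=lambda kv: (-kv[1], kv[0]),
        )
        rows = named + (
            [(NO_MAPPING, counter[NO_MAPPING])] if NO_MAPPING in counter else []
        )
    else:
        raise ParameterError(f"unknown ranking mode {mode!r}")
    return pd.DataFrame(
        {
            "signature_id": [s for s, _ in rows],
            "n_cases": [c for _, c in rows],
            "frequency": [round(c / denom, 2) if denom else 0.0 for _, c in rows],
        }
    )


def cluster_unmapped(spectra: Sequence[SampleSpectrum], k: int) -> np.ndarray:
    """Agglomerative clustering of NoMapping cases.

    Average linkage on cosine distance between proportion-normalised
    96-channel vectors; the dendrogram is cut into exactly ``k`` groups.
    Labels are 1-based and deterministic.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if len(spectra) < k:
        raise ParameterError(f"{len(spectra)} cases < k={k}")
    X = np.stack([sp.proportions() for sp in spectra])
    if k == 1 or len(spectra) == 1:
        return np.ones(len(spectra), dtype=int)
    d = np.clip(pdist(X, metric="cosine"), 0.0, None)
    Z = hierarchy.linkage(d, method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")
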