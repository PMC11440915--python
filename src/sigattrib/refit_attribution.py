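"""Exposure refitting, attribution rules, catalog matching, and NMF.

Refitting estimates nonnegative signature weights for one sample against
a fixed catalog by least squares on the proportion vector, then prunes
aggressively to avoid overfitting:

1. solve nonnegative least squares (NNLS);
2. iteratively drop any signature whose weight falls below the
   signature cutoff (default 0.02), re-solving after each removal;
3. greedily drop (smallest weight first) any remaining signature whose
   exclusion costs at most the similarity-gain threshold (default 0.02)
   in cosine similarity between the observed and reconstructed spectrum,
   re-solving after each removal;
4. renormalise the retained weights to sum 1.

Cohort-level attribution rules follow: per-sample weights below the
cohort floor (default 0.6%) are zeroed, and a signature is called
present in a sample only when at least ``presence_threshold`` (default
100) mutations are attributed to it.

De novo extraction is a small nonnegative matrix factorisation by
multiplicative updates minimising generalised Kullback-Leibler
divergence, with a per-iteration objective trace; candidate signatures
are matched back to a catalog by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import ParameterError, ValidationError
from .formats_io import SignatureCatalog
from .spectrum import SampleSpectrum

logger = logging.getLogger(__name__)


@dataclass
class RefitConfig:
    signature_cutoff: float = 0.02
    similarity_gain_threshold: float = 0.02
    cohort_floor: float = 0.006
    presence_threshold: int = 100
    max_iterations: int = 100
    match_threshold: float = 0.85

    def __post_init__(self) -> None:
        for name in ("signature_cutoff", "similarity_gain_threshold",
                     "cohort_floor", "match_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0,1), got {v}")
        if self.presence_threshold < 0 or self.max_iterations < 1:
            raise ParameterError("invalid presence_threshold/max_iterations")


@dataclass
class ExposureProfile:
    """Per-sample signature weights, attributed counts and presence."""

    sample_id: str
    weights: Dict[str, float]
    attributed_counts: Dict[str, float]
    reconstruction_similarity: float
    present: Dict[str, bool]
    total_mutations: int
    empty_after_floor: bool = False


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def refit_exposures(
    spectrum: SampleSpectrum,
    catalog: SignatureCatalog,
    config: RefitConfig = RefitConfig(),
) -> ExposureProfile:
    """Estimate pruned signature exposures for one sample."""
    if spectrum.scheme is not catalog.scheme:
        raise ValidationError(
            f"spectrum scheme {spectrum.scheme.value} != catalog "
            f"{catalog.scheme.value}"
        )
    total = spectrum.total
    if total == 0:
        raise ValidationError(f"sample {spectrum.sample_id!r}: zero spectrum")
    b = spectrum.proportions().astype(float)
    A = catalog.channels_by_signatures()
    sig_ids = catalog.signature_ids
    active = list(range(len(sig_ids)))

    def solve(idx: List[int]) -> np.ndarray:
        w, _ = nnls(A[:, idx], b)
        return w

    w = solve(active)
    # zero-weight signatures do not affect the solution; drop them outright
    keep = w > 0
    if keep.any():
        active = [i for i, k in zip(active, keep) if k]
        w = w[keep]
    for _ in range(config.max_iterations):
        changed = False
        # (2) cutoff pruning, smallest first, re-solving each time
        while len(active) > 1:
            j = int(np.argmin(w))
            if w[j] < config.signature_cutoff:
                logger.info(
                    "sample %s: pruning %s (weight %.4f < cutoff)",
                    spectrum.sample_id, sig_ids[active[j]], w[j],
                )
                del active[j]
                w = solve(active)
                changed = True
            else:
                break
        # (3) similarity-based pruning, smallest weight first
        while len(active) > 1:
            sim = _cosine(b, A[:, active] @ w)
            removed = False
            for j in np.argsort(w, kind="stable"):
                trial = [s for idx, s in enumerate(active) if idx != j]
                w_trial = solve(trial)
                sim_trial = _cosine(b, A[:, trial] @ w_trial)
                if sim - sim_trial <= config.similarity_gain_threshold:
                    logger.info(
                        "sample %s: pruning %s (similarity cost %.4f)",
                        spectrum.sample_id, sig_ids[active[int(j)]],
                        sim - sim_trial,
                    )
                    active, w = trial, w_trial
                    removed = changed = True
                    break
            if not removed:
                break
        if not changed:
            break

    sim = _cosine(b, A[:, active] @ w) if len(active) else 0.0
    wsum = float(w.sum())
    weights = {s: 0.0 for s in sig_ids}
    if wsum > 0:
        for idx, wi in zip(active, w):
            weights[sig_ids[idx]] = float(wi / wsum)
    attributed = {s: weights[s] * total for s in sig_ids}
    return ExposureProfile(
        sample_id=spectrum.sample_id,
        weights=weights,
        attributed_counts=attributed,
        reconstruction_similarity=sim,
        present={s: False for s in sig_ids},
        total_mutations=total,
    )


def zero_rare_signatures(
    profiles: Sequence[ExposureProfile], config: RefitConfig = RefitConfig()
) -> List[ExposureProfile]:
    """Zero per-sample weights strictly below the cohort floor.

    Surviving weights are renormalised to sum 1; a profile left with no
    weight at all is flagged and not renormalised.
    """
    out = []
    for prof in profiles:
        kept = {
            s: (w if w >= config.cohort_floor else 0.0)
            for s, w in prof.weights.items()
        }
        total_w = sum(kept.values())
        if total_w == 0:
            out.append(
                replace(
                    prof,
                    weights=kept,
                    attributed_counts={s: 0.0 for s in kept},
                    empty_after_floor=True,
                )
            )
            continue
        weights = {s: w / total_w for s, w in kept.items()}
        attributed = {s: w * prof.total_mutations for s, w in weights.items()}
        out.append(replace(prof, weights=weights, attributed_counts=attributed))
    return out


def call_presence(
    profile: ExposureProfile, config: RefitConfig = RefitConfig()
) -> ExposureProfile:
    """Flag a signature present only when its attributed mutation count
    reaches the presence threshold (fewer than 100 attributed mutations
    means absent, at the default)."""
    present = {
        s: c >= config.presence_threshold
        for s, c in profile.attributed_counts.items()
    }
    return replace(profile, present=present)


@dataclass
class CatalogMatch:
    signature_id: Optional[str]
    similarity: float
    matched: bool


def match_to_catalog(
    candidate: np.ndarray,
    catalog: SignatureCatalog,
    match_threshold: float = 0.85,
) -> CatalogMatch:
    """Best cosine-similarity match of a candidate signature.

    Returns the argmax catalog signature and its similarity; the match
    is declared only when similarity reaches the threshold, otherwise
    the candidate is labelled unmatched (``signature_id=None``).
    """
    candidate = np.asarray(candidate, dtype=float)
    if candidate.shape != (len(catalog.channel_labels),):
        raise ValidationError("candidate/catalog scheme mismatch")
    if np.linalg.norm(candidate) == 0:
        raise ValidationError("zero candidate vector")
    sims = [
        _cosine(candidate, catalog.matrix[i])
        for i in range(catalog.n_signatures)
    ]
    best = int(np.argmax(sims))
    sim = float(sims[best])
    if sim >= match_threshold:
        return CatalogMatch(catalog.signature_ids[best], sim, True)
    return CatalogMatch(None, sim, False)


@dataclass
class NMFResult:
    """De novo factorisation: ``signatures`` is k x channels (rows sum
    to 1), ``exposures`` is samples x k, ``objective`` the generalised
    KL divergence after each iteration."""

    signatures: np.ndarray
    exposures: np.ndarray
    objective: List[float]


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask]) - V[mask])
    return float(div + WH.sum())


def extract_denovo(
    spectra_counts: np.ndarray,
    k: int,
    seed: int,
    iterations: int = 200,
) -> NMFResult:
    """Multiplicative-update KL-NMF of a samples x channels count matrix.

    Deterministic given the seed; the objective is non-increasing
    across iterations (standard property of the updates).
    """
    X = np.asarray(spectra_counts, dtype=float)
    if X.ndim != 2:
        raise ParameterError("spectra matrix must be 2-D (samples x channels)")
    n_samples, n_channels = X.shape
    if k < 1 or k > n_samples:
        raise ParameterError(f"k={k} outside [1, {n_samples}]")
    if np.any(X < 0):
        raise ValidationError("negative counts in spectra matrix")
    V = X.T  # channels x samples
    rng = np.random.default_rng(seed)
    eps = 1e-12
    W = rng.uniform(0.5, 1.5, size=(n_channels, k)) * (V.mean() + eps)
    H = rng.uniform(0.5, 1.5, size=(k, n_samples))
    objective: List[float] = []
    for _ in range(iterations):
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        objective.append(_gkl(V, W @ H + eps))
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return NMFResult(signatures=W.T, exposures=H.T, objective=objective)
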