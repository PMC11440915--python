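"""Synthetic references, catalogs and cohorts with known ground truth.

The simulator emulates the study conditions of a medium-sized tumor
exome cohort: per-case mutation totals are log-normal with median 66
and enough dispersion that 175 cases span roughly 1-2000 mutations
(heavy-tailed); each case is a sparse mixture of 1-4 catalog
signatures; a configurable fraction of events are indels placed at
repeat contexts.

Mutations are placed so that the emitted MAF re-classifies exactly to
the drawn channel: each single-base substitution is assigned a
trinucleotide channel drawn from its signature and then placed at a
uniformly chosen reference position whose context matches the channel
on either strand. Spectra built from the MAF therefore follow the
signature mixture exactly, which is what known-truth tests need; the
price is that spectra do not reflect the sequence composition of the
toy genome, as real spectra would.

All randomness flows from a single integer seed; identical
configurations produce byte-identical MAF files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .channels import (
    PYRIMIDINES,
    SBS96_CHANNELS,
    SCHEME_CHANNELS,
    Scheme,
    revcomp,
)
from .errors import GenerationError, ParameterError
from .formats_io import MutationRecord, ReferenceSequence, SignatureCatalog
from .spectrum import SampleSpectrum

_CLASSIFICATIONS = ("Missense_Mutation", "Silent", "Splice_Site", "Nonsense_Mutation")
_CLASS_PROBS = (0.60, 0.25, 0.10, 0.05)


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    median_mutations/log_sigma parameterise the log-normal per-case
    mutation total (median 66, sigma 1.3 spans ~1-2000 over 175 cases);
    active_signatures bounds the number of signatures mixed per case;
    dirichlet_concentration shapes the exposure weights; min_exposure
    optionally rejects draws with any active weight below it (used when
    a floor on true weights is required); indel_fraction is the fraction
    of additional indel events relative to the substitution count.
    """

    n_samples: int = 175
    median_mutations: float = 66.0
    log_sigma: float = 1.3
    active_signatures: Tuple[int, int] = (1, 4)
    dirichlet_concentration: float = 1.0
    min_exposure: float = 0.0
    indel_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ParameterError("n_samples must be >= 0")
        if not 0 <= self.indel_fraction <= 1:
            raise ParameterError("indel_fraction must be in [0,1]")
        if self.active_signatures[0] < 1:
            raise ParameterError("need at least one active signature")
        if not 0 <= self.min_exposure < 1:
            raise ParameterError("min_exposure must be in [0,1)")


@dataclass
class GroundTruth:
    """Known per-sample exposures and counts for a simulated cohort."""

    exposures: Dict[str, Dict[str, float]]
    snv_counts: Dict[str, int]
    indel_counts: Dict[str, int]
    channel_counts: Dict[str, np.ndarray]


def simulate_reference(length: int, seed: int, contig: str = "sim1") -> ReferenceSequence:
    """Uniform random A/C/G/T contig; deterministic given the seed."""
    if length < 3:
        raise ParameterError("reference length must be >= 3")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ReferenceSequence({contig: seq})


def context_index(reference: ReferenceSequence) -> Dict[str, List[Tuple[str, int, str]]]:
    """Index interior positions by pyrimidine-collapsed trinucleotide.

    Maps each of the 32 pyrimidine-centered contexts to the list of
    ``(contig, 1-based position, strand)`` sites presenting it, where
    strand '-' marks positions whose forward-strand center is a purine.
    """
    index: Dict[str, List[Tuple[str, int, str]]] = {}
    for contig, seq in reference.contigs.items():
        for pos in range(2, len(seq)):  # 1-based interior positions
            tri = seq[pos - 2 : pos + 1]
            if "N" in tri:
                continue
            if tri[1] in PYRIMIDINES:
                index.setdefault(tri, []).append((contig, pos, "+"))
            else:
                index.setdefault(revcomp(tri), []).append((contig, pos, "-"))
    return index


def simulate_catalog(
    n_signatures: int,
    concentration: float = 0.1,
    seed: int = 0,
    scheme: Scheme = Scheme.SBS96,
    well_separated: bool = False,
    max_pairwise_cosine: float = 0.5,
    signature_prefix: str = "SynthSig",
) -> SignatureCatalog:
    """Draw a catalog of Dirichlet signatures over the scheme channels.

    With ``well_separated=True``, draws are rejected until every
    pairwise cosine similarity is below ``max_pairwise_cosine``.
    """
    if n_signatures < 1:
        raise ParameterError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    channels = SCHEME_CHANNELS[Scheme(scheme)]
    alpha = np.full(len(channels), concentration)
    rows = [rng.dirichlet(alpha) for _ in range(n_signatures)]
    if well_separated:
        for _ in range(10_000):
            mat = np.stack(rows)
            norm = mat / np.linalg.norm(mat, axis=1, keepdims=True)
            cos = norm @ norm.T
            np.fill_diagonal(cos, 0.0)
            worst = np.unravel_index(np.argmax(cos), cos.shape)
            if cos[worst] < max_pairwise_cosine:
                break
            rows[worst[1]] = rng.dirichlet(alpha)
        else:  # pragma: no cover
            raise GenerationError("could not draw well-separated signatures")
    return SignatureCatalog(
        scheme=Scheme(scheme),
        channel_labels=list(channels),
        signature_ids=[f"{signature_prefix}{i + 1}" for i in range(n_signatures)],
        matrix=np.stack(rows),
    )


def draw_mutation_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal per-case mutation totals (>= 1)."""
    mu = math.log(config.median_mutations)
    counts = np.exp(rng.normal(mu, config.log_sigma, size=config.n_samples))
    return np.maximum(1, np.rint(counts)).astype(int)


def _draw_exposures(
    config: SimulationConfig, catalog: SignatureCatalog, rng: np.random.Generator
) -> Dict[str, float]:
    lo, hi = config.active_signatures
    hi = min(hi, catalog.n_signatures)
    lo = min(lo, hi)
    n_active = int(rng.integers(lo, hi + 1))
    active = rng.choice(catalog.n_signatures, size=n_active, replace=False)
    for _ in range(10_000):
        w = rng.dirichlet(np.full(n_active, config.dirichlet_concentration))
        if n_active == 1 or w.min() >= config.min_exposure:
            break
    else:  # pragma: no cover
        raise GenerationError("could not satisfy min_exposure")
    return {catalog.signature_ids[i]: float(wi) for i, wi in zip(active, w)}


def _gene_symbol(contig: str, position: int) -> str:
    return f"GENE_{contig}_{(position - 1) // 200:04d}"


def simulate_cohort(
    config: SimulationConfig,
    catalog: SignatureCatalog,
    reference: ReferenceSequence,
) -> Tuple[List[MutationRecord], GroundTruth]:
    """Simulate a cohort MAF with known exposures.

    Each substitution's channel is drawn from the case's signature
    mixture and placed at a context-matching reference position (either
    strand presentation); position collisions within a sample are
    re-drawn. Indels duplicate or delete single bases at homopolymer
    sites. Raises :class:`GenerationError` if a needed context has no
    site in the reference.
    """
    if catalog.scheme is not Scheme.SBS96:
        raise ParameterError("cohort simulation requires an SBS96 catalog")
    rng = np.random.default_rng(config.seed)
    index = context_index(reference)
    # homopolymer sites for indels: interior positions inside a run of >= 2
    repeat_sites = []
    for contig, seq in reference.contigs.items():
        for pos in range(2, len(seq)):
            if seq[pos - 1] == seq[pos - 2] or (
                pos < len(seq) and seq[pos - 1] == seq[pos]
            ):
                repeat_sites.append((contig, pos))
    records: List[MutationRecord] = []
    exposures: Dict[str, Dict[str, float]] = {}
    snv_counts: Dict[str, int] = {}
    indel_counts: Dict[str, int] = {}
    channel_counts: Dict[str, np.ndarray] = {}
    if config.n_samples == 0:
        return records, GroundTruth({}, {}, {}, {})
    totals = draw_mutation_counts(config, rng)
    sig_rows = {s: catalog.signature(s) for s in catalog.signature_ids}
    for i in range(config.n_samples):
        sample = f"S{i + 1:04d}"
        sample_expo = _draw_exposures(config, catalog, rng)
        active_ids = list(sample_expo)
        active_w = np.array([sample_expo[s] for s in active_ids])
        n_snv = int(totals[i])
        used: set = set()
        chan_counts = np.zeros(len(SBS96_CHANNELS), dtype=int)
        for _ in range(n_snv):
            sig = active_ids[int(rng.choice(len(active_ids), p=active_w))]
            ch = int(rng.choice(96, p=sig_rows[sig]))
            label = SBS96_CHANNELS[ch]
            five, ref_py, alt_py, three = label[0], label[2], label[4], label[6]
            key = five + ref_py + three
            sites = index.get(key)
            if not sites:
                raise GenerationError(f"no site for context {key} in reference")
            for _attempt in range(1000):
                contig, pos, strand = sites[int(rng.integers(len(sites)))]
                if (contig, pos) not in used:
                    break
            else:  # pragma: no cover
                raise GenerationError(f"could not place mutation in context {key}")
            used.add((contig, pos))
            if strand == "+":
                ref, alt = ref_py, alt_py
            else:
                ref, alt = revcomp(ref_py), revcomp(alt_py)
            cls = _CLASSIFICATIONS[int(rng.choice(4, p=_CLASS_PROBS))]
            records.append(
                MutationRecord(
                    gene_symbol=_gene_symbol(contig, pos),
                    chromosome=contig,
                    start_position=pos,
                    reference_allele=ref,
                    alternate_allele=alt,
                    variant_classification=cls,
                    variant_type="SNP",
                    sample_id=sample,
                )
            )
            chan_counts[ch] += 1
        n_indel = int(round(config.indel_fraction * n_snv))
        placed_indels = 0
        for _ in range(n_indel):
            for _attempt in range(1000):
                if repeat_sites and rng.random() < 0.8:
                    contig, pos = repeat_sites[int(rng.integers(len(repeat_sites)))]
                else:
                    contig = list(reference.contigs)[0]
                    pos = int(rng.integers(2, reference.length(contig)))
                if (contig, pos) not in used:
                    break
            else:  # pragma: no cover
                continue
            used.add((contig, pos))
            base = reference.base(contig, pos)
            if rng.random() < 0.5:
                rec = MutationRecord(
                    gene_symbol=_gene_symbol(contig, pos),
                    chromosome=contig,
                    start_position=pos,
                    reference_allele=base,
                    alternate_allele="-",
                    variant_classification="Frame_Shift_Del",
                    variant_type="DEL",
                    sample_id=sample,
                )
            else:
                rec = MutationRecord(
                    gene_symbol=_gene_symbol(contig, pos),
                    chromosome=contig,
                    start_position=pos,
                    reference_allele="-",
                    alternate_allele=base,
                    variant_classification="Frame_Shift_Ins",
                    variant_type="INS",
                    sample_id=sample,
                )
            records.append(rec)
            placed_indels += 1
        exposures[sample] = sample_expo
        snv_counts[sample] = n_snv
        indel_counts[sample] = placed_indels
        channel_counts[sample] = chan_counts
    truth = GroundTruth(
        exposures=exposures,
        snv_counts=snv_counts,
        indel_counts=indel_counts,
        channel_counts=channel_counts,
    )
    return records, truth


def simulate_exposure_spectra(
    n_samples: int,
    n_mutations: int,
    catalog: SignatureCatalog,
    seed: int,
    active_signatures: Tuple[int, int] = (2, 4),
    dirichlet_concentration: float = 1.0,
    min_exposure: float = 0.1,
) -> Tuple[List[SampleSpectrum], Dict[str, Dict[str, float]]]:
    """Multinomial spectra drawn directly from signature mixtures.

    A lighter-weight path than full MAF simulation for exercising the
    refitting stage: returns spectra plus true per-sample exposures.
    """
    cfg = SimulationConfig(
        n_samples=n_samples,
        active_signatures=active_signatures,
        dirichlet_concentration=dirichlet_concentration,
        min_exposure=min_exposure,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    spectra = []
    truth: Dict[str, Dict[str, float]] = {}
    for i in range(n_samples):
        sample = f"S{i + 1:04d}"
        expo = _draw_exposures(cfg, catalog, rng)
        mix = np.zeros(len(catalog.channel_labels))
        for s, w in expo.items():
            mix += w * catalog.signature(s)
        counts = rng.multinomial(n_mutations, mix)
        spectra.append(
            SampleSpectrum(sample_id=sample, scheme=catalog.scheme, counts=counts)
        )
        truth[sample] = expo
    return spectra, truth
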