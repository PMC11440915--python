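"""End-to-end orchestration: spectra -> GLM mapping -> refitting -> tables.

``run_pipeline`` composes the stages in analysis order and writes TSV
reports plus a JSON manifest recording the package version, seed and
every threshold that affects the output. Re-running with the same
configuration produces byte-identical outputs: all randomness flows
from the single config seed and nothing time-dependent is written.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from . import __version__
from .channels import SCHEME_CHANNELS, Scheme
from .cohort_stats import gene_alteration_summary, gene_summary_frame, mutation_burden
from .errors import SchemeMismatchError, ValidationError
from .formats_io import ReferenceSequence, read_catalog, read_maf, write_matrix
from .glm_mapper import (
    NO_MAPPING,
    MapperConfig,
    cluster_unmapped,
    map_cohort,
    rank_signatures,
)
from .refit_attribution import (
    RefitConfig,
    call_presence,
    refit_exposures,
    zero_rare_signatures,
)
from .spectrum import (
    SUBSETS,
    SampleSpectrum,
    build_spectra,
    spectra_matrix,
    summarize_substitutions,
)


@dataclass
class PipelineConfig:
    maf: str
    fasta: str
    catalog: str
    out_dir: str
    subset: str = "ALL"
    target_size_mb: float = 50.0
    cluster_k: int = 3
    seed: int = 0
    mapper: MapperConfig = field(default_factory=MapperConfig)
    refit: RefitConfig = field(default_factory=RefitConfig)

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValidationError(f"unknown subset {self.subset!r}")


def spectra_from_frame(df: pd.DataFrame, scheme: Scheme) -> List[SampleSpectrum]:
    """Rebuild spectra from a channels x samples TSV frame."""
    scheme = Scheme(scheme)
    expected = SCHEME_CHANNELS[scheme]
    if set(df.index) != set(expected):
        raise SchemeMismatchError(
            f"matrix channels do not match scheme {scheme.value}"
        )
    df = df.loc[expected]
    return [
        SampleSpectrum(
            sample_id=str(col),
            scheme=scheme,
            counts=df[col].to_numpy().astype(int),
        )
        for col in df.columns
    ]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_maf(config.maf)
    reference = ReferenceSequence.from_fasta(config.fasta)
    catalog = read_catalog(config.catalog, Scheme.SBS96)
    subset = SUBSETS[config.subset]

    spectra = build_spectra(records, reference, Scheme.SBS96, subset)
    X, samples = spectra_matrix(spectra)
    write_matrix(
        X.T, SCHEME_CHANNELS[Scheme.SBS96], samples,
        out / f"spectra_sbs96_{subset.name}.tsv",
    )
    summary = summarize_substitutions(spectra)
    pd.DataFrame(
        {
            "class": list(summary.fractions) + ["Ti", "Tv"],
            "fraction": [round(v, 4) for v in summary.fractions.values()]
            + [round(summary.ti, 4), round(summary.tv, 4)],
        }
    ).to_csv(out / "substitution_summary.tsv", sep="\t", index=False,
             lineterminator="\n")

    assignments = map_cohort(spectra, catalog, config.mapper)
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "best_signature": [a.best for a in assignments],
            "n_significant": [len(a.significant) for a in assignments],
            "significant": [
                ",".join(sorted(a.significant)) for a in assignments
            ],
        }
    ).to_csv(out / "assignments.tsv", sep="\t", index=False, lineterminator="\n")
    rank_signatures(assignments, "all_significant").to_csv(
        out / "ranking_all_significant.tsv", sep="\t", index=False,
        lineterminator="\n",
    )
    rank_signatures(assignments, "best_only").to_csv(
        out / "ranking_best_only.tsv", sep="\t", index=False, lineterminator="\n"
    )

    unmapped = [
        sp
        for sp, a in zip(spectra, assignments)
        if a.best == NO_MAPPING and sp.total > 0
    ]
    if len(unmapped) >= config.cluster_k:
        labels = cluster_unmapped(unmapped, config.cluster_k)
        pd.DataFrame(
            {
                "sample_id": [sp.sample_id for sp in unmapped],
                "cluster": labels,
            }
        ).to_csv(out / "nomapping_clusters.tsv", sep="\t", index=False,
                 lineterminator="\n")

    profiles = [
        refit_exposures(sp, catalog, config.refit)
        for sp in spectra
        if sp.total > 0
    ]
    profiles = zero_rare_signatures(profiles, config.refit)
    profiles = [call_presence(p, config.refit) for p in profiles]
    sig_ids = catalog.signature_ids
    prof_samples = [p.sample_id for p in profiles]
    write_matrix(
        np.array([[p.weights[s] for p in profiles] for s in sig_ids]).round(6),
        sig_ids, prof_samples, out / "exposures.tsv", index_name="Signature",
    )
    write_matrix(
        np.array(
            [[p.attributed_counts[s] for p in profiles] for s in sig_ids]
        ).round(2),
        sig_ids, prof_samples, out / "attributed_counts.tsv",
        index_name="Signature",
    )
    write_matrix(
        np.array(
            [[int(p.present[s]) for p in profiles] for s in sig_ids]
        ),
        sig_ids, prof_samples, out / "presence.tsv", index_name="Signature",
    )

    genes = gene_alteration_summary(records, cohort_size=len(samples))
    gene_summary_frame(genes).to_csv(
        out / "gene_summary.tsv", sep="\t", index=False, lineterminator="\n"
    )
    burden = mutation_burden(records, config.target_size_mb, sample_ids=samples)
    pd.DataFrame(
        {
            "sample_id": list(burden.per_sample) + ["MEAN"],
            "alterations_per_mb": [
                round(v, 4) for v in burden.per_sample.values()
            ]
            + [round(burden.mean, 4)],
        }
    ).to_csv(out / "burden.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "subset": subset.name,
        "target_size_mb": config.target_size_mb,
        "cluster_k": config.cluster_k,
        "mapper": asdict(config.mapper),
        "refit": asdict(config.refit),
        "inputs": {
            "maf": str(config.maf),
            "fasta": str(config.fasta),
            "catalog": str(config.catalog),
        },
        "n_samples": len(samples),
        "n_records": len(records),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
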