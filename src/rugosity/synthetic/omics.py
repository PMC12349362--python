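"""Synthetic RNA-seq count matrices and qPCR Ct tables with known truth.

The count generator emulates an 18-sample bulk design: two genotypes
(M = rugose, G = smooth) x three developmental stages (6, 10, 14 days
post-anthesis) x three biological replicates.  Counts are negative binomial
with gene-wise dispersion; a chosen subset of genes is planted as
differentially expressed between genotypes at a stated log2 fold change, and
the truth record lists those genes for oracle comparisons downstream.

The Ct generator produces target/reference threshold-cycle tables whose
relative expression, recovered by the 2^-ddCt method, equals the configured
log2 ratios exactly when technical noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError

__all__ = [
    "CountsConfig",
    "CountsTruth",
    "generate_counts",
    "generate_ct_table",
]

GENOTYPES = ("M", "G")  # M = rugose, G = smooth
STAGES = (6, 10, 14)  # days post-anthesis


@dataclass(frozen=True)
class CountsConfig:
    """Parameters of the synthetic count matrix."""

    n_genes: int = 2000
    n_de: int = 50
    log2fc_de: float = 2.0
    replicates: int = 3
    dispersion: float = 0.05
    library_size_mean: float = 1.0e6
    gene_length_range_bp: tuple[int, int] = (200, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidParameterError("n_genes must be positive")
        if not 0 <= self.n_de <= self.n_genes:
            raise InvalidParameterError("need 0 <= n_de <= n_genes")
        if self.n_de > 0 and abs(self.log2fc_de) < 1.0:
            raise InvalidParameterError("planted |log2fc_de| must be >= 1")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be positive")
        if self.library_size_mean <= 0:
            raise InvalidParameterError("library_size_mean must be positive")
        lo, hi = self.gene_length_range_bp
        if lo < 1 or hi < lo:
            raise InvalidParameterError("gene_length_range_bp must be a positive interval")


@dataclass(frozen=True)
class CountsTruth:
    """Ground truth of a generated matrix: planted DE genes and their log2 FC (M vs G)."""

    de_genes: tuple[str, ...]
    log2fc: dict[str, float] = field(default_factory=dict)


def _sample_names(config: CountsConfig) -> list[str]:
    return [
        f"{g}{s}_r{r}"
        for g in GENOTYPES
        for s in STAGES
        for r in range(1, config.replicates + 1)
    ]


def generate_counts(config: CountsConfig) -> tuple[pd.DataFrame, pd.Series, CountsTruth]:
    """Draw a counts matrix for the two-genotype, three-stage design.

    Returns ``(counts, gene_lengths, truth)`` where ``counts`` is a gene x
    sample DataFrame of non-negative integers with columns named
    ``<genotype><stage>_r<rep>``, ``gene_lengths`` is the per-gene transcript
    length in bp, and ``truth`` records the planted DE genes.

    Gene relative abundances are log-normal; planted DE genes are drawn from
    at least median abundance so the planted effect is not confounded with
    detection-limit noise.  The fold change is applied to the rugose (M)
    genotype at all stages, alternating sign across the planted genes, and
    per-sample expected counts are renormalised to the library size so the
    matrix behaves like real compositional sequencing data.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"gene{i + 1:05d}" for i in range(config.n_genes)])
    lo, hi = config.gene_length_range_bp
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=config.n_genes), index=genes, name="gene_length_bp"
    )

    abundance = rng.lognormal(mean=2.0, sigma=1.2, size=config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    floor = float(np.median(abundance))
    abundance[de_idx] = np.maximum(abundance[de_idx], floor)
    signs = np.where(np.arange(config.n_de) % 2 == 0, 1.0, -1.0)
    lfc = np.zeros(config.n_genes)
    lfc[de_idx] = config.log2fc_de * signs

    dispersion = config.dispersion * np.exp(rng.normal(0.0, 0.25, size=config.n_genes))

    samples = _sample_names(config)
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, name in enumerate(samples):
        genotype = name[0]
        fold = 2.0 ** lfc if genotype == "M" else np.ones(config.n_genes)
        weights = abundance * fold
        library = config.library_size_mean * rng.uniform(0.85, 1.15)
        mu = library * weights / weights.sum()
        n_param = 1.0 / dispersion
        p_param = n_param / (n_param + mu)
        counts[:, j] = rng.negative_binomial(n_param, p_param)

    frame = pd.DataFrame(counts, index=genes, columns=samples)
    truth = CountsTruth(
        de_genes=tuple(genes[np.sort(de_idx)]),
        log2fc={genes[i]: float(lfc[i]) for i in np.sort(de_idx)},
    )
    return frame, lengths, truth


def generate_ct_table(
    n_genes: int,
    n_samples: int,
    true_log2_ratios: np.ndarray,
    seed: int = 0,
    noise_sd_ct: float = 0.0,
    n_replicates: int = 3,
    reference_gene: str = "UBI",
) -> tuple[pd.DataFrame, str]:
    """Build a Ct table whose 2^-ddCt recovery matches the configured ratios.

    ``true_log2_ratios`` has shape ``(n_genes, n_samples)`` and gives each
    gene's log2 expression relative to the calibrator (sample 1); the
    calibrator column should therefore be zero.  A log2 ratio of +r lowers
    the target Ct by r cycles (one cycle per doubling).  Gaussian technical
    noise of ``noise_sd_ct`` cycles is added independently to each replicate
    measurement.

    Returns ``(table, calibrator_sample)`` with table columns
    ``gene,sample,replicate,ct_target,ct_reference``.
    """
    ratios = np.asarray(true_log2_ratios, dtype=float)
    if ratios.shape != (n_genes, n_samples):
        raise InvalidParameterError(
            f"true_log2_ratios must have shape ({n_genes}, {n_samples}), got {ratios.shape}"
        )
    if not np.all(np.isfinite(ratios)):
        raise InvalidParameterError("true_log2_ratios must be finite")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if noise_sd_ct < 0:
        raise InvalidParameterError("noise_sd_ct must be non-negative")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:03d}" for i in range(n_genes)]
    sample_names = [f"S{j + 1}" for j in range(n_samples)]
    calibrator = sample_names[0]
    ct_reference_base = 20.0
    # per-gene baseline delta-Ct (target minus reference) in the calibrator
    baseline = rng.uniform(2.0, 8.0, size=n_genes)

    rows = []
    for i, gene in enumerate(genes):
        for j, sample in enumerate(sample_names):
            dct_true = baseline[i] - (ratios[i, j] - ratios[i, 0])
            for rep in range(1, n_replicates + 1):
                noise_t = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                noise_r = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "replicate": rep,
                        "ct_target": ct_reference_base + dct_true + noise_t,
                        "ct_reference": ct_reference_base + noise_r,
                    }
                )
    return pd.DataFrame(rows), calibrator
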