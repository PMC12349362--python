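"""Operational transcriptome computations for the rugosity study design.

This module implements the bookkeeping layer of a bulk RNA-seq comparison
between rugose (M) and smooth (G) fruit at three developmental stages:
FPKM quantification, a simple differential-expression test, Benjamini-
Hochberg FDR control, the |FC| >= 2 & FDR < 0.01 DEG filter, standardized
group-mean expression profiles, K-means co-expression modules, sample PCA,
and 2^-ddCt relative quantification for qPCR validation.

The differential-expression test is deliberately lightweight: median-of-
ratios library-size normalisation followed by a per-gene two-sample t-test
on log2(normalised + 1).  It is a stand-in whose contract is calibration
under the null and power on planted effects, not numerical agreement with
negative-binomial GLM engines such as edgeR or DESeq2.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import (
    DegenerateSampleError,
    InsufficientReplicationError,
    InvalidParameterError,
    MeasurementWarning,
)

__all__ = [
    "ExpressionMatrix",
    "DEGSet",
    "ClusterAssignment",
    "CtTable",
    "fpkm",
    "median_of_ratios_factors",
    "de_test",
    "bh_fdr",
    "filter_degs",
    "zscore_profiles",
    "kmeans_modules",
    "pca_samples",
    "delta_delta_ct",
]

_SAMPLE_RE = re.compile(r"^([MG])(\d+)_r(\d+)$")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with gene lengths and sample metadata.

    ``values`` holds counts (non-negative integers) or FPKM depending on
    ``kind``.  Sample metadata (genotype M/G, stage in DPA, replicate) is
    parsed from column names of the form ``<genotype><stage>_r<rep>``.
    """

    values: pd.DataFrame
    gene_length_bp: pd.Series
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fpkm"):
            raise InvalidParameterError(f"kind must be 'counts' or 'fpkm', got {self.kind!r}")
        if not self.values.index.equals(self.gene_length_bp.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.values.index)
        if self.gene_length_bp.isna().any():
            raise InvalidParameterError("every gene needs a length")
        if (self.gene_length_bp <= 0).any():
            raise InvalidParameterError("gene lengths must be positive")
        arr = self.values.to_numpy()
        if np.any(arr < 0):
            raise InvalidParameterError("expression values must be non-negative")
        if self.kind == "counts" and not np.allclose(arr, np.round(arr)):
            raise InvalidParameterError("counts must be integers")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def metadata(self) -> pd.DataFrame:
        """Per-sample genotype / stage / replicate parsed from column names."""
        rows = []
        for name in self.samples:
            m = _SAMPLE_RE.match(name)
            if m is None:
                raise InvalidParameterError(
                    f"sample name {name!r} does not match '<genotype><stage>_r<rep>'"
                )
            rows.append(
                {
                    "sample": name,
                    "genotype": m.group(1),
                    "stage": int(m.group(2)),
                    "replicate": int(m.group(3)),
                }
            )
        return pd.DataFrame(rows).set_index("sample")

    def samples_matching(self, genotype: str | None = None, stage: int | None = None) -> list[str]:
        meta = self.metadata()
        mask = pd.Series(True, index=meta.index)
        if genotype is not None:
            mask &= meta["genotype"] == genotype
        if stage is not None:
            mask &= meta["stage"] == stage
        return list(meta.index[mask])

    @classmethod
    def from_tsv(cls, path, kind: str = "counts") -> "ExpressionMatrix":
        """Read the TSV dialect: gene id, gene_length_bp, then sample columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "gene_length_bp" not in df.columns:
            raise InvalidParameterError("counts TSV needs a gene_length_bp column")
        lengths = df["gene_length_bp"]
        values = df.drop(columns=["gene_length_bp"])
        return cls(values=values, gene_length_bp=lengths, kind=kind)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_length_bp", self.gene_length_bp)
        out.to_csv(Path(path), sep="\t", index_label="gene")


@dataclass(frozen=True)
class DEGSet:
    """Per-gene DE statistics with the threshold filter applied."""

    table: pd.DataFrame  # columns: log2fc, p, q, pass
    fc_threshold: float
    fdr_threshold: float

    @property
    def passing(self) -> pd.Index:
        return self.table.index[self.table["pass"]]


@dataclass(frozen=True)
class ClusterAssignment:
    """K-means co-expression module assignment on standardized profiles."""

    modules: pd.Series  # gene -> module id (1-based)
    module_profiles: pd.DataFrame  # module x group mean standardized profile
    k: int
    seed: int
    inertia: float


@dataclass(frozen=True)
class CtTable:
    """qPCR threshold-cycle table for targets and a reference gene.

    ``data`` columns: ``gene,sample,replicate,ct_target,ct_reference``.
    """

    data: pd.DataFrame
    reference_gene: str = "UBI"
    calibrator_sample: str | None = None

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct_target", "ct_reference"}
        if not required.issubset(self.data.columns):
            raise InvalidParameterError(f"Ct table needs columns {sorted(required)}")
        ct = self.data[["ct_target", "ct_reference"]].to_numpy(float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise InvalidParameterError("Ct values must be finite and positive")
        if self.calibrator_sample is not None and (
            self.calibrator_sample not in set(self.data["sample"])
        ):
            raise InvalidParameterError(
                f"calibrator sample {self.calibrator_sample!r} not present"
            )


def fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped reads.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s])`` where
    ``total[s]`` is the column sum of the count matrix (the in-matrix proxy
    for the aligner's mapped-read total).
    """
    if matrix.kind != "counts":
        raise InvalidParameterError("fpkm() expects a counts matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise DegenerateSampleError(f"sample(s) with zero total counts: {list(zero.index)}")
    values = matrix.values * 1.0e9
    values = values.div(matrix.gene_length_bp, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=values, gene_length_bp=matrix.gene_length_bp, kind="fpkm")


def median_of_ratios_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median ratio to the geometric reference gene."""
    arr = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.all(np.isfinite(log_arr), axis=1)
    if not usable.any():
        raise DegenerateSampleError("no gene has positive counts in every sample")
    ref = log_arr[usable].mean(axis=1)
    factors = np.exp(np.median(log_arr[usable] - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def de_test(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    Library sizes are equalised with median-of-ratios factors computed on the
    contrast samples; the per-gene statistic is a pooled two-sample t-test on
    ``log2(normalised + pseudocount)`` and the reported effect is
    ``log2((mean_a + pc) / (mean_b + pc))`` on the normalised scale.

    Returns a DataFrame indexed by gene with columns ``log2fc`` and ``p``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicationError("each group needs at least two replicates")
    missing = (set(group_a) | set(group_b)) - set(matrix.samples)
    if missing:
        raise InvalidParameterError(f"unknown sample(s): {sorted(missing)}")
    if matrix.kind != "counts":
        raise InvalidParameterError("de_test expects a counts matrix")
    sub = matrix.values[group_a + group_b].astype(float)
    factors = median_of_ratios_factors(sub)
    norm = sub.div(factors, axis=1)
    log_norm = np.log2(norm + pseudocount)
    a = log_norm[group_a].to_numpy()
    b = log_norm[group_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
    # genes constant in both groups have undefined t; no evidence of change
    p = np.where(np.isfinite(p), p, 1.0)
    mean_a = norm[group_a].mean(axis=1).to_numpy()
    mean_b = norm[group_b].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=matrix.genes)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q[i] = min over ranks j >= rank(i) of p[(j)] * m / j``, capped at 1;
    monotone non-decreasing in the raw p ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def filter_degs(
    stats_table: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> DEGSet:
    """Apply the DEG criteria: ``|fold change| >= fc`` (inclusive) and ``FDR < fdr`` (strict).

    ``stats_table`` must carry ``log2fc`` and either ``q`` or raw ``p`` (in
    which case BH adjustment is applied here).
    """
    if fc_threshold < 1:
        raise InvalidParameterError("fc_threshold must be >= 1")
    if not 0 < fdr_threshold <= 1:
        raise InvalidParameterError("fdr_threshold must be in (0, 1]")
    if "log2fc" not in stats_table.columns:
        raise InvalidParameterError("stats table needs a log2fc column")
    table = stats_table.copy()
    if "q" not in table.columns:
        if "p" not in table.columns:
            raise InvalidParameterError("stats table needs a q or p column")
        table["q"] = bh_fdr(table["p"].to_numpy())
    log2_threshold = np.log2(fc_threshold)
    table["pass"] = (np.abs(table["log2fc"]) >= log2_threshold) & (table["q"] < fdr_threshold)
    return DEGSet(table=table, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold)


def zscore_profiles(
    matrix: ExpressionMatrix,
    group_order: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Standardized per-gene profiles of group-mean expression.

    Expression is averaged over replicates within each (genotype, stage)
    group, then each gene's profile is centred to mean 0 and scaled to
    standard deviation 1 (population SD).  Genes with a constant profile are
    dropped with a warning.  Group columns are ordered G then M, by stage,
    unless ``group_order`` is given.
    """
    meta = matrix.metadata()
    if group_order is None:
        group_order = sorted(
            {(g, s) for g, s in zip(meta["genotype"], meta["stage"])},
            key=lambda t: (t[0], t[1]),
        )
    if len(group_order) < 2:
        raise InvalidParameterError("need at least two sample groups")
    cols = {}
    for genotype, stage in group_order:
        samples = matrix.samples_matching(genotype=genotype, stage=stage)
        if not samples:
            raise InvalidParameterError(f"no samples for group {genotype}{stage}")
        cols[f"{genotype}{stage}"] = matrix.values[samples].mean(axis=1)
    profiles = pd.DataFrame(cols)
    sd = profiles.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} gene(s) with constant profiles",
            MeasurementWarning,
            stacklevel=2,
        )
        profiles = profiles.loc[~constant]
        sd = sd.loc[~constant]
    return profiles.sub(profiles.mean(axis=1), axis=0).div(sd, axis=0)


def kmeans_modules(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 25,
) -> ClusterAssignment:
    """K-means co-expression modules on standardized profiles.

    Euclidean K-means with ``n_init`` restarts; deterministic for a fixed
    seed.  Module ids are 1-based; each module's reported profile is the mean
    of its members' standardized profiles.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if k > len(profiles):
        raise InvalidParameterError(f"k={k} exceeds the {len(profiles)} available genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    modules = pd.Series(labels + 1, index=profiles.index, name="module")
    module_profiles = profiles.groupby(modules).mean()
    module_profiles.index.name = "module"
    return ClusterAssignment(
        modules=modules,
        module_profiles=module_profiles,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def pca_samples(matrix: ExpressionMatrix, n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples on log2(FPKM + 1).

    Genes are centred (features); returns ``(coordinates, explained_variance_fractions)``
    with samples as rows and columns ``PC1, PC2, ...``.
    """
    if len(matrix.samples) < 3:
        raise InvalidParameterError("PCA needs at least 3 samples")
    if matrix.kind != "fpkm":
        raise InvalidParameterError("pca_samples expects an FPKM matrix")
    x = np.log2(matrix.values.to_numpy(float) + 1.0).T  # samples x genes
    n_comp = n_components or min(len(matrix.samples) - 1, 10)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(
        coords,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, pca.explained_variance_ratio_.copy()


def delta_delta_ct(ct: CtTable) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged on the Ct scale first; then for each
    gene and sample ``dCt = Ct_target - Ct_reference``,
    ``ddCt = dCt(sample) - dCt(calibrator)`` and the relative expression is
    ``2**(-ddCt)``.  Returns a gene x sample DataFrame; the calibrator column
    is identically 1.
    """
    if ct.calibrator_sample is None:
        raise InvalidParameterError("CtTable needs a designated calibrator sample")
    mean_ct = (
        ct.data.groupby(["gene", "sample"])[["ct_target", "ct_reference"]].mean().reset_index()
    )
    dct = mean_ct.assign(dct=mean_ct["ct_target"] - mean_ct["ct_reference"])
    wide = dct.pivot(index="gene", columns="sample", values="dct")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any(axis=0)]
        raise InvalidParameterError(
            f"missing target/reference Ct for sample(s): {list(bad)}"
        )
    if ct.calibrator_sample not in wide.columns:
        raise InvalidParameterError(f"calibrator {ct.calibrator_sample!r} missing from table")
    ddct = wide.sub(wide[ct.calibrator_sample], axis=0)
    rel = np.power(2.0, -ddct)
    rel.columns.name = None
    return rel
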