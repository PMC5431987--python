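"""Count integration, filtering and normalization.

The stages mirror a standard RNA-seq co-expression preprocessing chain:
annotation/count integration with conservative merge rules, a mean-count
filter, within-sample full-quantile normalization over covariate strata
(%GC, then gene length), TMM between-sample scaling, log2 transform,
a CPM-based low-expression filter, and an ANOVA+PCA denoising step that
strips systematic structure not aligned with the experimental design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import CONVENTIONAL_CHROMOSOMES

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


class IntegrationError(PreprocessError):
    pass


@dataclass
class CountMatrix:
    """Genes x samples expression matrix with a layer tag.

    ``values`` rows are gene ids, columns sample ids; ``conditions`` maps
    sample -> condition label; ``layer`` names the current scale
    (``raw | fq | tmm | cpm | log2 | denoised``). The raw layer is
    integer-valued; all layers of one dataset share dimensions and ids.
    """

    values: pd.DataFrame
    conditions: pd.Series
    layer: str = "raw"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise PreprocessError("gene identifiers must be unique")
        if not self.values.columns.is_unique:
            raise PreprocessError("sample identifiers must be unique")
        self.conditions = pd.Series(self.conditions)
        missing = self.values.columns.difference(self.conditions.index)
        if len(missing):
            raise PreprocessError(f"samples without condition labels: {list(missing)[:5]}")
        self.conditions = self.conditions.loc[self.values.columns]
        # counts-scale layers are non-negative; log2/denoised may dip below 0
        if self.layer in ("raw", "fq", "tmm", "cpm") and (self.values.to_numpy() < 0).any():
            raise PreprocessError("negative counts")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, layer: str) -> "CountMatrix":
        return CountMatrix(values=values, conditions=self.conditions, layer=layer)

    def select_genes(self, genes: Iterable[str]) -> "CountMatrix":
        return self.with_values(self.values.loc[list(genes)], self.layer)

    def select_samples(self, samples: Iterable[str]) -> "CountMatrix":
        sub = self.values[list(samples)]
        return CountMatrix(values=sub, conditions=self.conditions.loc[sub.columns], layer=self.layer)

    def condition_samples(self, condition: str) -> pd.Index:
        return self.conditions.index[self.conditions == condition]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, layer: str = "raw") -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        conditions = sheet.set_index("sample")["condition"]
        return cls(values=values, conditions=conditions, layer=layer)


def load_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=False)


# ---------------------------------------------------------------------------
# Integration

def integrate(
    ann_raw: pd.DataFrame, cm: CountMatrix
) -> tuple[CountMatrix, pd.DataFrame]:
    """Merge annotation and counts under conservative filter rules.

    Annotation records with missing identifiers or symbols, or on
    non-conventional chromosomes (anything outside 1..22, X, Y), are dropped.
    When several candidate records share a gene_id they are kept only if both
    symbol namespaces agree, in which case the candidate with the lowest %GC
    wins; conflicting candidates are dropped entirely (reported as a warning
    count). The output is restricted to genes present in both tables; count
    values are untouched.
    """
    ann = ann_raw.copy()
    for col in ("gene_id", "symbol", "alt_symbol"):
        ann = ann[ann[col].notna() & (ann[col].astype(str).str.len() > 0)]
    ann = ann[ann["chromosome"].astype(str).isin(CONVENTIONAL_CHROMOSOMES)]
    ann = ann.reset_index(drop=True)

    resolved = []
    n_unresolvable = 0
    for gid, grp in ann.groupby("gene_id", sort=False):
        if len(grp) == 1:
            resolved.append(grp.iloc[0])
        elif grp["symbol"].nunique() == 1 and grp["alt_symbol"].nunique() == 1:
            resolved.append(grp.iloc[int(np.argmin(grp["gc"].to_numpy()))])
        else:
            n_unresolvable += 1
    if n_unresolvable:
        logger.warning("integrate: dropped %d unresolvable duplicate gene ids", n_unresolvable)
    if not resolved:
        raise IntegrationError("no annotation records survive the integration filters")
    ann_clean = pd.DataFrame(resolved).reset_index(drop=True)

    keep = cm.genes.intersection(pd.Index(ann_clean["gene_id"]))
    if keep.empty:
        raise IntegrationError("annotation and count matrix share no genes")
    keep = cm.genes[cm.genes.isin(keep)]  # preserve count-matrix order
    ann_clean = ann_clean.set_index("gene_id").loc[keep].reset_index()
    ann_clean.attrs["n_unresolvable"] = n_unresolvable
    return cm.select_genes(keep), ann_clean


# ---------------------------------------------------------------------------
# Count filters

def filter_mean_count(cm: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Keep genes whose mean count across all samples is >= ``min_mean``."""
    keep = cm.values.mean(axis=1) >= min_mean
    if not keep.any():
        raise PreprocessError("mean-count filter removed every gene")
    return cm.with_values(cm.values.loc[keep], cm.layer)


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: value * 1e6 / column sum. No pseudo-count."""
    colsum = cm.values.sum(axis=0)
    if (colsum == 0).any():
        bad = list(colsum.index[colsum == 0])
        raise PreprocessError(f"zero library size for samples {bad[:5]}")
    return cm.values * 1e6 / colsum


def filter_cpm(cm: CountMatrix, min_cpm: float = 10.0) -> CountMatrix:
    """Keep genes whose mean CPM across samples is >= ``min_cpm``."""
    keep = cpm(cm).mean(axis=1) >= min_cpm
    if not keep.any():
        raise PreprocessError("CPM filter removed every gene")
    return cm.with_values(cm.values.loc[keep], cm.layer)


# ---------------------------------------------------------------------------
# Within-sample full-quantile normalization over covariate strata

def within_fq_normalize(
    cm: CountMatrix, covariate: pd.Series | np.ndarray, n_bins: int = 10
) -> CountMatrix:
    """Full-quantile normalize each sample across covariate strata.

    Genes are split into ``n_bins`` equal-size strata by the covariate (e.g.
    %GC or gene length). Per sample, each stratum's count distribution is
    quantile-mapped onto a reference distribution defined as the median, at
    each quantile rank, over the strata of that sample. The map is monotone
    within each stratum, so within-stratum rank order is preserved. With a
    single stratum the output equals the input.
    """
    cov = np.asarray(pd.Series(covariate).loc[cm.genes] if isinstance(covariate, pd.Series) else covariate, dtype=float)
    if cov.shape[0] != cm.n_genes:
        raise PreprocessError("covariate length does not match gene count")
    if not np.isfinite(cov).all():
        raise PreprocessError("covariate contains non-finite values")
    if n_bins > cm.n_genes:
        raise PreprocessError("n_bins exceeds number of genes")

    order = np.argsort(cov, kind="stable")
    strata = [s for s in np.array_split(order, n_bins) if s.size]
    grid_size = max(s.size for s in strata)
    p_grid = np.linspace(0.0, 1.0, grid_size) if grid_size > 1 else np.array([0.0])

    X = cm.values.to_numpy(dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        qfuncs = np.empty((len(strata), p_grid.size))
        for s, idx in enumerate(strata):
            qfuncs[s] = np.quantile(col[idx], p_grid)
        ref = np.median(qfuncs, axis=0)
        for idx in strata:
            m = idx.size
            ranks = np.empty(m, dtype=np.int64)
            ranks[np.argsort(col[idx], kind="stable")] = np.arange(m)
            p = ranks / (m - 1) if m > 1 else np.array([0.5])
            out[idx, j] = np.interp(p, p_grid, ref)
    values = pd.DataFrame(out, index=cm.genes, columns=cm.samples)
    return cm.with_values(values, "fq")


# ---------------------------------------------------------------------------
# TMM between-sample normalization

def _upper_quartiles(values: pd.DataFrame) -> pd.Series:
    return values.quantile(0.75, axis=0)


def choose_tmm_reference(cm: CountMatrix) -> str:
    """Sample whose upper-quartile count is closest to the mean upper quartile."""
    uq = _upper_quartiles(cm.values)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    cm: CountMatrix,
    ref: str | None = None,
    trim_lfc: float = 0.30,
    trim_abund: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factor per sample.

    For each sample against the reference, genes with a zero count in either
    sample are excluded; per-gene log2 ratio ``M`` and average log2 abundance
    ``A`` are computed on raw counts, the upper and lower ``trim_lfc`` /
    ``trim_abund`` tails of M and A are discarded, and the remaining M values
    are averaged with inverse approximate-asymptotic-variance weights
    (delta-method on each library's proportion scale). The factor is
    ``2**weighted_mean_M``; factors are rescaled to geometric mean 1. A sample
    identical to the reference gets factor 1; an empty post-trim set falls
    back to factor 1 with a warning.
    """
    if cm.n_samples < 2:
        raise PreprocessError("TMM requires at least 2 samples")
    ref = ref if ref is not None else choose_tmm_reference(cm)
    y_ref = cm.values[ref].to_numpy(dtype=float)
    n_ref = y_ref.sum()
    factors = {}
    for s in cm.samples:
        y = cm.values[s].to_numpy(dtype=float)
        if s == ref:
            factors[s] = 1.0
            continue
        ok = (y > 0) & (y_ref > 0)
        if not ok.any():
            logger.warning("tmm_factors: no shared expressed genes for %s; factor 1", s)
            factors[s] = 1.0
            continue
        ys, yr = y[ok], y_ref[ok]
        n_s = y.sum()
        M = np.log2(ys) - np.log2(yr)
        A = 0.5 * (np.log2(ys) + np.log2(yr))
        n = M.size
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (
            (rM > n * trim_lfc)
            & (rM <= n * (1 - trim_lfc))
            & (rA > n * trim_abund)
            & (rA <= n * (1 - trim_abund))
        )
        if not keep.any():
            logger.warning("tmm_factors: empty doubly-trimmed set for %s; factor 1", s)
            factors[s] = 1.0
            continue
        var = (n_s - ys[keep]) / (n_s * ys[keep]) + (n_ref - yr[keep]) / (n_ref * yr[keep])
        var = np.where(var > 0, var, np.nan)
        w = 1.0 / var
        good = np.isfinite(w)
        if not good.any():
            factors[s] = 1.0
            continue
        factors[s] = float(2.0 ** (np.sum(w[good] * M[keep][good]) / np.sum(w[good])))
    f = pd.Series(factors).loc[cm.samples]
    f /= np.exp(np.mean(np.log(f)))
    return f.rename("tmm_factor")


def tmm_normalize(cm: CountMatrix, factors: pd.Series | None = None) -> CountMatrix:
    """Divide each sample by its TMM scale factor."""
    f = tmm_factors(cm) if factors is None else factors
    return cm.with_values(cm.values / f, "tmm")


# ---------------------------------------------------------------------------
# log2 and ARSyN-style denoising

def log2_transform(cm: CountMatrix, pseudocount: float = 1.0) -> CountMatrix:
    return cm.with_values(np.log2(cm.values + pseudocount), "log2")


def _truncated_svd_signal(mat: np.ndarray, var_explained: float) -> np.ndarray:
    """Reconstruction from the leading components reaching var_explained.

    Rows are gene-centered before the SVD; at least one component is kept.
    """
    row_means = mat.mean(axis=1, keepdims=True)
    A = mat - row_means
    if not np.any(A):
        return mat.copy()
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, var_explained) + 1)
    k = min(max(k, 1), s.size)
    return (U[:, :k] * s[:k]) @ Vt[:k] + row_means


def arsyn_denoise(
    cm: CountMatrix,
    conditions: pd.Series | None = None,
    var_explained: float = 0.75,
) -> CountMatrix:
    """ANOVA + per-term PCA denoising of a log2 expression matrix.

    The matrix is split into the condition-mean (design) part plus the
    residual. Each part is reconstructed from the leading principal
    components that reach ``var_explained`` cumulative variance; the design
    part's reconstruction error and the residual part's reconstruction
    (systematic, non-design structure) are subtracted from the input. If the
    residual is zero the output equals the input.
    """
    cond = cm.conditions if conditions is None else pd.Series(conditions).loc[cm.samples]
    counts = cond.value_counts()
    if (counts < 2).any():
        raise PreprocessError("arsyn_denoise requires >=2 samples per condition")
    X = cm.values.to_numpy(dtype=float)
    M = np.empty_like(X)
    for c in counts.index:
        cols = (cond == c).to_numpy()
        M[:, cols] = X[:, cols].mean(axis=1, keepdims=True)
    R = X - M

    M_signal = _truncated_svd_signal(M, var_explained)
    denoised = X - (M - M_signal)
    if np.any(R):
        R_signal = _truncated_svd_signal(R, var_explained)
        denoised = denoised - R_signal
    values = pd.DataFrame(denoised, index=cm.genes, columns=cm.samples)
    return cm.with_values(values, "denoised")


# ---------------------------------------------------------------------------
# Diagnostics

def gc_bias_slope(
    cm: CountMatrix, gc: pd.Series, n_bins: int = 10
) -> tuple[float, float]:
    """Slope (and its standard error) of binned mean log2 count on %GC.

    A simple bias-trend diagnostic: genes are binned into equal-size %GC
    strata; the per-bin mean log2(count+1), averaged over samples, is
    regressed on the bin-mean %GC.
    """
    gc = pd.Series(gc).loc[cm.genes].to_numpy(dtype=float)
    order = np.argsort(gc, kind="stable")
    logx = np.log2(cm.values.to_numpy(dtype=float) + 1).mean(axis=1)
    xs, ys = [], []
    for idx in np.array_split(order, n_bins):
        xs.append(gc[idx].mean())
        ys.append(logx[idx].mean())
    xs, ys = np.asarray(xs), np.asarray(ys)
    xc = xs - xs.mean()
    slope = float(np.sum(xc * ys) / np.sum(xc**2))
    resid = ys - ys.mean() - slope * xc
    dof = max(len(xs) - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(xc**2)))
    return slope, se
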