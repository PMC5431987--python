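"""Gene-wise two-group linear models with empirical-Bayes variance moderation.

Each gene g is modelled as  y_gj = mu_g + alpha_g,i + eps_gj  with condition
effect alpha and Gaussian error; the contrast of interest is the tumour-minus-
normal difference of condition means on the log2 scale (log2 fold change).
Residual variances are shrunk towards a common prior by the standard
moment-matching empirical-Bayes scheme: the prior degrees of freedom d0 and
prior variance s0^2 are fitted to the observed distribution of log sample
variances (a scaled F under the hierarchical model), giving the posterior

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)

and a moderated t statistic with d0 + d degrees of freedom. P-values are
adjusted by the Benjamini-Hochberg step-up procedure, and genes are flagged
differentially expressed when FDR and |log2FC| pass their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


class DiffExprError(ValueError):
    pass


@dataclass
class DEResult:
    """Per-gene differential-expression table plus the moderation prior.

    ``table`` columns: ``mean_<cond>`` per condition, ``log2fc``, ``s2``
    (residual variance, ``df`` degrees of freedom each), and after
    :func:`moderate`: ``s2_post``, ``t``, ``p``, ``fdr`` and after
    :func:`select_degs`: ``is_deg``.
    """

    table: pd.DataFrame
    conditions: tuple[str, str]  # (reference, treatment); log2fc = treatment - reference
    n_per_condition: dict = field(default_factory=dict)
    d0: float | None = None
    s02: float | None = None

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        cols = {
            "log2fc": "Log_2 FC",
            "p": "p-value",
            "fdr": "False Discovery Rate",
            "is_deg": "is_deg",
        }
        out = self.table.rename(columns=cols)
        out.to_csv(path, sep="\t", index_label="gene_id")


def fit_gene_models(cm, reference: str = "healthy", treatment: str = "cancer") -> DEResult:
    """Ordinary least squares of the two-group model for every gene.

    log2FC is the treatment-minus-reference difference of condition means;
    s2 is the pooled residual mean square with n - 2 degrees of freedom.
    Expects a log2-scale (typically denoised) layer.
    """
    cond = cm.conditions
    cols_ref = cm.condition_samples(reference)
    cols_trt = cm.condition_samples(treatment)
    if len(cols_ref) < 2 or len(cols_trt) < 2:
        raise DiffExprError("each condition needs at least 2 samples")
    Xr = cm.values[cols_ref].to_numpy(dtype=float)
    Xt = cm.values[cols_trt].to_numpy(dtype=float)
    n1, n2 = Xr.shape[1], Xt.shape[1]
    mean_r = Xr.mean(axis=1)
    mean_t = Xt.mean(axis=1)
    rss = ((Xr - mean_r[:, None]) ** 2).sum(axis=1) + ((Xt - mean_t[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    table = pd.DataFrame(
        {
            f"mean_{reference}": mean_r,
            f"mean_{treatment}": mean_t,
            "log2fc": mean_t - mean_r,
            "s2": rss / df,
            "df": df,
        },
        index=cm.genes,
    )
    return DEResult(
        table=table,
        conditions=(reference, treatment),
        n_per_condition={reference: n1, treatment: n2},
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Under the hierarchical model, z = log(s2) has mean
    log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2) and extra
    variance trigamma(d0/2) beyond trigamma(d/2); inverting the trigamma gives
    d0, then s0^2 follows from the mean. Infinite d0 (no excess dispersion)
    collapses all variances onto s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DiffExprError("not enough positive residual variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def squeeze_variance(s2: np.ndarray, df: int, d0: float, s02: float) -> np.ndarray:
    """Posterior variance (d0*s02 + df*s2) / (d0 + df); d0 = inf gives s02."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    if d0 == 0:
        return s2.copy()
    return (d0 * s02 + df * s2) / (d0 + df)


def moderate(de: DEResult, min_genes: int = 10) -> DEResult:
    """Empirical-Bayes moderation of gene variances and the moderated t test.

    Requires at least ``min_genes`` genes with positive residual variance;
    if every variance is zero the unmoderated t statistic is used (with a
    warning). Two-sided p-values use a t distribution with d0 + d degrees of
    freedom.
    """
    t0 = de.table
    s2 = t0["s2"].to_numpy()
    df = int(t0["df"].iloc[0])
    n1, n2 = (de.n_per_condition[c] for c in de.conditions)
    se_scale = 1.0 / n1 + 1.0 / n2
    if (s2 > 0).sum() >= min_genes:
        d0, s02 = estimate_prior(s2, df)
        s2_post = squeeze_variance(s2, df, d0, s02)
        df_total = d0 + df
    else:
        logger.warning("moderate: degenerate variances; falling back to unmoderated t")
        d0, s02 = 0.0, float("nan")
        s2_post = s2.copy()
        df_total = df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t0["log2fc"].to_numpy() / np.sqrt(s2_post * se_scale)
    dist_df = df_total if np.isfinite(df_total) else np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df=dist_df)
    p = np.where(np.isnan(p), 1.0, p)
    table = t0.assign(s2_post=s2_post, t=t, p=p, fdr=bh_adjust(p))
    return DEResult(
        table=table,
        conditions=de.conditions,
        n_per_condition=de.n_per_condition,
        d0=float(d0) if np.isfinite(d0) else np.inf,
        s02=s02,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    q_(i) = min_{j >= i} ( p_(j) * n / j ) for the ascending order statistics;
    ties share the adjusted value of their rank position.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DiffExprError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_degs(
    de: DEResult, fdr_max: float = 1e-5, lfc_min: float = 1.0
) -> tuple[pd.Index, float]:
    """Flag differentially expressed genes and the expected false count.

    A gene is a DEG when FDR < ``fdr_max`` and |log2FC| > ``lfc_min``. The
    expected number of genes passing the FDR threshold by chance alone is
    ``n_tested * fdr_max`` (returned alongside). Mutates ``de.table`` by
    adding the ``is_deg`` column.
    """
    if "fdr" not in de.table:
        raise DiffExprError("run moderate() before select_degs()")
    flag = (de.table["fdr"] < fdr_max) & (de.table["log2fc"].abs() > lfc_min)
    de.table["is_deg"] = flag
    return de.table.index[flag], expected_false_degs(len(de.table), fdr_max)


def expected_false_degs(n_tested: int, fdr_max: float) -> float:
    """Expected count of genes passing the FDR cut by chance: n * fdr_max."""
    return float(n_tested) * float(fdr_max)
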