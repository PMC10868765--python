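"""Count filtering, TMM normalization, log-CPM and moderated-t differential
expression.

The normalization follows the trimmed-mean-of-M-values (TMM) procedure used
throughout bulk RNA-seq: per-sample scale factors are the weighted trimmed
mean of gene-wise log-ratios against a reference sample, so that composition
differences (a few very high-count genes) do not masquerade as depth
differences.  Differential expression uses an empirical-Bayes moderated t on
log-CPM values: gene-wise sample variances are shrunk toward a common prior
estimated from the gene-wise variance distribution, which stabilizes
denominators for genes with few samples.  Precision weights per observation
(the voom approach) are deliberately not applied; moderation acts on log-CPM
directly (the trend-free "limma-trend"-style simplification) — downstream
stages consume p-value ranks and top-k sets, which are robust to this choice.
A ``weights`` hook is left in the interface for callers who need it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import CountMatrix

logger = logging.getLogger("nrf2screen")


@dataclass
class NormalizedMatrix:
    """log2-CPM (or proteomic abundance) values, genes x samples."""

    values: pd.DataFrame
    norm_factors: pd.Series
    mode: str = "rnaseq"  # or "proteomic"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite normalized values")
        if self.mode == "rnaseq":
            nf = self.norm_factors.to_numpy()
            if (nf <= 0).any():
                raise ValueError("norm factors must be positive")
            gm = np.exp(np.mean(np.log(nf)))
            if abs(gm - 1.0) > 1e-8:
                raise ValueError("rnaseq norm factors must have geometric mean 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    min_fraction: float = 0.2,
) -> CountMatrix:
    """Drop weakly expressed genes before normalization.

    A gene is kept iff its CPM is at least ``cpm_threshold`` in at least
    ``min_fraction`` of samples.  The pooled log-CPM skewness of the retained
    genes is logged as a diagnostic: heavy low-count tails pull the pooled
    distribution away from the roughly Gaussian shape the moderated-t model
    assumes, and this filter is the stand-in rule used to restore it.
    """
    if cpm_threshold <= 0 or min_fraction <= 0:
        raise ValueError("thresholds must be > 0")
    mat = counts.counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero library size")
    cpm = mat / libsize * 1e6
    keep = (cpm >= cpm_threshold).mean(axis=1) >= min_fraction
    if not keep.any():
        raise ValueError("all genes removed by the low-expression filter")
    out = counts.counts.loc[keep]
    retained = np.log2(cpm[keep] + 0.5)
    logger.info(
        "low-expression filter: kept %d/%d genes; pooled log-CPM skewness %.3f",
        keep.sum(), len(keep), stats.skew(retained.ravel()),
    )
    return CountMatrix(out.copy())


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one observation column against the reference column.

    Genes with a zero count in either column are excluded.  M (log-ratio) and
    A (mean log abundance) values are doubly trimmed — the most extreme
    ``trim_m`` fraction of M on each side and ``trim_a`` of A — and the
    remaining M values are averaged with inverse asymptotic-variance weights
    (the delta-method binomial variance of a log ratio).
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok], ref[ok]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic variance of M
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:  # columns proportional: no composition bias
        return 1.0

    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix,
    ref_policy: str = "upper_quartile",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    ``ref_policy``: ``"upper_quartile"`` picks as reference the sample whose
    75th CPM percentile is closest to the mean across samples (the standard
    heuristic); ``"first"`` uses the first column.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.counts.columns[libsize == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    if ref_policy == "upper_quartile":
        uq = np.array(
            [np.quantile(col[col > 0] / n, 0.75) if (col > 0).any() else 0.0
             for col, n in zip(mat.T, libsize)]
        )
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    elif ref_policy == "first":
        ref_idx = 0
    else:
        raise ValueError(f"unknown ref_policy {ref_policy!r}")

    ref = mat[:, ref_idx]
    factors = np.array(
        [_tmm_pair(mat[:, j], ref, trim_m, trim_a) for j in range(mat.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="tmm_factor")


def log_cpm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million on effective (TMM-scaled) library sizes.

    value_gs = log2( (count_gs + prior) / (libsize_s * factor_s + 2*prior) * 1e6 )
    """
    mat = counts.counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if factors is None:
        factors = pd.Series(1.0, index=counts.counts.columns)
    f = factors.reindex(counts.counts.columns).to_numpy(dtype=float)
    eff = libsize * f
    vals = np.log2((mat + prior_count) / (eff + 2 * prior_count) * 1e6)
    df = pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns)
    nf = pd.Series(f / np.exp(np.mean(np.log(f))), index=counts.counts.columns)
    return NormalizedMatrix(values=df, norm_factors=nf, mode="rnaseq")


def median_center(values: pd.DataFrame) -> NormalizedMatrix:
    """Proteomic-mode preprocessing: subtract each sample's median abundance."""
    centered = values - values.median(axis=0)
    nf = pd.Series(1.0, index=values.columns)
    return NormalizedMatrix(values=centered, norm_factors=nf, mode="proteomic")


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on gene-wise variances.

    Works on z = log(s^2): under the hierarchical model z - E[z] has variance
    trigamma(df/2) + trigamma(d0/2); solving the trigamma equation for d0 and
    back-substituting the mean yields (d0, s0^2).  Returns d0 = inf when the
    observed spread is no larger than the sampling spread (fully shrunk).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by Newton iteration (limma's approach)
    y = 0.5 + 1.0 / e_var  # starting value from trigamma(x) ~ 1/x
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1 - tri / e_var) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2 * y
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0_2


@dataclass
class DEResult:
    """Moderated-t differential expression table plus the fitted prior."""

    table: pd.DataFrame  # columns: gene, log2fc, t, p, padj
    d0: float
    s0_2: float


def moderated_t_de(
    norm: NormalizedMatrix,
    group_a: list[str],
    group_b: list[str],
    d0_policy: str | float = "estimate",
    weights: pd.DataFrame | None = None,
) -> DEResult:
    """Two-group moderated-t differential expression on normalized values.

    log2fc is group A minus group B.  ``d0_policy`` is ``"estimate"`` (fit the
    prior degrees of freedom from the variance distribution), a float (fixed
    d0; 0 disables moderation, ``inf`` uses the common prior variance for all
    genes).  ``weights`` is an optional per-observation precision-weight hook;
    it is not used by the default pipeline.
    """
    if weights is not None:
        raise NotImplementedError("precision weights hook not implemented")
    ga = [s for s in group_a]
    gb = [s for s in group_b]
    if set(ga) & set(gb):
        raise ValueError("groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >=2 samples")
    missing = (set(ga) | set(gb)) - set(norm.values.columns)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)[:5]}")

    a = norm.values[ga].to_numpy()
    b = norm.values[gb].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = mean_a - mean_b
    dg = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / dg

    if d0_policy == "estimate":
        d0, s0_2 = _fit_f_dist(s2, dg)
    else:
        d0 = float(d0_policy)
        _, s0_2 = _fit_f_dist(s2, dg)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = dg
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = dg + d0

    se = np.sqrt(s2_post * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": norm.values.index,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "padj": padj,
        }
    ).reset_index(drop=True)
    return DEResult(table=table, d0=d0, s0_2=s0_2)
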