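"""Negative-binomial pairwise differential testing.

The test is a two-group NB Wald test with a log link, applied identically
to gene and peak count matrices:

* library size factors by the median-of-ratios convention;
* per-feature dispersion ``alpha`` (variance ``mu + alpha mu^2``) by a
  method-of-moments estimate shrunk 50/50 (log scale) toward a
  mean-dispersion trend fitted by local regression;
* per-group means fitted by Newton iteration on the NB score equation
  with sample size factors as offsets; Wald standard errors from the
  expected information;
* Benjamini-Hochberg adjustment within each contrast over features
  passing an independent low-count filter (``baseMean >= 1``).

A feature is called induced when ``log2FC >= log2(1.5)`` and
``padj <= 0.05`` (both boundaries inclusive), repressed for the mirror
condition, unchanged otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ValidationError

__all__ = [
    "FC_MIN",
    "ALPHA",
    "DISPERSION_FLOOR",
    "contrast_name",
    "normalize_libraries",
    "estimate_dispersion",
    "pairwise_contrast",
    "run_contrasts",
    "classify_regulation",
    "compute_rpkm",
]

#: Regulation cutoffs used throughout the study design.
FC_MIN = 1.5
ALPHA = 0.05

DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5
_BASEMEAN_FILTER = 1.0


def contrast_name(cond_a: str, cond_b: str) -> str:
    """Canonical key for the contrast of ``cond_b`` over ``cond_a``."""
    return f"{cond_b}_vs_{cond_a}"


def normalize_libraries(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only features with a nonzero count in every sample enter the median;
    an all-zero sample raises a :class:`ValidationError` naming it.
    """
    counts = cm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = cm.counts.columns[np.flatnonzero(totals == 0)[0]]
        raise ValidationError(f"sample {bad!r} has zero total counts")
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        raise ValidationError("no feature observed in every sample")
    log_geo = np.log(counts[usable]).mean(axis=1)
    log_ratios = np.log(counts[usable]) - log_geo[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def estimate_dispersion(cm: CountMatrix, size_factors: pd.Series) -> pd.Series:
    """Per-feature NB dispersion (variance = mu + alpha mu^2).

    The per-feature estimate is method-of-moments,
    ``max(0, (s^2 - mu) / mu^2)`` with the within-condition variance
    pooled over conditions (>= 2 replicates each), shrunk 50/50 toward a
    trend of dispersion over log mean.  The trend is a local (binned)
    moment-matching fit: within each log-mean bin
    ``alpha = (sum s^2 - sum mu) / sum(mu^2 - s^2/n)``, which uses an
    unbiased estimate of ``mu^2`` and averages out the strong
    replicate-level noise of the per-feature ratios.  Estimates are
    floored at 1e-8.
    """
    norm = cm.normalized(size_factors)
    mom_num = np.zeros(len(norm))
    var_pool = np.zeros(len(norm))
    den = 0.0
    n_reps = 0
    mu_all = norm.mean(axis=1).to_numpy()
    for cond in cm.conditions:
        cols = cm.samples_of(cond)
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        mom_num += df * contrib
        var_pool += df * v
        den += df
        n_reps = max(n_reps, len(cols))
    if den == 0:
        raise ValidationError("need >= 2 replicates in at least one condition")
    raw = np.maximum(mom_num / den, 0.0)
    s2 = var_pool / den

    trend = _dispersion_trend(mu_all, s2, n_reps)
    shrunk = np.maximum(0.5 * raw + 0.5 * trend, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=cm.counts.index, name="dispersion")


def _dispersion_trend(
    mu: np.ndarray, s2: np.ndarray, n_reps: int, n_bins: int = 20
) -> np.ndarray:
    """Binned moment-matching dispersion trend over log mean."""
    ok = mu >= 1.0
    if ok.sum() < 2 * n_bins:
        # too few informative features for a trend: one global bin
        denom = np.sum(mu[ok] ** 2 - s2[ok] / n_reps) if ok.any() else 0.0
        level = (
            (s2[ok].sum() - mu[ok].sum()) / denom if denom > 0 else DISPERSION_FLOOR
        )
        return np.full(len(mu), max(level, DISPERSION_FLOOR))
    log_mu = np.log(mu[ok])
    bins = pd.qcut(log_mu, n_bins, duplicates="drop")
    xs, ys = [], []
    for _, idx in pd.Series(np.arange(ok.sum())).groupby(bins, observed=True):
        sel = idx.to_numpy()
        denom = np.sum(mu[ok][sel] ** 2 - s2[ok][sel] / n_reps)
        a = (s2[ok][sel].sum() - mu[ok][sel].sum()) / max(denom, 1e-12)
        xs.append(log_mu[sel].mean())
        ys.append(max(a, DISPERSION_FLOOR))
    return np.interp(
        np.log(np.maximum(mu, 1e-12)), np.asarray(xs), np.asarray(ys)
    )


def _fit_group_log_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB MLE of the per-feature log mean with offsets.

    Solves sum_i (y_i - s_i q) / (1 + alpha s_i q) = 0 for beta = log q by
    Newton steps using the expected information I = sum_i mu_i/(1+alpha mu_i).
    Features with zero total counts get q = 0.5 / sum(s) (a half-count
    continuity value) so the Wald statistic stays finite.

    Returns (beta, info).
    """
    tot = y.sum(axis=1)
    q0 = np.where(tot > 0, (y / s).mean(axis=1), 0.5 / s.sum())
    beta = np.log(np.maximum(q0, 1e-12))
    zero = tot == 0
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        step[zero] = 0.0
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def pairwise_contrast(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    size_factors: pd.Series,
    dispersions: pd.Series,
    pseudocount: float = _PSEUDOCOUNT,
) -> pd.DataFrame:
    """NB Wald test of ``cond_b`` over ``cond_a``.

    Returns a DataFrame indexed by feature id with columns baseMean,
    log2FC, pvalue, padj.  The reported fold change is the ratio of mean
    normalized counts with ``pseudocount`` added to both means (bounded
    for zero-count features); the Wald statistic itself comes from the
    unpenalized group fits.
    """
    cols_a = cm.samples_of(cond_a)
    cols_b = cm.samples_of(cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("both conditions need >= 2 replicates")
    alpha = dispersions.reindex(cm.counts.index).to_numpy()
    if np.any(~np.isfinite(alpha)):
        raise ValidationError("dispersions missing for some features")

    sf = size_factors.reindex(cm.counts.columns)
    ya = cm.counts[cols_a].to_numpy(dtype=float)
    yb = cm.counts[cols_b].to_numpy(dtype=float)
    sa = sf[cols_a].to_numpy()
    sb = sf[cols_b].to_numpy()

    beta_a, info_a = _fit_group_log_mean(ya, sa, alpha)
    beta_b, info_b = _fit_group_log_mean(yb, sb, alpha)
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    z = (beta_b - beta_a) / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    mean_a = (ya / sa).mean(axis=1)
    mean_b = (yb / sb).mean(axis=1)
    log2_fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    base_mean = np.concatenate([ya / sa, yb / sb], axis=1).mean(axis=1)

    padj = np.full(len(pvalue), np.nan)
    tested = base_mean >= _BASEMEAN_FILTER
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2_fc,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=cm.counts.index,
    )


def run_contrasts(
    cm: CountMatrix,
    pairs: list[tuple[str, str]],
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    fc_min: float = FC_MIN,
    alpha: float = ALPHA,
) -> dict[str, pd.DataFrame]:
    """Run several contrasts, attaching a ``status`` column to each.

    ``pairs`` are (cond_a, cond_b) with fold changes reported as B over A;
    keys of the returned dict follow :func:`contrast_name`.
    """
    if size_factors is None:
        size_factors = normalize_libraries(cm)
    if dispersions is None:
        dispersions = estimate_dispersion(cm, size_factors)
    out = {}
    for cond_a, cond_b in pairs:
        res = pairwise_contrast(cm, cond_a, cond_b, size_factors, dispersions)
        res["status"] = classify_regulation(res, fc_min=fc_min, alpha=alpha)["status"]
        out[contrast_name(cond_a, cond_b)] = res
    return out


def classify_regulation(
    results: pd.DataFrame, fc_min: float = FC_MIN, alpha: float = ALPHA
) -> pd.DataFrame:
    """Call induced / repressed / unchanged with inclusive boundaries.

    Induced: ``log2FC >= log2(fc_min)`` and ``padj <= alpha``; repressed is
    the mirror image; everything else (including untested features with
    NaN padj) is unchanged.
    """
    if fc_min <= 0 or alpha <= 0:
        raise ValidationError("thresholds must be > 0")
    lfc = results["log2FC"].to_numpy()
    padj = results["padj"].to_numpy()
    sig = np.nan_to_num(padj, nan=1.0) <= alpha
    status = np.where(
        sig & (lfc >= np.log2(fc_min)),
        "induced",
        np.where(sig & (lfc <= -np.log2(fc_min)), "repressed", "unchanged"),
    )
    return pd.DataFrame({"status": status}, index=results.index)


def compute_rpkm(
    cm: CountMatrix,
    lengths: pd.Series | None = None,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``RPKM = count * 1e9 / (length_bp * total_reads_of_sample)``.  Totals
    default to column sums of the matrix.
    """
    if lengths is None:
        lengths = cm.lengths
    if lengths is None:
        raise ValidationError("feature lengths required for RPKM")
    lengths = lengths.reindex(cm.counts.index)
    missing = cm.counts.index[lengths.isna() | (lengths <= 0)]
    if len(missing):
        raise ValidationError(f"missing/invalid lengths for: {list(missing[:5])}")
    if totals is None:
        totals = cm.counts.sum(axis=0)
    totals = totals.reindex(cm.counts.columns)
    return (
        cm.counts * 1e9 / totals
    ).div(lengths, axis=0)
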