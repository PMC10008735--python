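"""Negative-binomial exact test for AML-vs-control count data.

The procedure mirrors the classical count-model workflow: trimmed-mean
(TMM) normalization factors, a moment-based common dispersion, and a
conditional exact test on per-group sums of library-size-equalized counts.
Conditionally on the total, the group-A sum follows a distribution that is
free of the NB success probability (negative-hypergeometric weights built
from gamma functions), reducing to Binomial(total, n_A/(n_A+n_B)) in the
Poisson limit phi = 0.  Two-sided p-values sum the probabilities of all
outcomes no more likely than the observed one.

The significance rule is p <= 0.05 and |log2FC| >= 1,
with no multiple-testing correction (a Benjamini-Hochberg column is emitted
for information only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

P_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


@dataclass
class NormalizationFactors:
    factors: pd.Series          # geometric mean 1
    library_sizes: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.factors * self.library_sizes


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None,
                logratio_trim: float = 0.30, abundance_trim: float = 0.05
                ) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, the factor is the precision-weighted mean of per-feature
    log2 ratios against the reference sample after trimming the most extreme
    30% of M-values and 5% of A-values; factors are rescaled to geometric
    mean 1.  The reference defaults to the sample whose upper quartile of
    scaled counts is closest to the mean upper quartile.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    if reference_sample is None:
        uq = counts.apply(lambda c: np.quantile(c / c.sum(), 0.75), axis=0)
        reference_sample = (uq - uq.mean()).abs().idxmin()

    x_r = counts[reference_sample].to_numpy(dtype=float)
    n_r = lib[reference_sample]
    factors = {}
    for sample in counts.columns:
        x_k = counts[sample].to_numpy(dtype=float)
        n_k = lib[sample]
        if sample == reference_sample:
            factors[sample] = 1.0
            continue
        ok = (x_k > 0) & (x_r > 0)
        if not ok.any():
            factors[sample] = 1.0
            continue
        pk, pr = x_k[ok] / n_k, x_r[ok] / n_r
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # Asymptotic inverse variance of M (delta method).
        w = 1.0 / ((n_k - x_k[ok]) / (n_k * x_k[ok])
                   + (n_r - x_r[ok]) / (n_r * x_r[ok]))
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[sample] = float(2 ** (np.sum(w[keep] * m[keep])
                                      / np.sum(w[keep])))
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return NormalizationFactors(factors=f, library_sizes=lib)


@dataclass
class DispersionEstimate:
    phi: float  # variance = mu + phi * mu^2

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")


def estimate_common_dispersion(counts: pd.DataFrame, groups: pd.Series,
                               factors: NormalizationFactors | None = None
                               ) -> DispersionEstimate:
    """Moment-based common NB dispersion from within-group variability.

    Counts are rescaled to a common effective library size; per feature the
    within-group moment estimate is phi_f = (v - m) / m^2, pooled over
    groups; the common dispersion is the median of the positive phi_f (0 if
    none are positive).
    """
    if factors is None:
        factors = tmm_factors(counts)
    groups = groups[counts.columns]
    for g, cols in groups.groupby(groups):
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    eff = factors.effective_sizes[counts.columns]
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = counts * (common / eff)

    num = np.zeros(len(counts.index))
    den = np.zeros(len(counts.index))
    for g in groups.unique():
        sub = scaled.loc[:, groups[groups == g].index]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        num += v - m
        den += m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_f = np.where(den > 0, num / den, np.nan)
    positive = phi_f[np.isfinite(phi_f) & (phi_f > 0)]
    return DispersionEstimate(float(np.median(positive)) if positive.size else 0.0)


def _exact_pvalue(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for group-A sum ``s_a`` of ``total``."""
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi <= 1e-12:
        pi = n_a / (n_a + n_b)
        logw = (gammaln(total + 1) - gammaln(s + 1) - gammaln(total - s + 1)
                + s * np.log(pi) + (total - s) * np.log1p(-pi))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (gammaln(s + r_a) - gammaln(s + 1)
                + gammaln(total - s + r_b) - gammaln(total - s + 1))
        logw -= logsumexp(logw)
    logp_obs = logw[s_a]
    p = float(np.exp(logsumexp(logw[logw <= logp_obs + 1e-10])))
    return min(p, 1.0)


def nb_exact_test(feature_counts: pd.Series, groups: pd.Series, phi: float,
                  factors: NormalizationFactors,
                  group_a: str = "AML", group_b: str = "control",
                  pseudocount: float = 1.0) -> Tuple[float, float]:
    """Exact test for one feature; returns (p, log2fc of A over B).

    Counts are scaled to a common effective library size and summed per
    group; the two-sided p-value conditions on the total.  The fold change
    is computed on mean RPM with a pseudocount for finite values at zero.
    """
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    eff = factors.effective_sizes
    common = float(np.exp(np.mean(np.log(eff[list(a_cols) + list(b_cols)]))))
    scaled = feature_counts * (common / eff)
    s_a = int(round(scaled[a_cols].sum()))
    s_b = int(round(scaled[b_cols].sum()))
    rpm = feature_counts * 1e6 / eff
    lfc = float(np.log2((rpm[a_cols].mean() + pseudocount)
                        / (rpm[b_cols].mean() + pseudocount)))
    if s_a + s_b == 0:
        return 1.0, 0.0
    p = _exact_pvalue(s_a, s_a + s_b, len(a_cols), len(b_cols), phi)
    return p, lfc


def run_de(counts: pd.DataFrame, groups: pd.Series,
           feature_meta: pd.DataFrame | None = None,
           phi: float | None = None,
           group_a: str = "AML", group_b: str = "control") -> pd.DataFrame:
    """Full differential-expression table for one discovery cohort.

    Estimates TMM factors and (unless given) the common dispersion, tests
    every feature, and applies the significance rule p <= 0.05 and
    |log2FC| >= 1.  An FDR column (Benjamini-Hochberg) is informational only.
    """
    groups = groups[counts.columns]
    factors = tmm_factors(counts)
    if phi is None:
        phi = estimate_common_dispersion(counts, groups, factors).phi
    rows = []
    for fid in counts.index:
        p, lfc = nb_exact_test(counts.loc[fid], groups, phi, factors,
                               group_a=group_a, group_b=group_b)
        rows.append((fid, lfc, p))
    df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "p"]
                      ).set_index("feature_id")
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    if feature_meta is not None:
        df.insert(0, "category", feature_meta["category"].reindex(df.index))
    df.attrs["phi"] = phi
    return call_de(df)


def call_de(results: pd.DataFrame) -> pd.DataFrame:
    """Apply the significance rule and attach up/down summary counts."""
    df = results.copy()
    df["significant"] = (df["p"] <= P_THRESHOLD) & \
        (df["log2fc"].abs() >= LFC_THRESHOLD)
    up = int((df["significant"] & (df["log2fc"] > 0)).sum())
    down = int((df["significant"] & (df["log2fc"] < 0)).sum())
    n = len(df)
    df.attrs.update(results.attrs)
    df.attrs["summary"] = {
        "n_features": n, "n_up": up, "n_down": down,
        "frac_up": up / n if n else 0.0, "frac_down": down / n if n else 0.0,
    }
    return df
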