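"""Gene-wise two-group differential expression on log2 values.

The core test is a pooled-variance t-test on group means; with moderation
enabled (the default) gene variances are squeezed toward a method-of-moments
inverse-chi-square prior estimated from the distribution of log sample
variances, and the t statistic gains the prior degrees of freedom.  With
moderation off the p-values are the textbook pooled t to machine precision,
which is what the unit tests pin down.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import ExpressionStudy

LFC_CUT = 0.5
P_CUT = 0.05


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0)."""
    if y <= 0:
        return np.inf
    # trigamma is decreasing; bracket widely and bisect
    lo, hi = 1e-8, 1e8
    f = lambda x: float(special.polygamma(1, x)) - y
    if f(lo) < 0:  # y above trigamma(lo): solution below lo
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def moment_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Uses the mean/variance of ``log(s2)`` under the scaled-F model:
    ``var(log s2) = trigamma(df/2) + trigamma(d0/2)``.  Returns
    ``d0 = inf`` when the observed spread is no wider than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    excess = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        log_s0 = float(np.mean(z)) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        log_s0 = (
            float(np.mean(z))
            - float(special.digamma(df / 2.0))
            + np.log(df / 2.0)
            + float(special.digamma(half_d0))
            - np.log(half_d0)
        )
    return d0, float(np.exp(log_s0))


def differential_expression(
    study: ExpressionStudy,
    ref_group: str,
    alt_group: str,
    moderated: bool = True,
    lfc_cut: float = LFC_CUT,
    p_cut: float = P_CUT,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene LFC (alt - ref means) and t-test p-value with calls.

    ``adjust=True`` applies Benjamini-Hochberg before thresholding
    (off by default: the per-gene p is compared to ``p_cut`` directly).
    """
    a = study.subset(ref_group).to_numpy(dtype=float)
    b = study.subset(alt_group).to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >=2 samples for differential expression")
    lfc = b.mean(axis=1) - a.mean(axis=1)
    df = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    se_factor = 1.0 / na + 1.0 / nb

    if moderated:
        d0, s0sq = moment_prior(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0sq)
            df_post = np.inf
        else:
            s2_post = (d0 * s0sq + df * s2) / (d0 + df)
            df_post = d0 + df
    else:
        s2_post = s2
        df_post = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * se_factor)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)

    p_for_calls = p
    if adjust:
        from .enrichment import benjamini_hochberg

        p_for_calls = benjamini_hochberg(p)
    calls = classify_calls(lfc, p_for_calls, lfc_cut=lfc_cut, p_cut=p_cut)
    return pd.DataFrame(
        {
            "gene": study.gene_ids,
            "lfc": lfc,
            "p": p,
            "call": calls,
            "moderated": moderated,
        }
    )


def classify_calls(
    lfc: np.ndarray, p: np.ndarray, lfc_cut: float = LFC_CUT, p_cut: float = P_CUT
) -> np.ndarray:
    """over / under / unchanged calls.

    Boundary semantics: ``|lfc| == lfc_cut`` passes (>=), ``p == p_cut``
    fails (strict <).
    """
    lfc = np.asarray(lfc, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = p < p_cut
    out = np.where(
        sig & (lfc >= lfc_cut), "over", np.where(sig & (lfc <= -lfc_cut), "under", "unchanged")
    )
    return out
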