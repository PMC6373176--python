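"""Paired-donor siRNA screen: moderated testing and opposite-regulation filter.

The screen asks which genes respond to NRF2 knockdown (siNRF2) and KEAP1
knockdown (siKEAP1) in *opposite* directions relative to the donor-matched
scrambled control (siCON).  Requiring opposite regulation under the two
knockdowns guards against off-target effects of either siRNA.

Differential expression per contrast uses a moderated paired t-test: the
per-gene variance of donor-paired differences is shrunk towards a common
prior fitted across all genes by the method of moments on log variances
(an empirical-Bayes scheme in the limma tradition).  P-values are adjusted
per contrast by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

CONTRASTS = ("siNRF2_vs_siCON", "siKEAP1_vs_siCON")


@dataclass
class ScreenHit:
    gene: str
    regulation: str  # "positively_controlled" | "negatively_controlled"
    log2fc_siNRF2: float
    adj_p_siNRF2: float
    log2fc_siKEAP1: float
    adj_p_siKEAP1: float


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square variance prior (d0, s0^2).

    Method of moments on z = log(s^2): under the hierarchical model
    z = log(sigma0^2) + log(chi2_d0-related term) + log(chi2_df/df), giving
    Var(z) = psi1(df/2) + psi1(d0/2) and
    E(z) = log(s0^2) + [psi(df/2) - log(df/2)] - [psi(d0/2) - log(d0/2)].
    d0 = inf (complete shrinkage) when the observed log-variance spread does
    not exceed the sampling component psi1(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need at least two genes with positive variance to fit prior")
    z = np.log(positive)
    zvar = np.var(z, ddof=1)
    excess = zvar - special.polygamma(1, df / 2.0)
    if excess <= 1e-10:
        d0 = np.inf
        s0_sq = np.exp(np.mean(z) - special.digamma(df / 2.0) + np.log(df / 2.0))
        return d0, s0_sq

    def eqn(x):  # x = d0/2
        return special.polygamma(1, x) - excess

    # polygamma(1, x) is decreasing: bracket the root
    lo, hi = 1e-6, 1e8
    d0_half = brentq(eqn, lo, hi)
    d0 = 2.0 * d0_half
    s0_sq = np.exp(
        np.mean(z)
        - (special.digamma(df / 2.0) - np.log(df / 2.0))
        + (special.digamma(d0_half) - np.log(d0_half))
    )
    return d0, s0_sq


def paired_moderated_test(
    intensities: pd.DataFrame,
    condition_sheet: pd.DataFrame,
    condition: str,
    reference: str = "siCON",
) -> pd.DataFrame:
    """Moderated paired t-test of ``condition`` vs ``reference`` across donors.

    Parameters
    ----------
    intensities
        Genes x samples log2 intensities.
    condition_sheet
        Columns ``sample_id, donor, condition``; each donor must carry one
        sample per condition.

    Returns a DataFrame indexed by gene with columns
    ``contrast, log2fc, t, raw_p, adj_p``.
    """
    for col in ("sample_id", "donor", "condition"):
        if col not in condition_sheet.columns:
            raise ValueError(f"condition sheet missing column {col!r}")
    wide = condition_sheet.pivot(index="donor", columns="condition", values="sample_id")
    for c in (condition, reference):
        if c not in wide.columns or wide[c].isna().any():
            raise ValueError(f"every donor needs one {c} sample")
    donors = wide.index
    if len(donors) < 2:
        raise ValueError("paired test undefined with fewer than 2 donors")

    treat = intensities[wide[condition]].to_numpy()
    ctrl = intensities[wide[reference]].to_numpy()
    d = treat - ctrl  # genes x donors
    n = d.shape[1]
    df = n - 1

    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)

    d0, s0_sq = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s_post_sq = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_post_sq = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / np.sqrt(s_post_sq / n)
    # zero posterior variance can only arise in degenerate all-zero data
    fallback = np.where(mean_d > 0, np.inf, np.where(mean_d < 0, -np.inf, 0.0))
    t = np.where(s_post_sq > 0, t, fallback)
    raw_p = 2.0 * stats.t.sf(np.abs(t), df_total)
    raw_p = np.clip(raw_p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "contrast": f"{condition}_vs_{reference}",
            "log2fc": mean_d,
            "t": t,
            "raw_p": raw_p,
            "adj_p": benjamini_hochberg(raw_p),
        },
        index=intensities.index,
    )
    return out


def benjamini_hochberg(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards, cap at 1
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def opposite_regulation_filter(
    nrf2_results: pd.DataFrame,
    keap1_results: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ScreenHit]:
    """Genes significantly regulated in opposite directions by the knockdowns.

    positively_controlled: adj_p < alpha with log2fc < 0 under siNRF2 AND
    adj_p < alpha with log2fc > 0 under siKEAP1.  negatively_controlled is
    the mirrored condition.  Genes significant in only one contrast, or in
    the same direction in both, are excluded.
    """
    a = set(nrf2_results.index)
    b = set(keap1_results.index)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"contrasts cover different gene universes: {diff[:10]}")

    keap1 = keap1_results.loc[nrf2_results.index]
    sig_n = nrf2_results["adj_p"] < alpha
    sig_k = keap1["adj_p"] < alpha
    down_n = nrf2_results["log2fc"] < 0
    up_k = keap1["log2fc"] > 0

    pos = sig_n & sig_k & down_n & up_k
    neg = sig_n & sig_k & ~down_n & ~up_k & (nrf2_results["log2fc"] > 0) & (keap1["log2fc"] < 0)

    hits = []
    for gene in nrf2_results.index:
        if pos.loc[gene]:
            reg = "positively_controlled"
        elif neg.loc[gene]:
            reg = "negatively_controlled"
        else:
            continue
        hits.append(
            ScreenHit(
                gene=gene,
                regulation=reg,
                log2fc_siNRF2=float(nrf2_results.loc[gene, "log2fc"]),
                adj_p_siNRF2=float(nrf2_results.loc[gene, "adj_p"]),
                log2fc_siKEAP1=float(keap1.loc[gene, "log2fc"]),
                adj_p_siKEAP1=float(keap1.loc[gene, "adj_p"]),
            )
        )
    return hits


def hits_to_frame(hits: list[ScreenHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.gene, h.regulation, h.log2fc_siNRF2, h.adj_p_siNRF2, h.log2fc_siKEAP1, h.adj_p_siKEAP1)
            for h in hits
        ],
        columns=["gene", "regulation", "log2fc_siNRF2", "adj_p_siNRF2", "log2fc_siKEAP1", "adj_p_siKEAP1"],
    )


def run_screen(intensities: pd.DataFrame, condition_sheet: pd.DataFrame, alpha: float = 0.05):
    """Both contrasts plus the opposite-regulation filter in one call."""
    nrf2 = paired_moderated_test(intensities, condition_sheet, "siNRF2")
    keap1 = paired_moderated_test(intensities, condition_sheet, "siKEAP1")
    hits = opposite_regulation_filter(nrf2, keap1, alpha=alpha)
    return nrf2, keap1, hits
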