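"""Pseudo site occupancy, fold changes, t-tests, BH FDR and significance calls.

The differential rule is: a site is hyper-succinylated when its corrected
log2 fold change (case minus control) exceeds ``fc_threshold`` (strictly)
at ``q < q_threshold`` (strictly). The Q-value is Benjamini-Hochberg
applied once across all testable sites of an experiment. Protein-level
abundance is divided out per sample first ("pseudo site occupancy") so
that site-level changes are not confounded by protein-level changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from succmap.tables_io import ProteinQuantTable, SampleDesign, SiteQuantTable

RESULT_COLUMNS = [
    "site_id",
    "protein_id",
    "position",
    "n_case_obs",
    "n_control_obs",
    "mean_log2_case",
    "mean_log2_control",
    "log2fc",
    "p",
    "q",
    "significant",
    "corrected",
]


def pseudo_occupancy(
    sites: SiteQuantTable,
    proteins: ProteinQuantTable,
    policy: str = "drop",
) -> tuple[SiteQuantTable, pd.Series]:
    """Divide site intensities by host-protein intensities per sample.

    The ratio approximates the modified fraction of the protein pool and
    removes protein-level abundance effects: multiplying a sample's site
    and protein intensities by any constant leaves it unchanged. Missing
    values in either factor (including zero protein intensity) give a
    missing corrected value.

    policy
        ``"drop"`` (default) removes sites whose protein is not
        quantified; ``"passthrough"`` keeps them uncorrected and flags
        them ``corrected=False``.

    Returns the corrected table and a per-site boolean ``corrected`` flag.
    """
    if policy not in {"drop", "passthrough"}:
        raise ValueError(f"unknown policy '{policy}'")
    df = sites.data.copy()
    has_protein = df["protein_id"].isin(proteins.data.index)
    if policy == "drop":
        df = df[has_protein].copy()
        has_protein = has_protein[has_protein]

    prot = proteins.intensities()
    for s in sites.samples:
        denom = df["protein_id"].map(prot[s]).to_numpy(dtype=float)
        denom[denom == 0] = np.nan  # zero abundance cannot normalize
        ratio = df[s].to_numpy(dtype=float) / denom
        df.loc[has_protein, s] = ratio[has_protein.to_numpy()]
    corrected = pd.Series(has_protein.to_numpy(), index=df.index, name="corrected")
    return SiteQuantTable(df, samples=list(sites.samples)), corrected


def log2_fold_change(
    corrected: SiteQuantTable, design: SampleDesign
) -> pd.DataFrame:
    """Per-site log2 fold change: mean log2 over case minus over control.

    Sites with a group entirely missing get NaN (untestable for fold
    change). Returns a frame with observation counts, group means and
    ``log2fc`` indexed by site id.
    """
    mat = corrected.intensities()
    case = np.log2(mat[list(design.case)])
    ctrl = np.log2(mat[list(design.control)])
    out = pd.DataFrame(
        {
            "n_case_obs": case.notna().sum(axis=1),
            "n_control_obs": ctrl.notna().sum(axis=1),
            "mean_log2_case": case.mean(axis=1),
            "mean_log2_control": ctrl.mean(axis=1),
        }
    )
    out["log2fc"] = out["mean_log2_case"] - out["mean_log2_control"]
    return out


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_test(a, b) -> WelchResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df).

    Degenerate policy: if both sample variances are zero, p=1 when the
    means are equal and p=0 (flagged) when they differ. Groups with
    fewer than two observations are untestable (NaN everywhere).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return WelchResult(np.nan, np.nan, np.nan)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(np.inf, float(len(a) + len(b) - 2), 0.0, degenerate=True)
    se2a, se2b = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def _ttest_vectorized(
    case: np.ndarray, ctrl: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test on matrices with NaN missing values."""
    na = np.sum(~np.isnan(case), axis=1)
    nb = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(case, axis=1)
        mb = np.nanmean(ctrl, axis=1)
        va = np.nanvar(case, axis=1, ddof=1)
        vb = np.nanvar(ctrl, axis=1, ddof=1)
        if equal_var:
            df = (na + nb - 2).astype(float)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        else:
            se2a = va / na
            se2b = vb / nb
            t = (ma - mb) / np.sqrt(se2a + se2b)
            df = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    testable = (na >= 2) & (nb >= 2)
    zero_var = testable & (va == 0) & (vb == 0)
    p[zero_var & (ma == mb)] = 1.0
    p[zero_var & (ma != mb)] = 0.0
    p[~testable] = np.nan
    t[~testable] = np.nan
    return t, p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes shrinkage of per-site variances (limma squeezeVar).

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    residual variances by the method of moments on log s^2, then returns
    posterior variances (d0*s0^2 + df*s2)/(d0 + df) and total df d0+df.
    An infinite d0 (no excess variability) collapses every variance to
    the common value.
    """
    from scipy.special import digamma, polygamma

    s2 = np.maximum(s2, 1e-30)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        return post, df + d0
    # variances are under-dispersed relative to chi-square: common variance
    s0_2 = np.exp(e_mean)
    return np.full_like(s2, s0_2), np.full_like(s2, np.inf)


def _moderated_vectorized(
    case: np.ndarray, ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated t: pooled variances shrunk toward a common prior.

    The per-site pooled variance is replaced by its empirical-Bayes
    posterior under a scaled inverse-chi-square prior fitted across all
    testable sites, and the t-test gains the prior degrees of freedom —
    the standard small-n strategy in quantitative proteomics.
    """
    na = np.sum(~np.isnan(case), axis=1)
    nb = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(case, axis=1)
        mb = np.nanmean(ctrl, axis=1)
        va = np.nanvar(case, axis=1, ddof=1)
        vb = np.nanvar(ctrl, axis=1, ddof=1)
        df_resid = (na + nb - 2).astype(float)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df_resid
    testable = (na >= 2) & (nb >= 2)
    t = np.full(case.shape[0], np.nan)
    p = np.full(case.shape[0], np.nan)
    if testable.sum() >= 2:
        post_var, post_df = _squeeze_var(sp2[testable], df_resid[testable])
        se = np.sqrt(post_var * (1.0 / na[testable] + 1.0 / nb[testable]))
        tt = (ma[testable] - mb[testable]) / se
        finite = np.isfinite(post_df)
        pp = np.empty_like(tt)
        pp[finite] = 2.0 * stats.t.sf(np.abs(tt[finite]), post_df[finite])
        pp[~finite] = 2.0 * stats.norm.sf(np.abs(tt[~finite]))
        t[testable] = tt
        p[testable] = pp
    elif testable.any():  # too few sites to fit a prior; plain pooled t
        return _ttest_vectorized(case, ctrl, equal_var=True)
    return t, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame, fc_threshold: float = 1.0, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag hyper-succinylated sites: log2fc > fc AND q < q, both strict."""
    results = results.copy()
    results["significant"] = (results["log2fc"] > fc_threshold) & (
        results["q"] < q_threshold
    )
    results.loc[results["q"].isna(), "significant"] = False
    results["significant"] = results["significant"].astype(bool)
    return results


def differential_analysis(
    sites: SiteQuantTable,
    proteins: ProteinQuantTable | None,
    design: SampleDesign,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    policy: str = "drop",
    min_per_group: int = 2,
    test: str = "moderated",
) -> pd.DataFrame:
    """Full per-site differential pipeline.

    Corrects for protein abundance (when ``proteins`` is given), computes
    log2 fold changes, runs per-site two-sample t-tests on the log2
    pseudo-occupancies, applies BH FDR across all testable sites, and
    applies the significance rule. Untestable sites (fewer than
    ``min_per_group`` observations in either group) are reported with
    NaN p/q, never silently dropped.

    test
        ``"moderated"`` (default) shrinks per-site pooled variances
        toward a common empirical-Bayes prior before the t-test — the
        standard small-n strategy in quantitative proteomics, where
        n=2-3 samples per group leave per-site variance estimates far
        too unstable to test against directly. ``"pooled"`` is the plain
        equal-variance two-sample t-test; ``"welch"`` the
        unequal-variance Welch test (noticeably underpowered at these
        group sizes because of its random Satterthwaite df).
    """
    if test not in {"moderated", "pooled", "welch"}:
        raise ValueError(f"unknown test '{test}'")
    if proteins is not None:
        corrected_tbl, corrected_flag = pseudo_occupancy(sites, proteins, policy)
    else:
        corrected_tbl = sites
        corrected_flag = pd.Series(False, index=sites.data.index)

    fc = log2_fold_change(corrected_tbl, design)
    mat = corrected_tbl.intensities()
    case = np.log2(mat[list(design.case)].to_numpy(dtype=float))
    ctrl = np.log2(mat[list(design.control)].to_numpy(dtype=float))
    if test == "moderated":
        t, p = _moderated_vectorized(case, ctrl)
    else:
        t, p = _ttest_vectorized(case, ctrl, equal_var=(test == "pooled"))
    enough = (fc["n_case_obs"] >= min_per_group) & (
        fc["n_control_obs"] >= min_per_group
    )
    p[~enough.to_numpy()] = np.nan

    out = pd.DataFrame(
        {
            "site_id": corrected_tbl.data.index,
            "protein_id": corrected_tbl.data["protein_id"].to_numpy(),
            "position": corrected_tbl.data["position"].to_numpy(),
        }
    ).set_index("site_id", drop=False)
    out.index.name = None
    out = out.join(fc)
    out["p"] = p
    out["q"] = np.nan
    testable = ~np.isnan(p)
    if testable.any():
        out.loc[testable, "q"] = bh_fdr(p[testable])
    out = call_significant(out, fc_threshold, q_threshold)
    out["corrected"] = corrected_flag.reindex(out.index).astype(bool)
    return out[RESULT_COLUMNS]
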