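"""Per-protein site accounting and rank/ANOVA statistics.

Covers the abundance-corrected "succinyl sites per protein" density, the
Wilcoxon rank-sum comparison of a target protein set (e.g. TCA-cycle
enzymes) against all other detected proteins, and one-way ANOVA with
Tukey HSD across proteins on their site-level log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from succmap.tables_io import SiteQuantTable


def sites_per_protein(sites: SiteQuantTable) -> pd.Series:
    """Count distinct modified positions per protein."""
    if len(sites) == 0:
        return pd.Series(dtype=int, name="n_sites")
    counts = sites.data.groupby("protein_id")["position"].nunique()
    counts.name = "n_sites"
    return counts


def site_count_histogram(counts: pd.Series) -> pd.Series:
    """Histogram of proteins by number of sites (1 site, 2 sites, ...)."""
    if counts.empty:
        return pd.Series(dtype=int, name="n_proteins")
    hist = counts.value_counts().sort_index()
    hist.index.name = "n_sites"
    hist.name = "n_proteins"
    return hist


def top_proteins_by_sites(counts: pd.Series, n: int = 20) -> pd.Series:
    """The N proteins with the most sites (ties broken by accession)."""
    df = counts.rename("n_sites").rename_axis("protein_id").reset_index()
    df = df.sort_values(["n_sites", "protein_id"], ascending=[False, True])
    return df.set_index("protein_id")["n_sites"].head(n)


def corrected_site_density(
    counts: Mapping[str, int] | pd.Series,
    abundance: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Rank proteins by site count divided by protein abundance.

    Proteins with missing, zero or negative abundance are flagged
    ``excluded`` with NaN density and no rank. Ties in density are
    broken by accession (lexicographic), so the ranking is deterministic
    and invariant to scaling all abundances by a positive constant.
    """
    counts = pd.Series(dict(counts) if not isinstance(counts, pd.Series) else counts)
    abundance = pd.Series(
        dict(abundance) if not isinstance(abundance, pd.Series) else abundance
    )
    df = pd.DataFrame({"n_sites": counts})
    df["abundance"] = abundance.reindex(df.index)
    ok = df["abundance"] > 0
    df["excluded"] = ~ok
    df["density"] = np.where(ok, df["n_sites"] / df["abundance"], np.nan)
    df = df.rename_axis("protein_id").reset_index()
    df = df.sort_values(
        ["excluded", "density", "protein_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    rank = np.full(len(df), np.nan)
    n_ok = int((~df["excluded"]).sum())
    rank[:n_ok] = np.arange(1, n_ok + 1)  # excluded rows sort last
    df["rank"] = rank
    return df


def set_rank_test(
    summaries: pd.DataFrame,
    target_set: set[str],
    value_column: str = "density",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of a protein set against its complement.

    The values (default: abundance-corrected site density) of proteins in
    ``target_set`` are compared with those of all other listed proteins.
    Exact enumeration is used when the smaller group has <= 8 members and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction. Returns (U statistic, p).
    """
    df = summaries.dropna(subset=[value_column])
    in_set = df["protein_id"].isin(target_set)
    a = df.loc[in_set, value_column].to_numpy(dtype=float)
    b = df.loc[~in_set, value_column].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("target set and complement must both be non-empty")
    values = np.concatenate([a, b])
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    """One-way ANOVA across proteins with Tukey HSD post hoc."""

    f: float
    p: float
    groups: list[str]
    tukey_p: pd.DataFrame  # symmetric matrix of adjusted pairwise p-values
    degenerate: bool = False


def fold_change_anova(
    fc_by_protein: Mapping[str, Sequence[float]],
    min_sites: int = 3,
) -> AnovaResult:
    """One-way ANOVA of site-level log2 fold changes across proteins.

    Only proteins with at least ``min_sites`` sites enter; Tukey HSD
    (Tukey-Kramer for unequal group sizes) gives adjusted p-values for
    every protein pair. If between- and within-group variance are both
    zero (all values identical) the test is degenerate with p=1.
    """
    groups = {
        pid: np.asarray(v, dtype=float)
        for pid, v in fc_by_protein.items()
        if len(v) >= min_sites
    }
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 proteins with >= {min_sites} sites (got {len(groups)})"
        )
    names = sorted(groups)
    arrays = [groups[n] for n in names]
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        k = len(names)
        tukey = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        return AnovaResult(0.0, 1.0, names, tukey, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    tukey = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    return AnovaResult(float(f), float(p), names, tukey)
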