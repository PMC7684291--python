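"""Fisher-exact functional term enrichment of hyper-succinylated proteins.

For each annotation term a 2x2 table is formed from a query protein set
(e.g. the hyper-succinylated proteins) against a background (by default
every protein detected in the experiment): the one-sided enrichment
p-value is the upper hypergeometric tail P(X >= k) with k query hits,
K background proteins carrying the term, n query proteins and N
background proteins. No ontology propagation is performed — terms are
used exactly as annotated (direct terms only).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from succmap.differential import bh_fdr


def _term_map(annotation) -> pd.DataFrame:
    """Normalize an annotation (DataFrame or protein→terms mapping)."""
    if isinstance(annotation, pd.DataFrame):
        df = annotation.iloc[:, :2].copy()
        df.columns = ["protein_id", "term"]
        return df
    rows = []
    for pid, terms in annotation.items():
        if isinstance(terms, str):
            terms = [terms]
        rows.extend((pid, t) for t in terms)
    return pd.DataFrame(rows, columns=["protein_id", "term"])


def fisher_enrichment(
    query: Iterable[str],
    annotation,
    background: Iterable[str],
    term_names: Mapping[str, str] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of every annotated term.

    Parameters
    ----------
    query
        Proteins of interest; must be a subset of ``background``.
    annotation
        Two-column frame (protein id, term id) or protein → term(s)
        mapping; proteins outside the background are ignored.
    background
        The universe against which enrichment is judged.
    alternative
        ``"greater"`` (enrichment tail, default) or ``"two-sided"``.

    Returns a frame sorted by p with columns term, name, k, K, n, N,
    odds_ratio, p, q (BH across terms). Terms with no query hit are
    reported with their computed tail p (which is <= 1).
    """
    query = set(query)
    background = set(background)
    offenders = query - background
    if offenders:
        raise ValueError(
            f"query proteins missing from background: {sorted(offenders)[:10]}"
        )
    ann = _term_map(annotation)
    ann = ann[ann["protein_id"].isin(background)].drop_duplicates()
    if ann.empty:
        raise ValueError("annotation covers no background protein")

    N, n = len(background), len(query)
    rows = []
    for term, grp in ann.groupby("term"):
        members = set(grp["protein_id"])
        K = len(members)
        k = len(members & query)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        elif alternative == "two-sided":
            table = [[k, n - k], [K - k, N - K - n + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            raise ValueError(f"unknown alternative '{alternative}'")
        with np.errstate(divide="ignore", invalid="ignore"):
            num = k * (N - K - n + k)
            den = (n - k) * (K - k)
            odds = num / den if den else np.inf
        name = term_names.get(term, "") if term_names else ""
        rows.append((term, name, k, K, n, N, odds, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "odds_ratio", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
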