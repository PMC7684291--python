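"""Cross-species succinyl-site transfer by pairwise global alignment.

Human and mouse orthologues differ by substitutions and by insertions
and deletions, so residue coordinates cannot be compared directly. Sites
are projected through an optimal global alignment (Needleman-Wunsch with
Gotoh affine gaps, BLOSUM62, gap open 10 / extend 0.5 — the EMBOSS needle
defaults) and a site pair counts as matched only when both aligned
residues are lysine and both studies report the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from succmap.tables_io import SiteQuantTable, site_id

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
_NEG = -np.inf

#: transfer / match status codes
MATCHED = "matched"
UNMAPPED_GAP = "unmapped_gap"
UNMAPPED_RESIDUE = "unmapped_residue"
UNMAPPED_NO_ORTHOLOG = "unmapped_no_ortholog"
UNMODIFIED_IN_OTHER = "unmodified_in_other"


def _encode(seq: str, matrix_index: Mapping[str, int], x_index: int) -> np.ndarray:
    return np.fromiter(
        (matrix_index.get(c, x_index) for c in seq), dtype=np.intp, count=len(seq)
    )


@dataclass
class AlignmentResult:
    """Optimal global alignment of two protein sequences.

    ``columns`` lists aligned positions (1-based) — ``(i, j)`` for a
    residue pair, ``(i, None)`` for a gap in B, ``(None, j)`` for a gap
    in A. Every residue of both sequences appears in exactly one column.
    """

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str
    columns: list[tuple[int | None, int | None]]
    score: float
    percent_identity: float
    _a_to_b: dict[int, int | None] = field(default=None, repr=False)  # type: ignore

    def a_to_b(self, pos_a: int) -> int | None:
        """B position aligned to ``pos_a`` (1-based), or None for a gap."""
        if self._a_to_b is None:
            self._a_to_b = {i: j for i, j in self.columns if i is not None}
        return self._a_to_b[pos_a]

    def pretty(self, width: int = 60) -> str:
        a_line = "".join(
            self.seq_a[i - 1] if i is not None else "-" for i, _ in self.columns
        )
        b_line = "".join(
            self.seq_b[j - 1] if j is not None else "-" for _, j in self.columns
        )
        chunks = []
        for k in range(0, len(a_line), width):
            chunks.append(a_line[k : k + width])
            chunks.append(b_line[k : k + width])
            chunks.append("")
        return "\n".join(chunks).rstrip()


def global_align(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    id_a: str = "A",
    id_b: str = "B",
) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties (Gotoh).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized. Residues absent from the matrix alphabet are scored as
    'X'. Traceback is deterministic: on ties a residue pair is preferred,
    then a gap in B, then a gap in A.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if matrix is None:
        mat = np.asarray(_BLOSUM62, dtype=float)
        index, x_index = _AA_INDEX, _X_INDEX
    else:
        mat = np.asarray(matrix, dtype=float)
        alphabet = str(matrix.alphabet)
        index = {aa: i for i, aa in enumerate(alphabet)}
        x_index = index.get("X", 0)
    ai = _encode(seq_a.upper(), index, x_index)
    bi = _encode(seq_b.upper(), index, x_index)
    n, m = len(ai), len(bi)
    S = mat[np.ix_(ai, bi)]
    go, ge = float(gap_open), float(gap_extend)

    # three-state DP; state X = gap in B (consumes A), state Y = gap in A
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    Y[0, 1:] = -(go + (js - 1) * ge)
    col_ge = js * ge  # helper for the in-row running-max gap formulation
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1] + prev_best
        X[i] = np.maximum(
            np.maximum(M[i - 1] - go, X[i - 1] - ge), Y[i - 1] - go
        )
        # Y[i, j] = max_{k<j} (max(M,X)[i,k] - go - (j-1-k)*ge), as a prefix max
        mx = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(mx + np.arange(m + 1) * ge)
        Y[i, 1:] = run[:-1] - go - (js - 1) * ge

    score = max(M[n, m], X[n, m], Y[n, m])
    columns = _traceback(M, X, Y, S, go, ge, n, m)
    matches = sum(
        1
        for i, j in columns
        if i is not None and j is not None and seq_a[i - 1] == seq_b[j - 1]
    )
    pid = 100.0 * matches / len(columns)
    return AlignmentResult(id_a, id_b, seq_a, seq_b, columns, float(score), pid)


def _traceback(M, X, Y, S, go, ge, n, m) -> list[tuple[int | None, int | None]]:
    tol = 1e-9
    i, j = n, m
    # choose end state with priority M > X > Y on ties
    best = max(M[n, m], X[n, m], Y[n, m])
    for state in "MXY":
        if {"M": M, "X": X, "Y": Y}[state][n, m] >= best - tol:
            break
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            cols.append((i, j))
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for state, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) <= tol:
                    break
        elif state == "X":
            cols.append((i, None))
            cand = (
                ("M", M[i - 1, j] - go),
                ("X", X[i - 1, j] - ge),
                ("Y", Y[i - 1, j] - go),
            )
            target = X[i, j]
            i -= 1
            for state, val in cand:
                if abs(val - target) <= tol:
                    break
        else:  # Y
            cols.append((None, j))
            cand = (
                ("M", M[i, j - 1] - go),
                ("X", X[i, j - 1] - go),
                ("Y", Y[i, j - 1] - ge),
            )
            target = Y[i, j]
            j -= 1
            for state, val in cand:
                if abs(val - target) <= tol:
                    break
    cols.reverse()
    return cols


@dataclass(frozen=True)
class TransferResult:
    """Outcome of projecting one site through an alignment."""

    pos_b: int | None
    status: str  # matched-candidate ("ok") or an unmapped_* reason


def transfer_site(
    aln: AlignmentResult, pos_a: int, require_lysine: bool = True
) -> TransferResult:
    """Project a 1-based A position onto B through the alignment.

    Returns the aligned B position, or the reason it cannot be used:
    ``unmapped_gap`` when A's residue faces a gap, ``unmapped_residue``
    when the aligned B residue is not lysine (with ``require_lysine``).
    """
    if not (1 <= pos_a <= len(aln.seq_a)):
        raise ValueError(f"position {pos_a} outside sequence ({len(aln.seq_a)} aa)")
    pos_b = aln.a_to_b(pos_a)
    if pos_b is None:
        return TransferResult(None, UNMAPPED_GAP)
    if require_lysine and aln.seq_b[pos_b - 1] != "K":
        return TransferResult(None, UNMAPPED_RESIDUE)
    return TransferResult(pos_b, "ok")


@dataclass
class OverlapSummary:
    """Cross-study protein/site overlap accounting."""

    n_proteins_a: int
    n_proteins_b: int
    n_proteins_common: int
    n_sites_a: int
    n_sites_b: int
    n_sites_matched: int
    fraction_of_a: float
    fraction_of_b: float
    site_counts: pd.DataFrame  # per common protein: n_sites_a, n_sites_b, n_matched

    def to_dict(self) -> dict:
        return {
            "n_proteins_A": self.n_proteins_a,
            "n_proteins_B": self.n_proteins_b,
            "n_proteins_common": self.n_proteins_common,
            "n_sites_A": self.n_sites_a,
            "n_sites_B": self.n_sites_b,
            "n_sites_matched": self.n_sites_matched,
            "fraction_of_A": self.fraction_of_a,
            "fraction_of_B": self.fraction_of_b,
        }


def _site_frame(sites) -> pd.DataFrame:
    """Accept a SiteQuantTable or a DataFrame with protein_id/position."""
    if isinstance(sites, SiteQuantTable):
        df = sites.data[["protein_id", "position"]].copy()
    else:
        df = sites[
            ["protein_id", "position"]
            + (["log2fc"] if "log2fc" in sites.columns else [])
        ].copy()
    if "log2fc" not in df.columns:
        df["log2fc"] = np.nan
    df["position"] = df["position"].astype(int)
    return df.reset_index(drop=True)


MATCH_COLUMNS = [
    "protein_a",
    "pos_a",
    "log2fc_a",
    "protein_b",
    "pos_b",
    "log2fc_b",
    "status",
]


def match_site_sets(
    sites_a,
    sites_b,
    seqs_a: Mapping[str, str],
    seqs_b: Mapping[str, str],
    ortholog_map: pd.DataFrame | Mapping[str, str] | None = None,
    require_lysine: bool = True,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[pd.DataFrame, OverlapSummary]:
    """Align orthologue pairs and transfer every A site onto study B.

    ``sites_a``/``sites_b`` are site tables or DataFrames with
    ``protein_id``, ``position`` and optionally ``log2fc``. Proteins are
    paired through ``ortholog_map`` (two columns A id / B id, or a dict);
    without a map, identifiers are matched case-insensitively (gene
    symbols). Many-to-many orthology rows are resolved by the highest
    alignment score. Each A site gets a status: ``matched`` (lysine
    aligned to a reported B site), ``unmodified_in_other``,
    ``unmapped_gap``, ``unmapped_residue``, or ``unmapped_no_ortholog``.
    """
    a = _site_frame(sites_a)
    b = _site_frame(sites_b)
    prots_a = sorted(a["protein_id"].unique())
    prots_b = sorted(b["protein_id"].unique())

    # candidate orthologue pairs among proteins with sites in both studies
    if ortholog_map is None:
        lower_b = {}
        for pb in prots_b:
            lower_b.setdefault(pb.lower(), []).append(pb)
        candidates = [(pa, pb) for pa in prots_a for pb in lower_b.get(pa.lower(), [])]
    else:
        if isinstance(ortholog_map, pd.DataFrame):
            pairs_iter = ortholog_map.iloc[:, :2].itertuples(index=False)
        else:
            pairs_iter = ortholog_map.items()
        set_a, set_b = set(prots_a), set(prots_b)
        candidates = [
            (pa, pb) for pa, pb in pairs_iter if pa in set_a and pb in set_b
        ]

    # align candidates, resolving many-to-many by best score
    alignments: dict[str, AlignmentResult] = {}
    multi = {pa for pa in {p for p, _ in candidates} if sum(1 for p, _ in candidates if p == pa) > 1}
    if multi:
        logger.warning("many-to-many orthology for %d protein(s); keeping best alignment score", len(multi))
    for pa, pb in candidates:
        if pa not in seqs_a or pb not in seqs_b:
            continue
        aln = global_align(
            seqs_a[pa], seqs_b[pb], gap_open=gap_open, gap_extend=gap_extend,
            id_a=pa, id_b=pb,
        )
        if pa not in alignments or aln.score > alignments[pa].score:
            alignments[pa] = aln

    b_sites = {(pb, pos) for pb, pos in zip(b["protein_id"], b["position"])}
    b_fc = {
        (pb, pos): fc
        for pb, pos, fc in zip(b["protein_id"], b["position"], b["log2fc"])
    }

    rows = []
    for _, row in a.iterrows():
        pa, pos_a, fc_a = row["protein_id"], int(row["position"]), row["log2fc"]
        aln = alignments.get(pa)
        if aln is None:
            rows.append((pa, pos_a, fc_a, None, None, np.nan, UNMAPPED_NO_ORTHOLOG))
            continue
        tr = transfer_site(aln, pos_a, require_lysine=require_lysine)
        if tr.status != "ok":
            rows.append((pa, pos_a, fc_a, aln.id_b, None, np.nan, tr.status))
        elif (aln.id_b, tr.pos_b) in b_sites:
            rows.append(
                (pa, pos_a, fc_a, aln.id_b, tr.pos_b,
                 b_fc[(aln.id_b, tr.pos_b)], MATCHED)
            )
        else:
            rows.append(
                (pa, pos_a, fc_a, aln.id_b, tr.pos_b, np.nan, UNMODIFIED_IN_OTHER)
            )
    matches = pd.DataFrame(rows, columns=MATCH_COLUMNS)

    common = sorted(alignments)
    counts_a = a.groupby("protein_id")["position"].nunique()
    counts_b = b.groupby("protein_id")["position"].nunique()
    matched = matches[matches["status"] == MATCHED]
    site_counts = pd.DataFrame(
        {
            "protein_a": common,
            "protein_b": [alignments[pa].id_b for pa in common],
            "n_sites_a": [int(counts_a[pa]) for pa in common],
            "n_sites_b": [int(counts_b[alignments[pa].id_b]) for pa in common],
            "n_matched": [
                int((matched["protein_a"] == pa).sum()) for pa in common
            ],
        }
    )
    n_a, n_b = len(prots_a), len(prots_b)
    summary = OverlapSummary(
        n_proteins_a=n_a,
        n_proteins_b=n_b,
        n_proteins_common=len(common),
        n_sites_a=len(a),
        n_sites_b=len(b),
        n_sites_matched=len(matched),
        fraction_of_a=len(common) / n_a if n_a else 0.0,
        fraction_of_b=len(common) / n_b if n_b else 0.0,
        site_counts=site_counts,
    )
    return matches, summary


def site_count_correlation(
    summary: OverlapSummary, log_counts: bool = False
) -> tuple[float, float]:
    """Pearson correlation of per-protein site counts across the studies.

    Over the proteins detected in both studies, correlates the number of
    succinyl sites each carries in study A vs study B; returns (r, r²).
    ``log_counts`` correlates log10 counts instead of raw counts.
    """
    df = summary.site_counts
    if len(df) < 3:
        raise ValueError("need >= 3 common proteins for a correlation")
    x = df["n_sites_a"].to_numpy(dtype=float)
    y = df["n_sites_b"].to_numpy(dtype=float)
    if log_counts:
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("site counts have zero variance; correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), float(r**2)


def fold_change_concordance(
    matches: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein median fold changes over matched sites in both studies.

    Returns (medians, paired): per-protein medians of log2fc in study A
    and study B over matched sites only, and the per-site paired table
    with the A-minus-B difference. Proteins with no matched site are
    absent.
    """
    paired = matches[matches["status"] == MATCHED].copy()
    paired["fc_diff"] = paired["log2fc_a"] - paired["log2fc_b"]
    if paired.empty:
        medians = pd.DataFrame(
            columns=["protein_a", "protein_b", "n_matched",
                     "median_log2fc_a", "median_log2fc_b", "median_diff"]
        )
        return medians, paired
    grouped = paired.groupby(["protein_a", "protein_b"], as_index=False).agg(
        n_matched=("pos_a", "size"),
        median_log2fc_a=("log2fc_a", "median"),
        median_log2fc_b=("log2fc_b", "median"),
    )
    grouped["median_diff"] = grouped["median_log2fc_a"] - grouped["median_log2fc_b"]
    return grouped.sort_values("protein_a").reset_index(drop=True), paired
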