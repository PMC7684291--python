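"""Synthetic succinylome experiments and orthologue pairs with known truth.

The generator emulates the statistical structure of a two-group
(patient/control) succinylome in which nearly all succinyl-lysine sites
increase (log2 effects around 2) while protein-level changes are near
zero: log-normal intensity noise, a uniform missing-completely-at-random
mask, and orthologous sequences that differ by substitutions and short
indels while a chosen subset of lysines is conserved.

Randomness is consumed from a single `numpy.random.Generator` per call in
a fixed, documented order (per-protein draws first, then per-site draws,
then the noise matrices row-major, then the missing masks), so identical
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from succmap.tables_io import (
    ProteinQuantTable,
    SampleDesign,
    SiteQuantTable,
    site_id,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic succinylome generator.

    Defaults mirror the study conditions this package targets: two
    control and three case samples, ~2.5 succinyl sites per protein
    (geometric, capped at 27), 95% of sites affected with a mean +2
    log2 shift in cases, and a flat proteome (``protein_effect_log2=0``).
    """

    n_proteins: int = 120
    sites_per_protein_mean: float = 2.5
    max_sites_per_protein: int = 27
    n_case: int = 3
    n_control: int = 2
    affected_fraction: float = 0.95
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.4
    protein_noise_sd_log2: float = 0.15
    protein_effect_log2: float = 0.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be > 0")
        if self.protein_noise_sd_log2 <= 0:
            raise ValueError("protein_noise_sd_log2 must be > 0")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.sites_per_protein_mean < 1:
            raise ValueError("sites_per_protein_mean must be >= 1")


@dataclass
class SyntheticExperiment:
    """Generated experiment: tables, design, ground truth and sequences."""

    sites: SiteQuantTable
    proteins: ProteinQuantTable
    design: SampleDesign
    truth: pd.DataFrame
    sequences: dict[str, str]


def simulate_succinylome(config: SynthConfig) -> SyntheticExperiment:
    """Generate site/protein tables for a two-group succinylome experiment.

    Model (log2 scale): protein abundance ~ N(20, 2); each site sits at
    protein abundance + a site offset ~ N(-3, 1); affected sites gain
    ``effect_log2`` in case samples; ``protein_effect_log2`` shifts both
    the protein intensity and (being a property of the host protein) its
    sites in case samples; i.i.d. N(0, ``noise_sd_log2``) noise is added
    and intensities are exponentiated base 2. Cells are masked missing
    at ``missing_rate`` (MCAR).
    """
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins
    protein_ids = [f"SYN{i + 1:04d}" for i in range(n_prot)]

    # per-protein draws
    p_geom = 1.0 / config.sites_per_protein_mean
    n_sites = np.minimum(
        rng.geometric(p_geom, size=n_prot), config.max_sites_per_protein
    )
    seq_lens = rng.integers(150, 451, size=n_prot)
    seq_lens = np.maximum(seq_lens, 10 * n_sites)  # room for distinct K positions
    prot_log2 = rng.normal(20.0, 2.0, size=n_prot)

    # sequences with lysines planted at the site positions
    sequences: dict[str, str] = {}
    site_rows: list[tuple[str, int]] = []
    aa = np.array(list(AMINO_ACIDS))
    for i, pid in enumerate(protein_ids):
        length = int(seq_lens[i])
        letters = aa[rng.integers(0, len(aa), size=length)]
        positions = np.sort(rng.choice(length, size=int(n_sites[i]), replace=False)) + 1
        letters[positions - 1] = "K"
        sequences[pid] = "".join(letters)
        site_rows.extend((pid, int(pos)) for pos in positions)

    n_total = len(site_rows)
    site_offsets = rng.normal(-3.0, 1.0, size=n_total)
    affected = rng.random(n_total) < config.affected_fraction

    design = SampleDesign(
        case=tuple(f"p{j + 1}" for j in range(config.n_case)),
        control=tuple(f"c{j + 1}" for j in range(config.n_control)),
    )
    samples = list(design.samples)
    is_case = np.array([design.group_of(s) == "case" for s in samples])
    n_samp = len(samples)

    pid_index = {pid: i for i, pid in enumerate(protein_ids)}
    prot_idx = np.fromiter(
        (pid_index[pid] for pid, _ in site_rows), dtype=int, count=n_total
    )
    site_base = prot_log2[prot_idx] + site_offsets
    site_log2 = np.tile(site_base[:, None], (1, n_samp))
    site_log2[:, is_case] += (
        affected[:, None] * config.effect_log2 + config.protein_effect_log2
    )
    site_log2 += rng.normal(0.0, config.noise_sd_log2, size=(n_total, n_samp))

    prot_log2_mat = np.tile(prot_log2[:, None], (1, n_samp))
    prot_log2_mat[:, is_case] += config.protein_effect_log2
    prot_log2_mat += rng.normal(
        0.0, config.protein_noise_sd_log2, size=(n_prot, n_samp)
    )

    site_int = np.exp2(site_log2)
    prot_int = np.exp2(prot_log2_mat)
    site_int[rng.random(site_int.shape) < config.missing_rate] = np.nan
    prot_int[rng.random(prot_int.shape) < config.missing_rate] = np.nan

    site_df = pd.DataFrame(
        {
            "protein_id": [pid for pid, _ in site_rows],
            "position": [pos for _, pos in site_rows],
            "residue": "K",
        }
    )
    for j, s in enumerate(samples):
        site_df[s] = site_int[:, j]
    prot_df = pd.DataFrame({"protein_id": protein_ids})
    for j, s in enumerate(samples):
        prot_df[s] = prot_int[:, j]

    truth = pd.DataFrame(
        {
            "site_id": [site_id(pid, pos) for pid, pos in site_rows],
            "protein_id": [pid for pid, _ in site_rows],
            "position": [pos for _, pos in site_rows],
            "affected": affected,
            "effect_log2": np.where(affected, config.effect_log2, 0.0),
        }
    )

    return SyntheticExperiment(
        sites=SiteQuantTable(site_df, samples=samples),
        proteins=ProteinQuantTable(prot_df, samples=samples),
        design=design,
        truth=truth,
        sequences=sequences,
    )


def simulate_ortholog(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    preserved_positions: set[int] | frozenset[int] = frozenset(),
    seed: int = 0,
) -> tuple[str, dict[int, int | None]]:
    """Mutate a protein sequence into a synthetic orthologue with known map.

    Each non-preserved residue is substituted with probability
    ``sub_rate`` (uniform over the 19 alternatives). Short indels
    (length 1-3, geometric p=0.5) occur at ``indel_rate`` per residue,
    split evenly between insertions and deletions; deletions never touch
    preserved positions. Preserved positions keep their residue letter.

    Returns the mutated sequence and the exact residue correspondence:
    a dict mapping every 1-based position of ``seq`` to its 1-based
    position in the mutated sequence, or None if deleted.
    """
    if not (0.0 <= sub_rate <= 0.3) or not (0.0 <= indel_rate <= 0.3):
        raise ValueError("sub_rate and indel_rate must be in [0, 0.3]")
    preserved = set(preserved_positions)
    for pos in preserved:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"preserved position {pos} out of range")

    rng = np.random.default_rng(seed)
    out: list[str] = []
    amap: dict[int, int | None] = {}
    alphabet = list(AMINO_ACIDS)

    def indel_len() -> int:
        return int(min(rng.geometric(0.5), 3))

    i = 1
    n = len(seq)
    while i <= n:
        # deletion opening at i (never at a preserved position)
        if i not in preserved and rng.random() < indel_rate / 2.0:
            dlen = indel_len()
            j = i
            while j <= n and j - i < dlen and j not in preserved:
                amap[j] = None
                j += 1
            i = j
            if i > n:
                break
        residue = seq[i - 1]
        if i not in preserved and rng.random() < sub_rate:
            choices = [a for a in alphabet if a != residue]
            residue = choices[int(rng.integers(0, len(choices)))]
        out.append(residue)
        amap[i] = len(out)
        # insertion after the consumed residue
        if rng.random() < indel_rate / 2.0:
            for _ in range(indel_len()):
                out.append(alphabet[int(rng.integers(0, len(alphabet)))])
        i += 1

    if not out:  # degenerate: everything deleted; keep the first residue
        out.append(seq[0])
        amap[1] = 1
    return "".join(out), amap
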