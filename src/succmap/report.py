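"""Pipeline orchestration and accounting reports.

``run_pipeline`` drives the stages validate → diff → stats → xmap →
enrich from a single configuration mapping (any stage omissible) and
always produces a machine-readable run summary with the experiment's
accounting numbers: sites and proteins identified, testable and
significant sites, hyper-succinylated proteins, and the cross-study
overlap block. Rerunning with the same configuration and seed yields an
identical summary.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import succmap
from succmap import differential, site_stats, xspecies
from succmap.enrichment import fisher_enrichment
from succmap.synthetic import SynthConfig, simulate_ortholog, simulate_succinylome
from succmap.tables_io import (
    read_design,
    read_fasta,
    read_protein_table,
    read_site_table,
    site_id,
    validate_sites_against_sequences,
    write_design,
    write_fasta,
    write_protein_table,
    write_site_table,
)

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ["validate", "diff", "stats", "xmap", "enrich"]


def venn_report(sets: Mapping[str, set]) -> dict:
    """Region counts and shared fractions for two or three labeled sets.

    Returns all 2^k - 1 region counts (keys are '+'-joined label
    combinations, exclusive regions) and, per set, the fraction of its
    elements found in at least one other set.
    """
    labels = list(sets)
    if not (2 <= len(labels) <= 3):
        raise ValueError("venn_report takes two or three sets")
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(
                *(sets[l] for l in labels if l not in combo), set()
            )
            regions["+".join(combo)] = len(inside - outside)
    shared = {}
    for l in labels:
        others = set().union(*(sets[o] for o in labels if o != l))
        shared[l] = len(sets[l] & others) / len(sets[l]) if sets[l] else 0.0
    return {"regions": regions, "shared_fraction": shared, "union": len(universe)}


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _simulate_study_b(
    experiment, truth: pd.DataFrame, seed: int,
    sub_rate: float = 0.05, indel_rate: float = 0.01,
    detect_fraction: float = 0.8, fc_scale: float = 0.6, fc_noise: float = 0.3,
):
    """Derive a synthetic second study (other species) from study A.

    Each protein is mutated into an orthologue (site lysines preserved);
    a ``detect_fraction`` subset of the affected A sites is "detected"
    in study B at the true mapped position, with log2 fold changes
    scaled by ``fc_scale`` plus noise — emulating a weaker perturbation
    measured in a different organism.
    """
    proteins = sorted(experiment.sequences)
    seeds = _child_seeds(seed + 1, len(proteins) + 1)
    rng = np.random.default_rng(seeds[-1])
    seqs_b: dict[str, str] = {}
    maps: dict[str, dict[int, int | None]] = {}
    site_pos = truth.groupby("protein_id")["position"].apply(set).to_dict()
    for i, pid in enumerate(proteins):
        preserved = site_pos.get(pid, set())
        mutated, amap = simulate_ortholog(
            experiment.sequences[pid], sub_rate, indel_rate,
            preserved_positions=preserved, seed=seeds[i],
        )
        seqs_b[f"{pid}_b"] = mutated
        maps[pid] = amap
    rows = []
    for _, row in truth.iterrows():
        if not row["affected"] or rng.random() > detect_fraction:
            continue
        pos_b = maps[row["protein_id"]][int(row["position"])]
        if pos_b is None:
            continue
        fc_b = row["effect_log2"] * fc_scale + rng.normal(0.0, fc_noise)
        rows.append((f"{row['protein_id']}_b", pos_b, fc_b))
    sites_b = pd.DataFrame(rows, columns=["protein_id", "position", "log2fc"])
    orthologs = pd.DataFrame(
        {"protein_a": proteins, "protein_b": [f"{p}_b" for p in proteins]}
    )
    return sites_b, seqs_b, orthologs, maps


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages and return the run summary.

    Configuration keys (all optional unless a stage needs them):
    ``seed``, ``stages``, ``simulate`` (synthetic-generator parameters,
    with optional ``ortholog`` sub-block for a synthetic second study),
    ``inputs`` (paths: sites, proteins, design, fasta), ``study_b``
    (paths: sites, fasta, orthologs), ``thresholds`` (fc, q),
    ``stats`` (target_set), ``enrich`` (annotation path or mapping).
    When ``out_dir`` is given every stage output is written there as
    TSV/JSON, plus ``summary.json``.
    """
    config = dict(config)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "tool": "succmap",
        "version": succmap.__version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "stages"},
        "stages": stages,
    }

    # ----- inputs: simulated or from files
    truth = None
    experiment = None
    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        ortho_cfg = sim_cfg.pop("ortholog", None)
        experiment = simulate_succinylome(SynthConfig(seed=seed, **sim_cfg))
        sites, proteins, design = (
            experiment.sites, experiment.proteins, experiment.design,
        )
        seqs = experiment.sequences
        truth = experiment.truth
        if out:
            write_site_table(sites, out / "sites.tsv")
            write_protein_table(proteins, out / "proteins.tsv")
            write_design(design, out / "design.tsv")
            write_fasta(seqs, out / "seqs.fa")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        paths = config.get("inputs", {})
        if "design" not in paths or "sites" not in paths:
            raise ValueError("config needs 'simulate' or 'inputs' with sites+design")
        design = read_design(paths["design"])
        sites = read_site_table(paths["sites"], design)
        proteins = (
            read_protein_table(paths["proteins"], design)
            if "proteins" in paths else None
        )
        seqs = read_fasta(paths["fasta"]) if "fasta" in paths else {}
        ortho_cfg = None

    summary["n_sites"] = len(sites)
    summary["n_proteins"] = int(sites.data["protein_id"].nunique())

    # ----- validate
    if "validate" in stages and seqs:
        report = validate_sites_against_sequences(sites, seqs)
        summary["validate"] = report["status"].value_counts().to_dict()
        if out:
            report.to_csv(out / "validation.tsv", sep="\t", index=False)

    # ----- differential
    diff = None
    if "diff" in stages:
        thr = config.get("thresholds", {})
        diff = differential.differential_analysis(
            sites, proteins, design,
            fc_threshold=float(thr.get("fc", 1.0)),
            q_threshold=float(thr.get("q", 0.05)),
            policy=config.get("policy", "drop"),
        )
        sig = diff[diff["significant"]]
        summary["diff"] = {
            "n_testable": int(diff["p"].notna().sum()),
            "n_significant": int(len(sig)),
            "n_hyper_proteins": int(sig["protein_id"].nunique()),
            "median_log2fc": float(diff["log2fc"].median()),
            "median_log2fc_significant": (
                float(sig["log2fc"].median()) if len(sig) else None
            ),
        }
        if truth is not None:
            merged = diff.join(truth.set_index("site_id")["affected"], on="site_id")
            called = merged["significant"].to_numpy()
            affected = merged["affected"].fillna(False).to_numpy(dtype=bool)
            tp = int((called & affected).sum())
            summary["diff"]["sensitivity"] = (
                tp / int(affected.sum()) if affected.any() else None
            )
            summary["diff"]["false_discovery_proportion"] = (
                float((called & ~affected).sum() / called.sum())
                if called.any() else 0.0
            )
        if out:
            diff.to_csv(out / "diff.tsv", sep="\t", index=False)

    # ----- site statistics
    if "stats" in stages:
        counts = site_stats.sites_per_protein(sites)
        hist = site_stats.site_count_histogram(counts)
        block = {
            "max_sites_per_protein": int(counts.max()) if len(counts) else 0,
            "fraction_single_site": (
                float((counts == 1).mean()) if len(counts) else None
            ),
        }
        if proteins is not None:
            ctrl = proteins.intensities()[list(design.control)].mean(axis=1)
            density = site_stats.corrected_site_density(counts, ctrl)
            target = config.get("stats", {}).get("target_set")
            if target:
                u, p = site_stats.set_rank_test(density, set(target))
                block["set_rank_test_p"] = p
            if out:
                density.to_csv(out / "site_density.tsv", sep="\t", index=False)
        summary["stats"] = block
        if out:
            hist.to_frame().to_csv(out / "site_count_histogram.tsv", sep="\t")

    # ----- cross-species mapping
    if "xmap" in stages:
        sites_b = seqs_b = orthologs = None
        if ortho_cfg is not None and experiment is not None:
            sites_b, seqs_b, orthologs, _ = _simulate_study_b(
                experiment, truth, seed, **{
                    k: v for k, v in dict(ortho_cfg).items()
                    if k in {"sub_rate", "indel_rate", "detect_fraction",
                             "fc_scale", "fc_noise"}
                },
            )
        elif "study_b" in config:
            sb = config["study_b"]
            design_b = read_design(sb["design"]) if "design" in sb else None
            if design_b is not None:
                sites_b = read_site_table(sb["sites"], design_b).data
            else:
                sites_b = pd.read_csv(sb["sites"], sep="\t")
            seqs_b = read_fasta(sb["fasta"])
            orthologs = (
                pd.read_csv(sb["orthologs"], sep="\t") if "orthologs" in sb else None
            )
        if sites_b is not None:
            a_frame = sites.data[["protein_id", "position"]].copy()
            if diff is not None:
                a_frame["log2fc"] = diff["log2fc"].reindex(sites.site_ids).to_numpy()
            matches, overlap = xspecies.match_site_sets(
                a_frame, sites_b, seqs, seqs_b, ortholog_map=orthologs,
            )
            block = overlap.to_dict()
            try:
                r, r2 = xspecies.site_count_correlation(overlap)
                block["site_count_r2"] = r2
            except ValueError:
                block["site_count_r2"] = None
            medians, paired = xspecies.fold_change_concordance(matches)
            block["n_proteins_with_matches"] = int(len(medians))
            summary["xmap"] = block
            if out:
                matches.to_csv(out / "matches.tsv", sep="\t", index=False)
                medians.to_csv(out / "concordance.tsv", sep="\t", index=False)
                with open(out / "overlap.json", "w") as fh:
                    json.dump(block, fh, indent=2, sort_keys=True)

    # ----- enrichment
    if "enrich" in stages and "enrich" in config and diff is not None:
        ann_spec = config["enrich"]["annotation"]
        ann = (
            pd.read_csv(ann_spec, sep="\t")
            if isinstance(ann_spec, (str, Path)) else ann_spec
        )
        background = (
            set(proteins.data["protein_id"]) if proteins is not None
            else set(sites.data["protein_id"])
        )
        query = set(diff.loc[diff["significant"], "protein_id"]) & background
        if query:
            enr = fisher_enrichment(query, ann, background)
            summary["enrich"] = {
                "n_terms": int(len(enr)),
                "n_terms_q05": int((enr["q"] < 0.05).sum()),
                "top_term": enr.iloc[0]["term"] if len(enr) else None,
            }
            if out:
                enr.to_csv(out / "enrich.tsv", sep="\t", index=False)

    if out:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
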