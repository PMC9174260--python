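"""End-to-end orchestration: simulate -> call -> classify -> compare ->
borders -> report, with a reproducibility manifest.

Every stage writes sorted plain-text artifacts; the manifest records the
configuration hash, seeds and a checksum per artifact, so identical inputs
reproduce a run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomeio as gio
from .borders import (assign_to_nucleosomes, edge_statistics,
                      on_nucleosome_fraction, pair_gap_distribution)
from .calling import call_dyads, spacing_stats
from .config import SyntheticConfig
from .model import (ModelParams, classify_states, compute_mark_profiles,
                    group_feature_table, group_nucleosomes)
from .report import filter_de, overlap_percentage
from .simulate import generate_borders, generate_condition_pair, \
    generate_gene_tables
from .switching import associate_genes, flag_switches, match_regions, \
    transition_table

VERSION = "0.1.0"


@dataclass
class RunManifest:
    version: str
    seed: int
    config_sha256: str
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "seed": self.seed,
             "config_sha256": self.config_sha256, "files": self.files},
            indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: SyntheticConfig, outdir, seed: int = 0,
                 params: ModelParams | None = None) -> RunManifest:
    """Run the full synthetic pipeline into ``outdir``; return the manifest."""
    params = params or ModelParams()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. simulate ---------------------------------------------------------
    pair = generate_condition_pair(config, seed=seed)
    genes = pair.veh.genes
    _, de = generate_gene_tables(config, seed=seed, genes=genes)
    borders_veh = generate_borders(config, pair.veh.nucleosomes, "Veh",
                                   n_pairs=max(200, 5 * config.n_regions),
                                   seed=seed)
    gio.write_tsv(genes.drop(columns=["region_id", "region_class"],
                             errors="ignore"), out / "genes.tsv")
    gio.write_tsv(de, out / "de.tsv")
    gio.write_tsv(pair.regions, out / "truth_regions.tsv")

    results: dict = {"seed": seed}
    state_maps = {}
    for cond, smap in (("Veh", pair.veh), ("DHT", pair.dht)):
        gio.write_points_bed(smap.midpoints, out / f"midpoints_{cond}.bed")

        # 2. call dyads ---------------------------------------------------
        nucs = call_dyads(smap.midpoints, bandwidth=30.0)
        nucs["name"] = [f"nuc{i}" for i in range(len(nucs))]
        gio.write_bed(nucs.assign(score=nucs["score"].round(3)),
                      out / f"nucleosomes_{cond}.bed",
                      extra_cols=["dyad", "width", "dop"])
        if len(nucs) >= 2:
            results[f"spacing_mode_{cond}"] = spacing_stats(nucs).mode

        # 3. profiles, grouping, classification ---------------------------
        profiles = compute_mark_profiles(nucs, smap.marks, smap.midpoints)
        grouped = group_nucleosomes(nucs, profiles, params)
        feats = group_feature_table(grouped, genes, smap.midpoints, params)
        assign = classify_states(feats, params)
        groups = feats.join(assign)
        gio.write_tsv(groups.reset_index(), out / f"groups_{cond}.tsv")
        state_maps[cond] = (grouped, groups)

    # 4. compare ----------------------------------------------------------
    gveh = state_maps["Veh"][1].reset_index()[
        ["group_id", "chrom", "start", "end", "state"]]
    gdht = state_maps["DHT"][1].reset_index()[
        ["group_id", "chrom", "start", "end", "state"]]
    matched = match_regions(gveh, gdht,
                            nucleosomes_b=state_maps["DHT"][0])
    matched["ras_flag"] = flag_switches(matched)
    tt = transition_table(matched)
    gio.write_tsv(tt.counts.reset_index(), out / "transitions.tsv")
    (out / "sankey.json").write_text(
        json.dumps(tt.to_sankey(), indent=2, sort_keys=True) + "\n")
    gio.write_tsv(matched, out / "matched_regions.tsv")

    # 5. borders ----------------------------------------------------------
    nucs_veh = state_maps["Veh"][0].copy()
    groups_veh = state_maps["Veh"][1]
    nucs_veh = nucs_veh.merge(
        groups_veh["state"], left_on="group_id", right_index=True, how="left")
    assignments = assign_to_nucleosomes(borders_veh, nucs_veh)
    gap_hist, gap_mode = pair_gap_distribution(borders_veh)
    results["border_gap_mode"] = gap_mode
    results["border_on_nucleosome_fraction"] = round(
        on_nucleosome_fraction(assignments), 4)
    try:
        es = edge_statistics(assignments, states=["S3", "S4"])
        results["edge_fraction_S3_S4"] = round(es["edge_fraction"], 4)
    except ValueError:
        results["edge_fraction_S3_S4"] = None
    gio.write_tsv(assignments.assign(
        offset=assignments["offset"].fillna(-999)),
        out / "border_assignments.tsv")

    # 6. report -----------------------------------------------------------
    matched["gene"] = associate_genes(matched, genes)
    ras1_genes = set(matched.loc[(matched["ras_flag"] == "S4->RAS1")
                                 & matched["gene"].notna(), "gene"])
    ras2_genes = set(matched.loc[(matched["ras_flag"] == "S3->RAS2")
                                 & matched["gene"].notna(), "gene"])
    de_genes = filter_de(de)
    for name, gset in (("S4_RAS1", ras1_genes), ("S3_RAS2", ras2_genes)):
        if gset:
            rep = overlap_percentage(gset, de_genes)
            results[f"overlap_{name}"] = {
                "n": rep.n_a, "intersection": rep.intersection,
                "percentage": rep.percentage}
        else:
            results[f"overlap_{name}"] = None
    (out / "report.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n")

    # manifest ------------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(_stable(config.to_dict()), sort_keys=True).encode()
    ).hexdigest()
    files = {p.name: _sha256(p)
             for p in sorted(out.iterdir())
             if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(VERSION, seed, cfg_hash, files)
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _stable(obj):
    if isinstance(obj, dict):
        return {str(k): _stable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float):
        return round(obj, 12)
    return obj
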