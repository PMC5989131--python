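"""End-to-end orchestration: simulate -> bin -> profile -> analyze.

A single JSON-able config drives the full synthetic analysis; every stage
writes its artifacts under the run directory and a manifest records the
parameters, seeds and package version so identical configs reproduce
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, io, netboot, neighbornet, permstats, profiles, synthio, taxbin

__all__ = ["DEFAULT_CONFIG", "run_full_analysis"]

log = logging.getLogger("benthos.pipeline")

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_reps": 6,
        "n_taxa": 60,
        "library_size": 5000,
        "landuse_effect": 0.8,
        "rain_effect": 0.3,
        "dirichlet_concentration": 200.0,
        "decoy_rate": 0.02,
        "nohit_rate": 0.05,
        "lowcomplexity_rate": 0.01,
    },
    "binning": {"min_score": 35.0, "top_percent": 10.0,
                "min_support": 25, "min_complexity": 0.44},
    "rank": "genus",
    "bootstrap": {"n_iter": 20, "n_reads": 10_000, "grouping": "land_use"},
    "stats": {"factors": ["land_use", "timing", "rain_event"],
              "random_factors": ["rain_event"], "n_perm": 999},
    "seed": 0,
}


def alternating_effects(n_taxa: int, magnitude: float) -> np.ndarray:
    """Deterministic +/- effect pattern of a given log magnitude."""
    signs = np.where(np.arange(n_taxa) % 2 == 0, 1.0, -1.0)
    return magnitude * signs


def _merge(default: dict, override: dict | None) -> dict:
    out = {}
    for k, v in default.items():
        if isinstance(v, dict):
            out[k] = _merge(v, (override or {}).get(k))
        else:
            out[k] = (override or {}).get(k, v)
    return out


def run_full_analysis(config: dict | None = None, out_dir=".",
                      seed: int | None = None) -> dict:
    """Run the full synthetic analysis; returns the manifest dict."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "config": cfg, "outputs": {}}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage=%s seed=%s start", name, cfg["seed"])
        return lambda: log.info("stage=%s elapsed=%.2fs", name,
                                time.perf_counter() - t0)

    try:
        # --- simulate -------------------------------------------------
        done = stage("simulate")
        sc = cfg["simulate"]
        metadata = synthio.generate_metadata(sc["n_reps"])
        params = synthio.SimulationParams(
            n_reps=sc["n_reps"], n_taxa=sc["n_taxa"],
            landuse_log_effects=alternating_effects(sc["n_taxa"], sc["landuse_effect"]),
            rain_log_effects=alternating_effects(sc["n_taxa"], sc["rain_effect"]),
            dirichlet_concentration=sc["dirichlet_concentration"],
            library_sizes=sc["library_size"], decoy_rate=sc["decoy_rate"],
            nohit_rate=sc["nohit_rate"],
            lowcomplexity_rate=sc["lowcomplexity_rate"], seed=cfg["seed"])
        truth, hits, reads, tree = synthio.generate_profiles_and_hits(metadata, params)
        io.write_metadata(metadata, out / "metadata.tsv")
        tree.to_table().to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        reads.to_csv(out / "reads.tsv", sep="\t")
        io.write_count_matrix(truth, out / "truth_species.tsv")
        manifest["outputs"]["simulate"] = ["metadata.tsv", "taxonomy.tsv",
                                           "hits.tsv", "reads.tsv",
                                           "truth_species.tsv"]
        done()

        # --- taxonomic binning ---------------------------------------
        done = stage("taxbin")
        bp = taxbin.BinningParams(**cfg["binning"])
        assignments = {sid: taxbin.bin_reads(rs, bp, tree)
                       for sid, rs in synthio.hits_to_readsets(hits, reads)}
        profile = taxbin.profile_at_rank(assignments, cfg["rank"], tree)
        profile = profile.loc[:, metadata.index]  # column order = design order
        io.write_count_matrix(profile, out / f"profile_{cfg['rank']}.tsv")
        done()

        # --- profiles and distances ----------------------------------
        done = stage("profiles")
        norm = profiles.normalize_to_smallest(profile)
        sq = profiles.transform(norm, "sqrt")
        dm = profiles.distance(sq, "braycurtis")
        io.write_count_matrix(norm, out / "profile_normalized.tsv")
        io.write_distance_matrix(dm, out / "braycurtis.tsv")
        io.write_phylip_lower(dm, out / "braycurtis.phylip")
        done()

        # --- diversity ------------------------------------------------
        done = stage("diversity")
        div = diversity.diversity_table(profile)
        div.to_csv(out / "diversity.tsv", sep="\t")
        done()

        # --- neighbor-net network ------------------------------------
        done = stage("network")
        css = neighbornet.neighbor_net(dm)
        graph = neighbornet.build_splits_graph(css)
        io.write_nexus_splits(css, out / "network.nex")
        io.write_edge_list(graph, out / "network_edges.tsv")
        manifest["outputs"]["network"] = {"n_nodes": graph.number_of_nodes(),
                                          "n_splits": len(css.splits)}
        done()

        # --- bootstrap reproducibility -------------------------------
        done = stage("bootstrap")
        bc = cfg["bootstrap"]
        bcfg = netboot.BootstrapConfig(n_iter=bc["n_iter"], n_reads=bc["n_reads"],
                                       grouping=bc["grouping"], seed=cfg["seed"])
        groups = metadata.loc[[str(c) for c in profile.columns], bc["grouping"]]
        table, _, _ = netboot.bootstrap_networks(profile, groups, bcfg)
        table.to_csv(out / "bootstrap_iterations.tsv", sep="\t", index=False)
        netboot.summarize_iterations(table).to_csv(out / "bootstrap_summary.tsv", sep="\t")
        done()

        # --- permutation statistics ----------------------------------
        done = stage("stats")
        st = cfg["stats"]
        pa = permstats.permanova(dm, metadata, st["factors"],
                                 st["random_factors"], n_perm=st["n_perm"],
                                 seed=cfg["seed"])
        pa.to_csv(out / "permanova.tsv", sep="\t")
        pdisp = permstats.permdisp(dm, metadata.loc[list(dm.ids), "land_use"],
                                   n_perm=st["n_perm"], seed=cfg["seed"])
        pd.Series(pdisp["group_mean_dispersion"]).to_frame("mean_dispersion") \
            .assign(F=pdisp["F"], p=pdisp["p"]) \
            .to_csv(out / "permdisp.tsv", sep="\t")
        simp = permstats.simper(sq, metadata.loc[[str(c) for c in sq.columns],
                                                 "land_use"])
        simp.to_csv(out / "simper.tsv", sep="\t")
        # structure/function coupling stands in for the taxon-vs-function
        # comparison: species-level vs genus-level distance matrices
        sp_profile = taxbin.profile_at_rank(assignments, "species", tree)
        sp_profile = sp_profile.loc[:, metadata.index]
        dm2 = profiles.distance(profiles.transform(
            profiles.normalize_to_smallest(sp_profile), "sqrt"), "braycurtis")
        rho, p = permstats.relate(dm, dm2, n_perm=st["n_perm"], seed=cfg["seed"])
        (out / "relate.tsv").write_text(f"rho\tp\n{rho:.6f}\t{p:.6g}\n",
                                        encoding="utf-8")
        done()
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
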