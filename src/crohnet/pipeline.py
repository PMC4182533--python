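"""End-to-end pipeline: simulate -> prioritise -> sub-network -> characterise.

The pipeline runs the full analysis on either synthetic artifacts (generated
from a scenario section in the config) or user-supplied files, writing every
stage's tabular outputs plus a JSON provenance record into the output
directory. Stage seeds are derived deterministically from the global seed and
the stage name, so a rerun with the same config is byte-identical. In
incremental mode a stage whose outputs already exist is skipped, and deleting
an intermediate artifact regenerates only the stages downstream of it.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Any

import networkx as nx

from . import io as nio
from .disease_network import connected_components, density_ratio, extract_disease_network
from .enrichment import de_enrichment, hub_overrep, identify_hubs
from .motifs import motif_participation, motif_zscores
from .prioritise import consensus, rwr, select_by_steady_state, select_external
from .robustness import removal_trajectory
from .segregation import annotation_segregation, list_segregation
from .simulate import SyntheticScenario, generate_scenario_artifacts
from .topology import er_ensemble_compare
from .types import GeneSet

__all__ = ["DEFAULT_CONFIG", "stage_seed", "run_pipeline", "load_config"]

STAGES = (
    "simulate",
    "prioritise",
    "subnetwork",
    "topology",
    "robustness",
    "motifs",
    "segregation",
    "enrichment",
    "report",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "scenario": {},  # SyntheticScenario field overrides
    "prioritise": {
        "restart": 0.5,
        "tol": 1e-10,
        "max_iter": 10_000,
        "rule": "top_k",
        "rule_value": 30,
        "p_threshold": 0.1,
        "combiner": "intersection",
    },
    "topology": {"er_replicates": 50},
    "robustness": {"step_fraction": 0.05, "strategies": ["random", "degree_desc", "degree_asc"]},
    "motifs": {"k": [3], "replicates": 20, "z_threshold": 2.0, "swaps_per_edge": 10},
    "segregation": {"min_size": 5},
    "enrichment": {"alpha": 0.05, "min_size": 5},
}


class DependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _provenance(out: Path, stage: str, params: dict, outputs: list[str], extra: dict | None = None):
    record = {"stage": stage, "parameters": params, "outputs": outputs}
    if extra:
        record.update(extra)
    with open(out / f"{stage}.provenance.json", "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _outputs_exist(out: Path, names: list[str]) -> bool:
    return all((out / n).exists() for n in names)


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise DependencyError(f"stage {stage!r} needs missing artifact {name!r}")
    return p


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "crohnet_results",
    incremental: bool = False,
    verbose: bool = False,
) -> dict:
    """Execute every stage in dependency order; returns the report dict."""
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: list[str] = []

    def say(msg: str):
        log.append(msg)
        if verbose:
            print(msg)

    # -- simulate ----------------------------------------------------------
    sim_outputs = [
        "network.tsv",
        "module.txt",
        "training.txt",
        "candidates.txt",
        "ranking.tsv",
        "de_table.tsv",
        "classes.gmt",
    ]
    if cfg["scenario"] is None:
        # external-inputs mode: artifacts must already be in the output directory
        say("simulate: disabled, expecting external artifacts")
    elif not (incremental and _outputs_exist(out, sim_outputs)):
        scenario = SyntheticScenario(**{"seed": stage_seed(seed, "simulate"), **cfg["scenario"]})
        art = generate_scenario_artifacts(scenario)
        nio.write_edge_list(art["network"], out / "network.tsv")
        nio.write_gene_set(art["module"], out / "module.txt")
        nio.write_gene_set(art["training"], out / "training.txt")
        nio.write_gene_set(art["candidates"], out / "candidates.txt")
        nio.write_ranked_list(art["ranking"], out / "ranking.tsv")
        nio.write_de_table(art["de_table"], out / "de_table.tsv")
        nio.write_annotations(art["annotations"], out / "classes.gmt")
        _provenance(out, "simulate", {**scenario.__dict__}, sim_outputs)
        say(
            f"simulate: {art['network'].number_of_nodes()} nodes, "
            f"{art['network'].number_of_edges()} edges"
        )
    else:
        say("simulate: outputs present, skipped")

    net, _ = nio.read_edge_list(_require(out, "network.tsv", "prioritise"))
    training = nio.read_gene_set(_require(out, "training.txt", "prioritise"), "training")
    candidates = nio.read_gene_set(_require(out, "candidates.txt", "prioritise"), "candidates")
    ranking = nio.read_ranked_list(_require(out, "ranking.tsv", "prioritise"))

    # -- prioritise --------------------------------------------------------
    pri_cfg = cfg["prioritise"]
    if not (incremental and _outputs_exist(out, ["prioritised.txt"])):
        vector = rwr(
            net,
            training,
            r=pri_cfg["restart"],
            tol=pri_cfg["tol"],
            max_iter=pri_cfg["max_iter"],
        )
        rwr_sel = select_by_steady_state(
            vector, candidates, rule=pri_cfg["rule"], value=pri_cfg["rule_value"]
        )
        ext_sel = select_external(ranking, pri_cfg["p_threshold"])
        result = consensus(rwr_sel, ext_sel, training, combiner=pri_cfg["combiner"])
        nio.write_gene_set(result.consensus, out / "prioritised.txt")
        _provenance(
            out,
            "prioritise",
            pri_cfg,
            ["prioritised.txt"],
            {
                "iterations": vector.iterations,
                "converged": vector.converged,
                "n_rwr_selected": len(rwr_sel),
                "n_external_selected": len(ext_sel),
                "n_consensus": len(result.consensus),
            },
        )
        say(f"prioritise: {len(result.consensus)} consensus genes")
    else:
        say("prioritise: outputs present, skipped")

    prioritised = nio.read_gene_set(_require(out, "prioritised.txt", "subnetwork"), "prioritised")

    # -- subnetwork --------------------------------------------------------
    if not (incremental and _outputs_exist(out, ["disease_edges.tsv", "node_roles.tsv"])):
        disease = extract_disease_network(net, prioritised)
        nio.write_edge_list(disease, out / "disease_edges.tsv")
        with open(out / "node_roles.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\trole\n")
            for n in sorted(disease.nodes()):
                fh.write(f"{n}\t{disease.nodes[n]['role']}\n")
        _provenance(
            out,
            "subnetwork",
            {},
            ["disease_edges.tsv", "node_roles.tsv"],
            {
                "n_nodes": disease.number_of_nodes(),
                "n_edges": disease.number_of_edges(),
                "n_components": len(connected_components(disease)),
                "density_ratio": density_ratio(disease, net),
            },
        )
        say(
            f"subnetwork: {disease.number_of_nodes()} nodes, "
            f"{disease.number_of_edges()} edges"
        )
    else:
        say("subnetwork: outputs present, skipped")

    disease, _ = nio.read_edge_list(_require(out, "disease_edges.tsv", "topology"))

    # -- topology ----------------------------------------------------------
    if not (incremental and _outputs_exist(out, ["topology.json"])):
        report = er_ensemble_compare(
            disease, n_random=cfg["topology"]["er_replicates"], seed=stage_seed(seed, "topology")
        )
        payload = {
            "metrics": dict(report.metrics),
            "null_mean": dict(report.null_mean),
            "null_sd": dict(report.null_sd),
            "z_scores": dict(report.z_scores),
            "p_values": dict(report.p_values),
            "n_random": report.n_random,
        }
        with open(out / "topology.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _provenance(out, "topology", cfg["topology"], ["topology.json"])
        say("topology: ER comparison done")
    else:
        say("topology: outputs present, skipped")

    # -- robustness --------------------------------------------------------
    if not (incremental and _outputs_exist(out, ["robustness.tsv"])):
        rows = []
        for strategy in cfg["robustness"]["strategies"]:
            traj = removal_trajectory(
                disease,
                strategy,
                step_fraction=cfg["robustness"]["step_fraction"],
                seed=stage_seed(seed, f"robustness:{strategy}"),
            )
            for s in traj.steps:
                rows.append(
                    (strategy, s.fraction_removed, s.surviving_edges, s.secondary_extinctions)
                )
        with open(out / "robustness.tsv", "w", encoding="utf-8") as fh:
            fh.write("strategy\tfraction_removed\tsurviving_edges\tsecondary_extinctions\n")
            for r in rows:
                fh.write(f"{r[0]}\t{r[1]:.6f}\t{r[2]}\t{r[3]}\n")
        _provenance(out, "robustness", cfg["robustness"], ["robustness.tsv"])
        say(f"robustness: {len(rows)} trajectory rows")
    else:
        say("robustness: outputs present, skipped")

    # -- motifs ------------------------------------------------------------
    if not (incremental and _outputs_exist(out, ["motifs.tsv", "participation.tsv"])):
        mcfg = cfg["motifs"]
        with open(out / "motifs.tsv", "w", encoding="utf-8") as fh, open(
            out / "participation.tsv", "w", encoding="utf-8"
        ) as pf:
            fh.write("k\tmotif_id\treal_count\tnull_mean\tnull_sd\tz_score\tcall\n")
            pf.write("k\tid\tmotif_instances\n")
            for k in mcfg["k"]:
                census = motif_zscores(
                    disease,
                    k,
                    n_random=mcfg["replicates"],
                    z_threshold=mcfg["z_threshold"],
                    swaps_per_edge=mcfg["swaps_per_edge"],
                    seed=stage_seed(seed, f"motifs:{k}"),
                )
                for cid in sorted(census.classes):
                    s = census.classes[cid]
                    fh.write(
                        f"{k}\t{cid}\t{s.real_count}\t{s.null_mean:.4f}\t"
                        f"{s.null_sd:.4f}\t{s.z_score:.4f}\t{s.call}\n"
                    )
                part = motif_participation(disease, census, genes=prioritised)
                for g, c in part.items():
                    pf.write(f"{k}\t{g}\t{c}\n")
        _provenance(out, "motifs", mcfg, ["motifs.tsv", "participation.tsv"])
        say("motifs: census written")
    else:
        say("motifs: outputs present, skipped")

    # -- segregation -------------------------------------------------------
    annotations = nio.read_annotations(_require(out, "classes.gmt", "segregation"))
    if not (incremental and _outputs_exist(out, ["segregation.tsv"])):
        profiles = annotation_segregation(
            disease, annotations, min_size=cfg["segregation"]["min_size"]
        )
        try:
            profiles.append(list_segregation(disease, prioritised))
        except Exception:  # prioritised list too small/disconnected in the sub-network
            pass
        with open(out / "segregation.tsv", "w", encoding="utf-8") as fh:
            fh.write("class\tpopulation\tnetwork_size\td_max\tindex\n")
            for p in profiles:
                fh.write(
                    f"{p.class_name}\t{p.population}\t{p.network_size}\t{p.d_max}\t{p.index:.6f}\n"
                )
        _provenance(out, "segregation", cfg["segregation"], ["segregation.tsv"])
        say(f"segregation: {len(profiles)} class profiles")
    else:
        say("segregation: outputs present, skipped")

    # -- enrichment --------------------------------------------------------
    de = nio.read_de_table(_require(out, "de_table.tsv", "enrichment"))
    if not (incremental and _outputs_exist(out, ["enrichment.tsv"])):
        universe = GeneSet("universe", net.nodes())
        rows = []
        hubs = identify_hubs(net)
        for label, gene_set in (
            ("prioritised", prioritised),
            ("disease_network", GeneSet("disease_network", disease.nodes())),
        ):
            res = hub_overrep(gene_set, net)
            rows.append((f"hub_overrep:{label}", res.p_value, json.dumps(res.counts, sort_keys=True)))
        res = de_enrichment(prioritised, de, universe, alpha=cfg["enrichment"]["alpha"])
        rows.append(("de_enrichment", res.p_value, json.dumps(res.counts, sort_keys=True)))
        with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write("test\tp_value\tcounts\n")
            for name, p, counts_json in rows:
                fh.write(f"{name}\t{p:.6g}\t{counts_json}\n")
        _provenance(
            out, "enrichment", cfg["enrichment"], ["enrichment.tsv"], {"n_hubs": len(hubs)}
        )
        say(f"enrichment: {len(rows)} tests")
    else:
        say("enrichment: outputs present, skipped")

    # -- report ------------------------------------------------------------
    manifest = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "report.json")
    report_payload = {
        "seed": seed,
        "config": cfg,
        "manifest": manifest,
        "log": log,
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report_payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")
    return report_payload
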