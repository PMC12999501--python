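"""End-to-end pipeline orchestration.

Stage order: score-mcq -> propagate -> hierarchy -> enrich.  Every run
writes a manifest JSON recording the configuration, the master seed and
every exclusion count, and all stage outputs are plain TSV so that a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich_hierarchy
from .errors import DDNetMapError, ParameterError, StageError
from .hierarchy import HierarchyConfig, build_hierarchy, persistent_communities, \
    sweep_resolutions
from .io import read_gmt, read_seed_list, write_gmt
from .mcq import DiscountModel, QCThresholds, default_item_bank, read_items_csv, \
    write_items_csv
from .network import GeneNetwork, read_edge_list
from .propagation import NetworkPropagation, PropagationConfig
from .synthetic import PlantedNetworkSpec, gen_cohort, gen_network, gen_seed_set, \
    gen_trait_sets
from .enrichment import TraitGeneSet

log = logging.getLogger("ddnetmap")

__all__ = ["RunConfig", "run_all", "simulate_preset"]


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    network_path: str = ""
    seeds_path: str = ""
    traits_path: str = ""
    annotations_path: str = ""
    items_path: str = ""
    responses_path: str = ""
    out_dir: str = "ddnetmap_out"
    rng_seed: int = 0
    run_mcq: bool = True
    run_propagate: bool = True
    run_hierarchy: bool = True
    run_enrich: bool = True
    # stage settings (flat keys; see the per-stage config dataclasses)
    alpha: float = 0.5
    n_null: int = 100
    nps_threshold: float = 3.0
    degree_bins: int = 10
    max_resolution: float = 5.0
    resolution_steps: int = 10
    jaccard_threshold: float = 0.75
    persistence_min: int = 5
    ci_threshold: float = 0.75
    min_consistency: float = 0.75
    max_missing: int = 0
    fdr_level: float = 0.05
    universe: str = "network"  # or "selected"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def propagation_config(self) -> PropagationConfig:
        return PropagationConfig(alpha=self.alpha, n_null=self.n_null,
                                 nps_threshold=self.nps_threshold,
                                 degree_bins=self.degree_bins,
                                 rng_seed=self.rng_seed)

    def hierarchy_config(self) -> HierarchyConfig:
        grid = tuple(np.round(np.linspace(
            self.max_resolution / self.resolution_steps * 1,
            self.max_resolution, self.resolution_steps), 10))
        return HierarchyConfig(resolution_grid=grid,
                               jaccard_threshold=self.jaccard_threshold,
                               persistence_min=self.persistence_min,
                               ci_threshold=self.ci_threshold,
                               partition_seed=self.rng_seed)


def simulate_preset(preset: str, seed: int, out_dir) -> dict[str, str]:
    """Write the packaged synthetic inputs for a pipeline run.

    ``preset`` is ``network`` (network + seeds + trait sets), ``mcq``
    (item table + choice matrix) or ``full`` (both).  Returns the paths
    written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    if preset not in {"network", "mcq", "full"}:
        raise ParameterError(f"unknown preset {preset!r}")
    if preset in {"network", "full"}:
        planted = gen_network(PlantedNetworkSpec(
            n_genes=200, n_communities=4, p_within=0.15, p_between=0.01,
            rng_seed=seed))
        seeds = gen_seed_set(planted, community_id=0, size=10, purity=1.0,
                             rng_seed=seed + 1)
        overlap = pd.DataFrame(
            [[0.6, 0.0, 0.0, 0.0],
             [0.4, 0.2, 0.0, 0.0],
             [0.0, 0.6, 0.0, 0.0],
             [0.2, 0.0, 0.2, 0.0],
             [0.0, 0.0, 0.0, 0.6],
             [0.0, 0.0, 0.0, 0.0]],
            index=["trait_A", "trait_B", "trait_C", "trait_D", "trait_E", "trait_F"],
            columns=[0, 1, 2, 3])
        sizes = {t: 25 for t in overlap.index}
        traits = gen_trait_sets(planted, overlap, sizes, rng_seed=seed + 2)
        net_path = out / "network.tsv"
        planted.network.write_edge_list(net_path)
        seeds_path = out / "seeds.txt"
        seeds_path.write_text("\n".join(seeds) + "\n")
        traits_path = out / "traits.gmt"
        write_gmt([TraitGeneSet(n, g, "synthetic") for n, g in traits.items()],
                  traits_path)
        (out / "planted_membership.tsv").write_text(
            "gene\tcommunity\n" + "".join(
                f"{g}\t{c}\n" for g, c in sorted(planted.membership.items())))
        paths |= {"network": str(net_path), "seeds": str(seeds_path),
                  "traits": str(traits_path)}
    if preset in {"mcq", "full"}:
        items = default_item_bank()
        grid_lo, grid_hi = -3.5, -0.7
        true_ks = rng.uniform(grid_lo, grid_hi, size=60)
        cohort = gen_cohort(true_ks, noise_temperature=2.0, items=items,
                            rng_seed=seed + 3)
        items_path = out / "items.csv"
        write_items_csv(items, items_path)
        resp_path = out / "responses.csv"
        cohort.to_csv(resp_path, index=False)
        paths |= {"items": str(items_path), "responses": str(resp_path)}
    return paths


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage in order and write the manifest.

    Returns the manifest dictionary.  A stage failure raises
    :class:`StageError` naming the stage; outputs written before the
    failure are flagged as partial in the manifest on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ddnetmap_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "rng_seed": config.rng_seed,
        "stages": {},
    }

    def _save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    current = "setup"
    try:
        if config.run_mcq:
            current = "score-mcq"
            items = read_items_csv(config.items_path) if config.items_path \
                else default_item_bank()
            responses = pd.read_csv(config.responses_path)
            model = DiscountModel(responses, items, QCThresholds(
                min_consistency=config.min_consistency,
                max_missing=config.max_missing))
            res = model.fit()
            res.to_tsv(out / "mcq_scores.tsv")
            manifest["stages"]["score_mcq"] = {
                "n_participants": len(res.table),
                "n_excluded": res.n_excluded,
            }
            log.info("score-mcq: %d participants, %d excluded",
                     len(res.table), res.n_excluded)

        selected: list[str] | None = None
        network: GeneNetwork | None = None
        prop_res = None
        if config.run_propagate:
            current = "propagate"
            network = read_edge_list(config.network_path)
            seeds = read_seed_list(config.seeds_path)
            model = NetworkPropagation(network, seeds, config.propagation_config())
            prop_res = model.fit()
            prop_res.to_tsv(out / "nps.tsv")
            selected = prop_res.selected()
            manifest["stages"]["propagate"] = {
                "n_genes": network.n_genes,
                "n_seeds": len(model.seed_genes),
                "n_seeds_dropped": len(model.dropped_seeds),
                "n_selected": len(selected),
                "n_zero_heat": int((prop_res.nps["flags"] == "zero_heat").sum()),
                "load_report": network.report.as_dict(),
            }
            log.info("propagate: %d genes selected at NPS > %s",
                     len(selected), config.nps_threshold)

        hier = None
        if config.run_hierarchy:
            current = "hierarchy"
            if network is None or selected is None:
                raise StageError("hierarchy stage requires the propagate stage")
            sub_genes = sorted(set(selected) | set(prop_res.model.seed_genes))
            sub = network.subnetwork(sub_genes)
            hcfg = config.hierarchy_config()
            sweep = sweep_resolutions(sub, hcfg)
            comms = persistent_communities(sweep, hcfg.jaccard_threshold,
                                           hcfg.persistence_min, hcfg.min_size)
            if not comms:
                raise StageError("no persistent communities found")
            hier = build_hierarchy(comms, hcfg.ci_threshold,
                                   all_genes=sub.genes)
            hier.write_tsv(out / "hierarchy_nodes.tsv", out / "hierarchy_edges.tsv")
            (out / "hierarchy.json").write_text(hier.to_json())
            manifest["stages"]["hierarchy"] = {
                "n_subnetwork_genes": sub.n_genes,
                "n_communities": len(hier.nodes),
                "n_edges": len(hier.edges),
            }
            log.info("hierarchy: %d persistent communities", len(hier.nodes))

        if config.run_enrich:
            current = "enrich"
            if hier is None:
                raise StageError("enrich stage requires the hierarchy stage")
            trait_sets = read_gmt(config.traits_path)
            universe = network.genes if config.universe == "network" \
                else sorted(set(selected) | set(prop_res.model.seed_genes))
            table = enrich_hierarchy(hier, trait_sets, universe,
                                     fdr_level=config.fdr_level)
            _write_enrichment_tsv(table, out / "enrichment.tsv")
            table.to_csv(out / "enrichment_heatmap.csv", index=False)
            if config.annotations_path:
                from .enrichment import annotate_communities
                terms = read_gmt(config.annotations_path)
                labels = annotate_communities(hier, terms, universe,
                                              config.fdr_level)
                manifest["stages"].setdefault("enrich", {})["n_annotated"] = len(labels)
                hier.write_tsv(out / "hierarchy_nodes.tsv",
                               out / "hierarchy_edges.tsv")
            manifest["stages"].setdefault("enrich", {}).update({
                "n_tests": len(table),
                "n_significant": int(table["significant"].sum()),
                "universe": config.universe,
                "universe_size": len(universe),
            })
            log.info("enrich: %d/%d significant at FDR %s",
                     int(table["significant"].sum()), len(table), config.fdr_level)
    except DDNetMapError:
        manifest["failed_stage"] = current
        manifest["partial_outputs"] = True
        _save_manifest()
        raise
    except Exception as exc:  # wrap foreign errors with the stage name
        manifest["failed_stage"] = current
        manifest["partial_outputs"] = True
        _save_manifest()
        raise StageError(f"stage {current} failed: {exc}") from exc
    _save_manifest()
    return manifest


def _write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    df = table.copy()
    for c in ("odds_ratio", "p_value", "q_value"):
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    df.to_csv(path, sep="\t", index=False)
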