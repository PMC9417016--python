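"""End-to-end pipeline: load/simulate -> condense -> metrics -> social map
-> zones -> clustering -> group maps -> focal subgraphs -> report bundle.

The pipeline is a pure function of (inputs, configuration, seed): repeated
runs write byte-identical artifacts.  Every table export is sorted and
float-formatted stably, and the JSON run report has sorted keys and no
timestamps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .aggregate import build_social_map, filter_social_map, focus_subgraph, group_social_maps
from .cluster import compare_clusters, hcpc, run_pca
from .condense import condense_collection, condensation_report
from .metrics import accumulation_curve, metrics_table
from .model import LEVELS, MapCollection, PipelineError, validate_collection
from .simulate import GeneratorConfig, generate_collection
from .zones import compare_zone_tables, zone_table, zone_summary


@dataclass
class PipelineConfig:
    """Everything a run needs; see the CLI or analysis scripts for examples."""

    out_dir: str = "results/run"
    seed: int = 0
    # either a generator spec ...
    simulate: GeneratorConfig | dict | None = None
    # ... or input files
    edge_list: str | None = None
    catalog: str | None = None
    metadata: str | None = None
    input_level: str = "raw"
    # analysis choices
    analysis_level: str = "component"
    display_level: str = "type"
    node_freq_min: float = 0.10
    edge_occ_min: int = 10
    focus_targets: list = field(default_factory=list)
    focus_edge_min: int = 2
    rank_mode: str = "raw"
    retain: float = 0.8
    k: object = "auto"
    test: str = "student"
    n_permutations: int = 100

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = GeneratorConfig(**self.simulate)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunResult:
    out_dir: Path
    report: dict
    collection: MapCollection
    scm: object
    zone_table: object
    pca: object
    clusters: object
    comparison: object


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> RunResult:
    out = Path(config.out_dir)
    report: dict = {"seed": config.seed}

    # -- load ---------------------------------------------------------
    truth = None
    if config.simulate is not None:
        gen = dataclasses.replace(config.simulate, seed=config.seed)
        collection, truth = _stage("simulate")(generate_collection, gen)
    elif config.edge_list is not None:
        collection = _stage("load")(
            rio.load_collection,
            config.edge_list,
            catalog_path=config.catalog,
            metadata_path=config.metadata,
            level=config.input_level,
        )
    else:
        raise PipelineError("stage 'load': neither input files nor a generator spec given")
    if collection.R == 0:
        raise PipelineError("stage 'load': no maps")

    validation = validate_collection(collection)
    if not validation.valid:
        raise PipelineError(f"stage 'validate': {validation}")
    out.mkdir(parents=True, exist_ok=True)

    # -- condense -----------------------------------------------------
    if LEVELS.index(collection.level) < LEVELS.index(config.analysis_level):
        condensed = _stage("condense")(condense_collection, collection, config.analysis_level)
        cond_report = condensation_report(collection, condensed)
        rio.write_tsv(cond_report.per_respondent, out / "condensation_report.tsv", index=False)
        report["condensation"] = {
            "unique_nodes_before": cond_report.unique_nodes_before,
            "unique_nodes_after": cond_report.unique_nodes_after,
        }
        collection = condensed
    report["R"] = collection.R
    report["level"] = collection.level

    # -- metrics ------------------------------------------------------
    table = _stage("metrics")(metrics_table, collection)
    rio.write_tsv(table, out / "metrics.tsv")
    curve = _stage("metrics")(accumulation_curve, collection, config.n_permutations, config.seed)
    rio.write_tsv(curve, out / "saturation.tsv", index=False)
    report["n_unique_components"] = int(curve["mean_unique"].iloc[-1])

    # -- social map ---------------------------------------------------
    scm = _stage("scm")(build_social_map, collection)
    rio.write_tsv(scm.nodes_frame(), out / "scm_nodes.tsv", index=False)
    rio.write_tsv(scm.edges_frame(), out / "scm_edges.tsv", index=False)
    display = collection
    if LEVELS.index(collection.level) < LEVELS.index(config.display_level):
        display = _stage("scm")(condense_collection, collection, config.display_level)
    scm_display = filter_social_map(
        build_social_map(display),
        node_freq_min=config.node_freq_min,
        edge_occ_min=config.edge_occ_min,
    )
    rio.write_graphml(scm_display, out / "scm_display.graphml", catalog=collection.catalog)
    rio.write_dot(scm_display, out / "scm_display.dot", catalog=collection.catalog)
    report["scm"] = {
        "nodes": scm.n_nodes,
        "edges": scm.n_edges,
        "display_nodes": scm_display.n_nodes,
        "display_edges": scm_display.n_edges,
    }

    # -- zones --------------------------------------------------------
    zt = _stage("zones")(zone_table, collection, "median", "median", config.rank_mode)
    zdf = zt.table.copy()
    zdf["type"] = [collection.catalog.map_label(c, collection.level, "type") for c in zdf.index]
    zdf["category"] = [collection.catalog.category_of(c, collection.level) for c in zdf.index]
    rio.write_tsv(zdf[["type", "category", "frequency", "median_rank", "zone"]], out / "zones.tsv")
    rio.write_tsv(zone_summary(zt, collection.catalog), out / "zone_summary.tsv", index=False)
    report["zones"] = {
        "freq_cut": zt.freq_cut,
        "rank_cut": zt.rank_cut,
        "counts": {k: int(v) for k, v in zt.counts().items()},
    }

    # -- clustering ---------------------------------------------------
    pca = _stage("cluster")(run_pca, table)
    rio.write_tsv(pca.scores, out / "pca_scores.tsv")
    rio.write_tsv(pca.loadings, out / "pca_loadings.tsv")
    eig = pd.DataFrame(
        {
            "eigenvalue": pca.eigenvalues,
            "percent_variance": pca.percent_variance,
            "cumulative_percent": pca.cumulative_percent,
        },
        index=pd.Index(pca.scores.columns, name="axis"),
    )
    rio.write_tsv(eig, out / "pca_eigenvalues.tsv")
    if pca.supplementary_coords is not None:
        rio.write_tsv(pca.supplementary_coords, out / "pca_supplementary.tsv")
    clusters = _stage("cluster")(hcpc, pca, config.retain, config.k, None, False, config.seed)
    rio.write_tsv(clusters.labels.to_frame(), out / "clusters.tsv")
    comparison = _stage("cluster")(compare_clusters, table, clusters, config.test)
    rio.write_tsv(comparison.stats, out / "cluster_comparison.tsv")
    rio.write_tsv(comparison.composition, out / "cluster_composition.tsv")
    report["clustering"] = {
        "k": clusters.k,
        "n_axes": clusters.n_axes,
        "percent_variance_first_two": [round(float(p), 6) for p in pca.percent_variance[:2]],
        "cluster_sizes": {
            str(lab): int((clusters.labels == lab).sum()) for lab in sorted(clusters.labels.unique())
        },
    }

    # -- group maps and zone overlap ----------------------------------
    labels = clusters.labels.to_dict()
    groups = _stage("groups")(group_social_maps, collection, labels)
    for lab, gmap in groups.items():
        rio.write_tsv(gmap.edges_frame(), out / f"group_{lab}_edges.tsv", index=False)
        rio.write_graphml(gmap, out / f"group_{lab}.graphml", catalog=collection.catalog)
    if clusters.k == 2:
        ids = clusters.labels
        sub_tables = {
            lab: zone_table(collection.subset(ids.index[ids == lab]), "median", "median", config.rank_mode)
            for lab in sorted(ids.unique())
        }
        labs = sorted(sub_tables)
        overlap = compare_zone_tables(sub_tables[labs[0]], sub_tables[labs[1]])
        rio.write_tsv(overlap.frame, out / "zone_overlap.tsv")
        core = overlap.frame.loc["core"]
        report["core_zone_overlap"] = {
            "n_shared": int(core["n_shared"]),
            "share_of_a": float(core["share_of_a"]),
            "share_of_b": float(core["share_of_b"]),
        }

    # -- focal subgraphs ----------------------------------------------
    for target in config.focus_targets:
        sub = _stage("focus")(
            focus_subgraph, scm, [target], config.focus_edge_min, collection.catalog
        )
        safe = str(target).replace("/", "_")
        rio.write_tsv(sub.edges_frame(), out / f"focus_{safe}_edges.tsv", index=False)
        rio.write_dot(sub, out / f"focus_{safe}.dot", catalog=collection.catalog)

    rio.write_json(report, out / "report.json")
    return RunResult(
        out_dir=out,
        report=report,
        collection=collection,
        scm=scm,
        zone_table=zt,
        pca=pca,
        clusters=clusters,
        comparison=comparison,
    )
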