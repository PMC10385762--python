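"""End-to-end orchestration: features -> graphs -> clusters -> mapping.

The product of a run is a *labelled target dataset*: every unlabeled
target window receives a source activity label, plus the intermediate
artifacts (network graphs, partitions, dependency graphs, mapping tables)
so each stage can be inspected independently.  The downstream classifier
is deliberately optional — the labelled dataset is model-agnostic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clusters import Partition, identify_core_clusters
from .dependency import DependencyGraph, build_dependency_graph, source_dependency_graph
from .features import (
    FeatureMatrix,
    extract_feature_matrix,
    read_recording_csv,
    reduce_dimensions,
)
from .mapping import (
    Mapping,
    direct_map,
    map_dependency_graphs,
    propagate_labels,
)
from .network import NetworkGraph, build_network_graph, default_k

__all__ = ["RunConfig", "StageError", "TransferResult", "transfer_labels", "run_actilabel"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full run.

    Unknown keys are rejected at construction so typos fail fast.
    """

    window_s: float = 2.0
    overlap_frac: float = 0.25
    sampling_rate: float | None = None
    triaxial_groups: dict | None = None
    features: str = "precomputed"          # or "raw"
    reduce_method: str = "none"            # or "umap"
    reduce_components: int = 2
    reduce_seed: int = 42
    k_fraction: float = 0.02
    k_min: int = 3
    k_dep_cap_fraction: float = 0.2
    min_fingerprint_edges_per_class: int = 2
    target_count: int | None = None        # default: number of source classes
    mapper: str = "actilabel"              # or "direct"
    classifier: str = "5nn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.features not in ("precomputed", "raw"):
            raise ValueError("features must be 'precomputed' or 'raw'")
        if self.mapper not in ("actilabel", "direct"):
            raise ValueError("mapper must be 'actilabel' or 'direct'")
        if not 0 < self.k_fraction < 1:
            raise ValueError("k_fraction must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping of keys to values")
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TransferResult:
    """Everything a run produces, stage by stage."""

    labels: pd.DataFrame               # predicted_label, fallback_flag per window
    partition: Partition
    isolated: list[int]
    graph_target: NetworkGraph
    dg_target: DependencyGraph
    dg_source: DependencyGraph
    mapping: Mapping                   # the mapping used for propagation
    vertex_mapping: Mapping | None = None
    edge_mapping: Mapping | None = None

    def mapping_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.mapping.pairs):
            j = self.mapping.pairs[cid]
            rows.append(
                {
                    "target_cluster": cid,
                    "source_label": self.dg_source.class_labels[j],
                    "cost": None,
                    "votes": None
                    if self.mapping.votes is None
                    else int(self.mapping.votes[cid, j]),
                }
            )
        return pd.DataFrame(rows)


def transfer_labels(
    source: FeatureMatrix, target: FeatureMatrix, config: RunConfig | None = None
) -> TransferResult:
    """Label every target observation by structural mapping to the source.

    Stages: target network graph (mutual k-NN, k a fraction of n); core
    cluster identification (CNM + alpha-merging down to the number of
    source classes); dependency graphs for both domains; two-tier Hungarian
    consensus mapping (or the DirectMap baseline); label propagation with
    nearest-centroid fallback for noise vertices and dummy-mapped clusters.

    Clustering and dependency statistics have opposite sparsity needs: the
    community structure is cleanest on a sparse graph (k around 2% of n),
    but the dependency fingerprint — inter-cluster cut mass — is empty on a
    graph that clean.  The pipeline therefore keeps the sparse graph for
    clustering and recomputes the dependency statistics on a densified
    graph, doubling k until the target dependency graph carries at least
    ``min_fingerprint_edges_per_class * m`` nonzero edge weights (or k
    reaches ``k_dep_cap_fraction * n``).  The source graph uses the same
    densified k so the two domains' weights are on a comparable scale.
    """
    config = config or RunConfig()
    if source.labels is None:
        raise StageError("source", "source feature matrix carries no labels")
    m = len(pd.unique(source.labels))
    target_count = config.target_count or m

    try:
        k_t = default_k(target.n, fraction=config.k_fraction, k_min=config.k_min)
        G_t = build_network_graph(target, k_t)
        logger.info("target network graph: n=%d k=%d |E|=%d", target.n, k_t, G_t.n_edges)
    except Exception as e:
        raise StageError("network_graph", str(e)) from e

    try:
        # CCI can only merge communities, never split them; if greedy
        # modularity finds fewer communities than activity classes, retry
        # on a sparser graph (smaller k yields more communities)
        while True:
            try:
                P_t, isolated = identify_core_clusters(G_t, target_count)
                break
            except ValueError:
                if k_t <= config.k_min:
                    raise
                k_t = max(config.k_min, k_t // 2)
                G_t = build_network_graph(target, k_t)
                logger.info("retrying clustering with sparser graph: k=%d", k_t)
        logger.info(
            "core clusters: %d (sizes %s), %d fallback vertices",
            P_t.n_clusters,
            [len(c) for c in P_t.clusters],
            len(isolated),
        )
    except Exception as e:
        raise StageError("core_clusters", str(e)) from e

    try:
        k_dep, dg_t = k_t, build_dependency_graph(G_t, P_t)
        min_nonzero = config.min_fingerprint_edges_per_class * m
        while (
            np.count_nonzero(dg_t.edge_weights) < min_nonzero
            and 2 * k_dep < config.k_dep_cap_fraction * target.n
        ):
            k_dep *= 2
            dg_t = build_dependency_graph(build_network_graph(target, k_dep), P_t)
        if k_dep != k_t:
            logger.info("dependency statistics densified to k=%d", k_dep)
        dg_s = source_dependency_graph(
            source, k=min(k_dep, source.n - 1)
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("dependency_graph", str(e)) from e

    M_v = M_e = None
    try:
        if config.mapper == "direct":
            M = direct_map(dg_t, dg_s, target, source)
        else:
            try:
                M_v, M_e, M = map_dependency_graphs(dg_t, dg_s)
            except ValueError:
                # no informative component matches (degenerate weights):
                # fall back to the vertex tier alone
                from .mapping import vertex_mapping

                M_v = M = vertex_mapping(dg_t, dg_s)
                M_e = None
                logger.warning("consensus had no votes; using vertex tier")
            logger.info(
                "mapping tier costs: vertex=%.4f edge=%.4f consensus=%.4f",
                M_v.total_cost, M_e.total_cost, M.total_cost,
            )
            logger.info("vote table:\n%s", M.votes)
    except Exception as e:
        raise StageError("label_mapping", str(e)) from e

    try:
        labels = propagate_labels(P_t, M, dg_s, target, extra_vertices=isolated)
    except Exception as e:
        raise StageError("propagate_labels", str(e)) from e

    return TransferResult(
        labels=labels,
        partition=P_t,
        isolated=isolated,
        graph_target=G_t,
        dg_target=dg_t,
        dg_source=dg_s,
        mapping=M,
        vertex_mapping=M_v,
        edge_mapping=M_e,
    )


def _load_features(path, config: RunConfig) -> FeatureMatrix:
    if config.features == "raw":
        rec = read_recording_csv(
            path,
            sampling_rate=config.sampling_rate,
            triaxial_groups=config.triaxial_groups,
        )
        return extract_feature_matrix(rec, config.window_s, config.overlap_frac)
    return FeatureMatrix.from_csv(path)


def run_actilabel(
    source_csv, target_csv, config: RunConfig | None = None, out_dir=None
) -> TransferResult:
    """File-level entry point: read CSVs, run the pipeline, write artifacts.

    Output files (all deterministic for fixed config + inputs):
    ``labeled_target.csv`` (input columns + predicted_label +
    fallback_flag), ``mapping.csv``, ``clusters.csv``, network edge list,
    dependency-graph vertex/edge tables for both domains, and
    ``provenance.json`` with the resolved configuration.
    """
    config = config or RunConfig()
    try:
        source = _load_features(source_csv, config)
        target = _load_features(target_csv, config)
        if target.labels is not None:
            # hidden truth must not leak into the run
            target = FeatureMatrix(
                X=target.X,
                feature_names=list(target.feature_names),
                window_start=target.window_start,
                window_end=target.window_end,
            )
        if config.reduce_method != "none":
            source = reduce_dimensions(
                source, config.reduce_components, config.reduce_seed,
                method=config.reduce_method,
            )
            target = reduce_dimensions(
                target, config.reduce_components, config.reduce_seed,
                method=config.reduce_method,
            )
    except StageError:
        raise
    except Exception as e:
        raise StageError("input", str(e)) from e

    result = transfer_labels(source, target, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.features == "raw":
            # predictions are per window; attach them to the window table
            labelled = target.to_frame()
        else:
            labelled = pd.read_csv(target_csv)
        labelled["predicted_label"] = result.labels["predicted_label"].to_numpy()
        labelled["fallback_flag"] = result.labels["fallback_flag"].to_numpy()
        labelled.to_csv(out / "labeled_target.csv", index=False)
        result.mapping_frame().to_csv(out / "mapping.csv", index=False)
        result.partition.to_frame().to_csv(out / "clusters.csv", index=False)
        result.graph_target.write_edge_csv(out / "target_network_edges.csv")
        result.dg_target.vertex_frame().to_csv(out / "dg_target_vertices.csv", index=False)
        result.dg_target.edge_frame().to_csv(out / "dg_target_edges.csv", index=False)
        result.dg_source.vertex_frame().to_csv(out / "dg_source_vertices.csv", index=False)
        result.dg_source.edge_frame().to_csv(out / "dg_source_edges.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "config": config.as_dict(),
                    "source": str(source_csv),
                    "target": str(target_csv),
                    "n_source": source.n,
                    "n_target": target.n,
                    "n_isolated": len(result.isolated),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
    return result
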