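"""Merging single-source networks into one multi-layer network.

Each input network becomes a *layer*.  Nodes with the same canonical
(namespace, id) pair are merged and their layer sets unioned; the same
interaction curated in several layers collapses to a single edge carrying the
union of layers and the maximum weight (max, not sum, so repeated curation of
one interaction does not inflate connectivity).  A node typed as two different
modalities across layers is a hard error, because downstream diffusion
backgrounds and evaluation negatives are modality-restricted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .exceptions import DegenerateInputError, MergeConflictError, NetpropError, NetworkFormatError
from .network import DEFAULT_MODALITY, Network, read_network, split_namespace
from .scores import LabelInput

logger = logging.getLogger(__name__)


@dataclass
class LayerSpec:
    """One source network of a multi-layer collection."""

    layer_name: str
    source_path: str | Path
    format: str | None = None
    namespace_map: dict[str, str] = field(default_factory=dict)


@dataclass
class MergeReport:
    """Bookkeeping of a merge: per-layer sizes, dedup and sharing counts."""

    per_layer_nodes: dict[str, int]
    per_layer_edges: dict[str, int]
    merged_nodes: int = 0
    merged_edges: int = 0
    shared_nodes: int = 0  # sum of per-layer node counts minus merged count
    deduplicated_edges: int = 0

    def as_dict(self) -> dict:
        return {
            "per_layer_nodes": self.per_layer_nodes,
            "per_layer_edges": self.per_layer_edges,
            "merged_nodes": self.merged_nodes,
            "merged_edges": self.merged_edges,
            "shared_nodes": self.shared_nodes,
            "deduplicated_edges": self.deduplicated_edges,
        }


def _apply_namespace_map(node_id: str, nsmap: dict[str, str]) -> str:
    ns, cid = split_namespace(node_id)
    if ns in nsmap:
        local = cid.split(":", 1)[1] if ":" in cid else cid
        return f"{nsmap[ns]}:{local}"
    return cid


def load_collection(path: str | Path) -> list[LayerSpec]:
    """Read a collection YAML: a list of {layer, path, format, namespace_map}."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list) or not raw:
        raise NetworkFormatError(f"{path}: collection YAML must be a non-empty list of layer specs")
    specs = []
    base = Path(path).parent
    for i, item in enumerate(raw):
        if "layer" not in item or "path" not in item:
            raise NetworkFormatError(f"{path}: layer spec #{i + 1} needs 'layer' and 'path' keys")
        source = Path(item["path"])
        if not source.is_absolute():
            source = base / source
        specs.append(
            LayerSpec(
                layer_name=str(item["layer"]),
                source_path=source,
                format=item.get("format"),
                namespace_map=dict(item.get("namespace_map") or {}),
            )
        )
    return specs


def merge_layer_networks(layers: list[tuple[str, Network]]) -> tuple[Network, MergeReport]:
    """Merge already-loaded ``(layer_name, Network)`` pairs."""
    if not layers:
        raise NetpropError("merge requires at least one layer")
    names = [name for name, _ in layers]
    if len(set(names)) != len(names):
        raise NetpropError(f"layer names must be unique, got {names}")

    report = MergeReport(per_layer_nodes={}, per_layer_edges={})
    g = nx.Graph()
    modality_source: dict[str, tuple[str, str]] = {}
    total_nodes = 0
    # deterministic merge: sort layers by name so the result is order-invariant
    for layer_name, net in sorted(layers, key=lambda item: item[0]):
        report.per_layer_nodes[layer_name] = net.n_nodes
        report.per_layer_edges[layer_name] = net.n_edges
        total_nodes += net.n_nodes
        for node, attrs in net.graph.nodes(data=True):
            modality = attrs["modality"]
            if node in g:
                g.nodes[node]["layers"].add(layer_name)
                prev_mod, prev_layer = modality_source[node]
                if modality != DEFAULT_MODALITY:
                    if prev_mod not in (DEFAULT_MODALITY, modality):
                        raise MergeConflictError(
                            f"node {node!r} is typed {prev_mod!r} in layer {prev_layer!r} "
                            f"but {modality!r} in layer {layer_name!r}"
                        )
                    g.nodes[node]["modality"] = modality
                    modality_source[node] = (modality, layer_name)
            else:
                g.add_node(node, namespace=attrs["namespace"], modality=modality,
                           layers={layer_name})
                modality_source[node] = (modality, layer_name)
        for u, v, attrs in net.graph.edges(data=True):
            if g.has_edge(u, v):
                report.deduplicated_edges += 1
                g[u][v]["weight"] = max(g[u][v]["weight"], attrs["weight"])
                g[u][v]["layers"].add(layer_name)
            else:
                g.add_edge(u, v, weight=attrs["weight"], layers={layer_name})
    if report.deduplicated_edges:
        logger.warning("merge collapsed %d duplicate cross-layer edge(s) keeping max weight",
                       report.deduplicated_edges)
    merged = Network.from_graph(g)
    report.merged_nodes = merged.n_nodes
    report.merged_edges = merged.n_edges
    report.shared_nodes = total_nodes - merged.n_nodes
    return merged, report


def merge_networks(specs: list[LayerSpec]) -> tuple[Network, MergeReport]:
    """Load every layer spec from disk and merge into a multi-layer network."""
    if not specs:
        raise NetpropError("merge requires at least one layer spec")
    layers = []
    for spec in specs:
        net = read_network(spec.source_path, spec.format, layer=spec.layer_name)
        if spec.namespace_map:
            relabel = {
                node: _apply_namespace_map(node, spec.namespace_map) for node in net.graph.nodes
            }
            net = Network.from_graph(
                nx.relabel_nodes(net.graph, relabel, copy=True), default_layer=spec.layer_name
            )
            for node in net.graph.nodes:
                ns, _ = split_namespace(node)
                net.graph.nodes[node]["namespace"] = ns
        layers.append((spec.layer_name, net))
    return merge_layer_networks(layers)


def subgraph_by_layers(net: Network, layers: set[str]) -> Network:
    """Restrict a multi-layer network to the nodes/edges of the given layers.

    Layer sets of the retained nodes/edges are intersected with the request,
    so selecting one layer of a merge recovers that source network.
    """
    layers = set(layers)
    if not layers:
        raise DegenerateInputError("empty layer selection")
    known = net.layers
    unknown = layers - known
    if unknown:
        raise NetpropError(f"unknown layer(s) {sorted(unknown)}; known: {sorted(known)}")
    g = nx.Graph()
    for node, attrs in net.graph.nodes(data=True):
        keep = attrs["layers"] & layers
        if keep:
            g.add_node(node, namespace=attrs["namespace"], modality=attrs["modality"], layers=keep)
    for u, v, attrs in net.graph.edges(data=True):
        keep = attrs["layers"] & layers
        if keep and u in g and v in g:
            g.add_edge(u, v, weight=attrs["weight"], layers=keep)
    return Network.from_graph(g)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a 2-column source-id -> canonical-id table (TSV, or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) != 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 fields")
            mapping[fields[0]] = fields[1]
    if not mapping:
        raise NetworkFormatError(f"{path}: empty identifier mapping")
    return mapping


def map_identifiers(labels: LabelInput, mapping: dict[str, str]) -> LabelInput:
    """Re-key a label input through an identifier mapping.

    Many-to-one collisions keep the value of largest absolute magnitude
    (logged); unmapped keys are retained verbatim so they surface later as
    unmatched entities rather than vanishing.
    """
    if not mapping:
        raise NetpropError("identifier mapping is empty")
    out: dict[str, float] = {}
    collisions = 0
    for key, value in labels.entries.items():
        new_key = mapping.get(key, key)
        if new_key in out:
            collisions += 1
            if abs(value) > abs(out[new_key]):
                out[new_key] = value
        else:
            out[new_key] = value
    if collisions:
        logger.warning("identifier mapping produced %d collision(s); kept max |value|", collisions)
    return LabelInput(out, labels.declared_type)
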