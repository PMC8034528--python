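"""Network container, file I/O and Laplacian construction.

The :class:`Network` is an undirected, weighted graph whose nodes carry a
namespace (identifier authority, e.g. ``ncbigene``), a modality (gene,
metabolite, mirna, ...) and the set of source layers they appear in.  A frozen
lexicographic node ordering defines the row/column order of every matrix view
(adjacency, Laplacian, kernel), so vectors and matrices produced anywhere in
the package are mutually aligned by construction.

Supported on-disk formats: edge list (TSV/CSV), GraphML, GML and node-link
JSON.  Edge lists are lossy (no isolated nodes, no node annotations); the
other three round-trip the full annotation set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .exceptions import (
    DegenerateInputError,
    NetworkFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

FORMATS = ("edgelist", "graphml", "gml", "nodelink-json")

_EXTENSION_FORMATS = {
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".edgelist": "edgelist",
    ".csv": "edgelist",
    ".graphml": "graphml",
    ".gml": "gml",
    ".json": "nodelink-json",
}

DEFAULT_MODALITY = "unspecified"
DEFAULT_NAMESPACE = "unknown"
_LAYER_SEP = "|"


def split_namespace(node_id: str) -> tuple[str, str]:
    """Return ``(namespace, canonical_id)`` for a raw identifier.

    Identifiers written as ``namespace:local`` keep that namespace; bare
    identifiers get namespace ``unknown`` and keep their bare form as the
    canonical id (so files without CURIE-style ids round-trip unchanged).
    """
    if ":" in node_id:
        return node_id.split(":", 1)[0], node_id
    return DEFAULT_NAMESPACE, node_id


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class Network:
    """Validated undirected network with a frozen matrix ordering."""

    graph: nx.Graph
    node_order: tuple[str, ...]

    # -- construction -----------------------------------------------------

    @classmethod
    def from_graph(
        cls,
        g: nx.Graph,
        *,
        default_layer: str = "base",
        default_modality: str = DEFAULT_MODALITY,
    ) -> "Network":
        """Validate an arbitrary networkx graph into a :class:`Network`.

        Directed edges are symmetrized (union, max weight), parallel edges
        collapse to the max weight, self-loops are dropped; all three events
        are counted and logged.
        """
        clean = nx.Graph()
        for node, attrs in g.nodes(data=True):
            node = str(node)
            ns, cid = split_namespace(node)
            layers = attrs.get("layers", {default_layer})
            if isinstance(layers, str):
                layers = set(layers.split(_LAYER_SEP)) if layers else set()
            clean.add_node(
                cid,
                namespace=attrs.get("namespace", ns),
                modality=attrs.get("modality", default_modality),
                layers=set(layers),
            )

        n_self, n_dup = 0, 0
        edges: dict[tuple[str, str], tuple[float, set[str]]] = {}
        for u, v, attrs in g.edges(data=True):
            u, v = split_namespace(str(u))[1], split_namespace(str(v))[1]
            if u == v:
                n_self += 1
                continue
            w = float(attrs.get("weight", 1.0))
            if not np.isfinite(w) or w < 0:
                raise ValidationError(
                    f"edge ({u}, {v}) has invalid weight {w!r}; weights must be finite and >= 0"
                )
            layers = attrs.get("layers", attrs.get("layer", default_layer))
            if isinstance(layers, str):
                layers = set(layers.split(_LAYER_SEP)) if layers else set()
            layers = set(layers)
            key = _edge_key(u, v)
            if key in edges:
                n_dup += 1
                w0, l0 = edges[key]
                edges[key] = (max(w0, w), l0 | layers)
            else:
                edges[key] = (w, layers)
        for (u, v), (w, layers) in edges.items():
            for endpoint in (u, v):
                if endpoint not in clean:
                    raise ValidationError(f"edge ({u}, {v}) references unknown node {endpoint!r}")
            clean.add_edge(u, v, weight=w, layers=layers)
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        if n_dup:
            logger.warning("collapsed %d duplicate/antiparallel edge(s) keeping max weight", n_dup)

        return cls(graph=clean, node_order=tuple(sorted(clean.nodes)))

    # -- basic views -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def layers(self) -> set[str]:
        out: set[str] = set()
        for _, _, attrs in self.graph.edges(data=True):
            out |= attrs["layers"]
        for _, attrs in self.graph.nodes(data=True):
            out |= attrs["layers"]
        return out

    def modality_of(self, node: str) -> str:
        return self.graph.nodes[node]["modality"]

    def nodes_by_modality(self, modality: str) -> list[str]:
        return [n for n in self.node_order if self.graph.nodes[n]["modality"] == modality]

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency in ``node_order``."""
        return nx.to_numpy_array(self.graph, nodelist=list(self.node_order), weight="weight")

    def edge_set(self) -> dict[tuple[str, str], float]:
        return {
            _edge_key(u, v): attrs["weight"] for u, v, attrs in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        """Order-insensitive equality on node ids and weighted edges."""
        if not isinstance(other, Network):
            return NotImplemented
        return set(self.graph.nodes) == set(other.graph.nodes) and self.edge_set() == other.edge_set()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges}, layers={sorted(self.layers)})"


def build_network(
    edges: Iterable[tuple],
    nodes: Iterable[str] = (),
    *,
    layer: str = "base",
    modalities: Mapping[str, str] | None = None,
) -> Network:
    """Convenience constructor from ``(u, v[, weight])`` tuples."""
    g = nx.Graph()
    for node in nodes:
        g.add_node(str(node))
    for edge in edges:
        u, v = edge[0], edge[1]
        w = float(edge[2]) if len(edge) > 2 else 1.0
        if g.has_edge(u, v):
            w = max(w, g[u][v]["weight"])
        g.add_edge(str(u), str(v), weight=w)
    if modalities:
        for node, modality in modalities.items():
            if node in g:
                g.nodes[node]["modality"] = modality
    return Network.from_graph(g, default_layer=layer)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    fmt = _EXTENSION_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise NetworkFormatError(
            f"cannot infer network format from extension {path.suffix!r}; pass format explicitly"
        )
    return fmt


def _parse_edgelist(path: Path) -> nx.Graph:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    g = nx.Graph()
    dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            if len(fields) > 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 or 3 {sep!r}-separated fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if not u or not v:
                raise NetworkFormatError(f"{path}:{lineno}: empty node identifier")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from exc
            else:
                w = 1.0
            if g.has_edge(u, v):
                dup += 1
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
    if dup:
        logger.warning("%s: %d duplicate edge line(s) collapsed keeping max weight", path, dup)
    return g


def read_network(path: str | Path, format: str | None = None, *, layer: str = "base") -> Network:
    """Read and validate a network file.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``edgelist``, ``graphml``, ``gml``, ``nodelink-json``;
        inferred from the file extension when omitted.
    layer:
        Layer name assigned to nodes/edges that carry no layer annotation.
    """
    path = Path(path)
    if not path.exists():
        raise NetworkFormatError(f"network file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise NetworkFormatError(f"unknown network format {fmt!r}; supported: {FORMATS}")
    try:
        if fmt == "edgelist":
            g = _parse_edgelist(path)
        elif fmt == "graphml":
            g = nx.read_graphml(path)
        elif fmt == "gml":
            g = nx.read_gml(path)
        else:
            with open(path) as handle:
                data = json.load(handle)
            g = nx.node_link_graph(data, edges="links")
    except NetworkFormatError:
        raise
    except Exception as exc:
        raise NetworkFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return Network.from_graph(g, default_layer=layer)


def _sanitized_copy(net: Network) -> nx.Graph:
    """Copy with set-valued attributes flattened to strings (for serializers)."""
    g = nx.Graph()
    for node, attrs in net.graph.nodes(data=True):
        g.add_node(
            node,
            namespace=attrs["namespace"],
            modality=attrs["modality"],
            layers=_LAYER_SEP.join(sorted(attrs["layers"])),
        )
    for u, v, attrs in net.graph.edges(data=True):
        g.add_edge(u, v, weight=attrs["weight"], layers=_LAYER_SEP.join(sorted(attrs["layers"])))
    return g


def write_network(net: Network, path: str | Path, format: str | None = None) -> None:
    """Write a network; ``read_network(write_network(net))`` reproduces it.

    The edge-list format stores only weighted edges: isolated nodes and all
    node annotations are lost (a warning is emitted).  GraphML, GML and
    node-link JSON are faithful.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise NetworkFormatError(f"unknown network format {fmt!r}; supported: {FORMATS}")
    if fmt == "edgelist":
        isolated = [n for n in net.node_order if net.graph.degree(n) == 0]
        if isolated:
            logger.warning(
                "edge-list output is lossy: %d isolated node(s) will not survive a round trip",
                len(isolated),
            )
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        with open(path, "w") as handle:
            handle.write(f"# source{sep}target{sep}weight\n")
            for u, v in sorted(_edge_key(a, b) for a, b in net.graph.edges):
                handle.write(f"{u}{sep}{v}{sep}{net.graph[u][v]['weight']!r}\n")
            for node in isolated:
                handle.write(f"{node}\n")
        return
    g = _sanitized_copy(net)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gml":
        nx.write_gml(g, path)
    else:
        with open(path, "w") as handle:
            json.dump(nx.node_link_data(g, edges="links"), handle, indent=1)


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------


@dataclass
class LaplacianMatrix:
    """Dense graph Laplacian bound to a node ordering.

    ``variant`` is ``"unnormalized"`` (L = D - A, rows sum to zero) or
    ``"normalized"`` (L~ = I - D^{-1/2} A D^{-1/2}, spectrum in [0, 2]).
    """

    matrix: np.ndarray
    variant: str
    node_order: tuple[str, ...] = field(default_factory=tuple)


def laplacian(net: Network, variant: str = "unnormalized", *, isolated: str = "identity") -> LaplacianMatrix:
    """Construct the graph Laplacian of a validated network.

    Parameters
    ----------
    variant:
        ``"unnormalized"`` or ``"normalized"``.
    isolated:
        Policy for zero-degree nodes under the normalized variant:
        ``"identity"`` (default) leaves them with the identity row/column
        (self-similarity one, no coupling); ``"strict"`` raises instead.
    """
    if variant not in ("unnormalized", "normalized"):
        raise ValueError(f"unknown Laplacian variant {variant!r}")
    a = net.adjacency()
    deg = a.sum(axis=1)
    if variant == "unnormalized":
        mat = np.diag(deg) - a
    else:
        if isolated not in ("identity", "strict"):
            raise ValueError(f"unknown isolated-node policy {isolated!r}")
        zero = deg == 0
        if zero.any() and isolated == "strict":
            offenders = [net.node_order[i] for i in np.flatnonzero(zero)]
            raise DegenerateInputError(
                f"normalized Laplacian undefined for isolated nodes (strict policy): {offenders}"
            )
        with np.errstate(divide="ignore"):
            dinv = np.where(zero, 0.0, 1.0 / np.sqrt(np.where(zero, 1.0, deg)))
        mat = np.eye(len(deg)) - dinv[:, None] * a * dinv[None, :]
    mat = (mat + mat.T) / 2.0
    return LaplacianMatrix(matrix=mat, variant=variant, node_order=net.node_order)
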