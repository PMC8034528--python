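"""Deterministic synthetic networks and label sets for tests and demos.

These generators stand in for real pathway-database content: they produce
validated :class:`~netprop.network.Network` objects with a planted signal
whose recovery a diffusion method can be scored on.  The planted-community
generator emulates the one property diffusion exploits — label-sharing
neighbourhoods are denser than background — and the multi-layer mode slices
the edge set into layers at random, so each single layer is an edge-depleted
view of the same underlying biology, mirroring how individual pathway
databases each cover part of an integrated network.

Everything is driven by one explicit seed per call; the same spec always
yields byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import NetpropError, ParameterError
from .network import Network
from .scores import LabelInput

GENERATORS = ("erdos_renyi", "preferential_attachment", "planted_community", "toy")

#: Default planted-community condition: two 25-node blocks, dense inside
#: (p_in = 0.3), sparse between (p_out = 0.02).
PLANTED_DEFAULTS = {"sizes": (25, 25), "p_in": 0.3, "p_out": 0.02}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic network; the seed fully determines the output."""

    generator: str = "planted_community"
    n: int = 50
    params: dict = field(default_factory=dict)
    n_layers: int = 1
    seed: int = 0


@dataclass
class SyntheticNetwork:
    """A generated network plus, when planted, the ground-truth membership."""

    network: Network
    ground_truth: dict[str, int] | None = None  # node -> community index

    def community(self, index: int) -> set[str]:
        if self.ground_truth is None:
            raise NetpropError("this fixture has no planted communities")
        return {node for node, c in self.ground_truth.items() if c == index}


def _node_name(i: int, width: int) -> str:
    return f"v{i:0{width}d}"


def _slice_layers(g: nx.Graph, n_layers: int, rng: np.random.Generator) -> None:
    edges = sorted(g.edges)
    assignment = rng.integers(0, n_layers, size=len(edges))
    for (u, v), a in zip(edges, assignment):
        g[u][v]["layers"] = {f"L{a + 1}"}
    for node in g.nodes:
        g.nodes[node]["layers"] = set().union(
            *(g[node][nbr]["layers"] for nbr in g[node]), set()
        ) or {"L1"}


def generate_network(spec: FixtureSpec) -> SyntheticNetwork:
    """Generate a validated synthetic network from a fixture spec.

    ``planted_community`` uses a stochastic block model and also returns the
    ground-truth block membership.  With ``n_layers > 1`` every edge is
    assigned to one of ``n_layers`` random layers.
    """
    if spec.generator not in GENERATORS:
        raise ParameterError(f"unknown generator {spec.generator!r}; choose one of {GENERATORS}")
    if spec.n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    rng = np.random.default_rng(spec.seed)
    ground_truth: dict[str, int] | None = None

    if spec.generator == "toy":
        # two triangles joined by a bridge: the smallest graph with community
        # structure, handy for worked examples
        g = nx.Graph()
        g.add_edges_from(
            [("v0", "v1"), ("v1", "v2"), ("v0", "v2"),
             ("v2", "v3"), ("v3", "v4"), ("v4", "v5"), ("v3", "v5")]
        )
    elif spec.generator == "erdos_renyi":
        if spec.n < 1:
            raise ParameterError("n must be >= 1")
        p = float(spec.params.get("p", 0.1))
        g = nx.gnp_random_graph(spec.n, p, seed=int(rng.integers(2**31)))
    elif spec.generator == "preferential_attachment":
        m = int(spec.params.get("m", 2))
        if spec.n <= m:
            raise ParameterError(f"preferential attachment needs n > m (n={spec.n}, m={m})")
        g = nx.barabasi_albert_graph(spec.n, m, seed=int(rng.integers(2**31)))
    else:  # planted_community
        sizes = list(spec.params.get("sizes", PLANTED_DEFAULTS["sizes"]))
        p_in = float(spec.params.get("p_in", PLANTED_DEFAULTS["p_in"]))
        p_out = float(spec.params.get("p_out", PLANTED_DEFAULTS["p_out"]))
        if sum(sizes) < 2 or (p_in == 0 and p_out == 0):
            raise ParameterError("planted-community parameters imply an empty graph")
        probs = [[p_in if i == j else p_out for j in range(len(sizes))] for i in range(len(sizes))]
        g = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))
        blocks = [b for b, size in enumerate(sizes) for _ in range(size)]
        width = len(str(sum(sizes) - 1))
        ground_truth = {_node_name(i, width): blocks[i] for i in range(sum(sizes))}

    if spec.generator != "toy":
        width = len(str(g.number_of_nodes() - 1)) if g.number_of_nodes() else 1
        g = nx.relabel_nodes(g, {i: _node_name(i, width) for i in g.nodes})
    g = nx.Graph(g)  # strip block-model metadata / ensure simple graph
    for _, _, attrs in g.edges(data=True):
        attrs.clear()
        attrs["weight"] = 1.0
    for _, attrs in g.nodes(data=True):
        attrs.clear()
        attrs["modality"] = "gene"
    if spec.n_layers > 1:
        _slice_layers(g, spec.n_layers, rng)
    net = Network.from_graph(g)
    return SyntheticNetwork(network=net, ground_truth=ground_truth)


def generate_labels(
    net: Network,
    ground_truth: set[str],
    noise_flip_prob: float = 0.0,
    seed: int = 0,
) -> LabelInput:
    """Binary labels from a ground-truth positive set with membership noise.

    Every node's membership is independently flipped with probability
    ``noise_flip_prob`` (< 0.5), so labels are a noisy readout of the planted
    signal.  The returned input lists the resulting positives.
    """
    ground_truth = set(ground_truth)
    unknown = ground_truth - set(net.node_order)
    if unknown:
        raise NetpropError(f"ground-truth nodes not in network: {sorted(unknown)[:5]}")
    if not 0 <= noise_flip_prob < 0.5:
        raise ParameterError(f"noise_flip_prob must lie in [0, 0.5), got {noise_flip_prob}")
    rng = np.random.default_rng(seed)
    flips = rng.random(net.n_nodes) < noise_flip_prob
    positives = {
        node
        for node, flip in zip(net.node_order, flips)
        if (node in ground_truth) != bool(flip)
    }
    return LabelInput.from_ids(sorted(positives))
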