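"""Label encoding and the four diffusion scores: raw, ml, gm and z.

A diffusion score is the kernel-vector product ``f = K @ y`` for some encoding
``y`` of the user's labels over the network's node order:

* ``raw`` / ``z``: matched entities carry their value (1 for bare lists),
  everything else 0.  ``z`` additionally standardizes each ``f_i`` by its
  exact first two moments under uniform permutation of the labels — the
  statistically normalized score, which corrects for the bias of raw
  diffusion toward high-degree nodes.
* ``ml``: +1 for positives, -1 for explicit negatives, 0 for unlabeled.
* ``gm``: like ml, but unlabeled nodes carry the class-imbalance constant
  ``k = (n+ - n-) / (n+ + n-)`` instead of 0.

The permutation-null moments for z are closed-form.  Writing
``S1_i = sum_j K_ij`` and ``S2_i = sum_j K_ij^2`` over the background of
``n`` nodes:

    E[f_i]   = S1_i * mean(y)
    Var[f_i] = (n*sum(y^2) - sum(y)^2) * (n*S2_i - S1_i^2) / (n^2 * (n-1))

A seeded Monte-Carlo estimator of the same null is provided for
cross-checking; the analytic form is always the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    EmptyOverlapError,
    NetpropError,
    NetworkFormatError,
    ParameterError,
)
from .kernels import KernelMatrix
from .network import Network

logger = logging.getLogger(__name__)

SCORE_METHODS = ("raw", "ml", "gm", "z")

_VAR_FLOOR = 1e-300  # below this the permutation null is treated as degenerate


@dataclass
class LabelInput:
    """User-supplied entity -> value mapping before network alignment.

    ``declared_type`` is ``"binary"`` (values in {0, 1}; bare entity lists
    coerce to 1) or ``"quantitative"`` (any finite reals).
    """

    entries: dict[str, float]
    declared_type: str = "binary"

    def __post_init__(self) -> None:
        if self.declared_type not in ("binary", "quantitative"):
            raise ParameterError(f"unknown label type {self.declared_type!r}")
        for key, value in self.entries.items():
            value = float(value)
            if not np.isfinite(value):
                raise ParameterError(f"label value for {key!r} is not finite")
            if self.declared_type == "binary" and value not in (0.0, 1.0):
                raise ParameterError(
                    f"binary label input contains non-binary value {value!r} for {key!r}"
                )
            self.entries[key] = value

    @classmethod
    def from_ids(cls, ids) -> "LabelInput":
        """Bare entity list: every listed entity counts as a positive (1)."""
        return cls({str(i): 1.0 for i in ids}, "binary")


def read_labels(path: str | Path) -> LabelInput:
    """Read a label CSV/TSV: column 1 entity id, optional column 2 value.

    One-column files are entity lists (all values 1, binary).  Two-column
    files are binary if every value is 0/1 and quantitative otherwise.
    A ``#`` prefix marks comment lines.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    entries: dict[str, float] = {}
    saw_value = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) == 1:
                entries[fields[0]] = 1.0
            elif len(fields) == 2:
                saw_value = True
                try:
                    entries[fields[0]] = float(fields[1])
                except ValueError as exc:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: value {fields[1]!r} is not a number"
                    ) from exc
            else:
                raise NetworkFormatError(f"{path}:{lineno}: expected 1 or 2 fields")
    if not entries:
        raise NetworkFormatError(f"{path}: no label entries found")
    binary = (not saw_value) or set(entries.values()) <= {0.0, 1.0}
    return LabelInput(entries, "binary" if binary else "quantitative")


@dataclass
class EncodedLabels:
    """A label vector aligned to a network's node order."""

    y: np.ndarray
    matched: set[str]
    unmatched: list[str]
    background: str  # "all-nodes" or "modality:<name>"
    method: str
    node_order: tuple[str, ...]
    background_mask: np.ndarray = field(repr=False, default=None)


def encode_labels(
    labels: LabelInput,
    net: Network,
    method: str = "raw",
    *,
    negatives: LabelInput | set | None = None,
    background_modality: str | None = None,
) -> EncodedLabels:
    """Align a label input onto a network as the score vector ``y``.

    Unmatched entities are reported (``EncodedLabels.unmatched``) and warned
    about, never dropped silently; only a fully empty overlap is an error.
    Explicit negatives apply to ml/gm; without them all matched entities are
    positives.  ``background_modality`` restricts the encoding background
    (and the z permutation null downstream) to nodes of one modality.
    """
    if method not in SCORE_METHODS:
        raise ParameterError(f"unknown score method {method!r}; choose one of {SCORE_METHODS}")
    if labels.declared_type == "quantitative" and method in ("ml", "gm"):
        raise ParameterError(
            f"quantitative label values are incompatible with the {method} encoding; "
            "use raw or z, or binarize the input"
        )
    node_set = set(net.node_order)
    index = {node: i for i, node in enumerate(net.node_order)}
    if background_modality is None:
        mask = np.ones(net.n_nodes, dtype=bool)
        background = "all-nodes"
    else:
        mask = np.array(
            [net.modality_of(node) == background_modality for node in net.node_order], dtype=bool
        )
        if not mask.any():
            raise DegenerateInputError(f"no nodes of modality {background_modality!r} in network")
        background = f"modality:{background_modality}"
    in_background = lambda e: e in node_set and mask[index[e]]

    if isinstance(negatives, LabelInput):
        neg_ids = {e for e, v in negatives.entries.items() if v != 0}
    else:
        neg_ids = set(negatives) if negatives else set()

    matched = {e for e in labels.entries if in_background(e)}
    matched_neg = {e for e in neg_ids if in_background(e)}
    unmatched = sorted((set(labels.entries) | neg_ids) - matched - matched_neg)
    if unmatched:
        logger.warning("%d input entit(ies) not matched to the network: %s",
                       len(unmatched), ", ".join(unmatched[:10]))
    if not matched and not matched_neg:
        raise EmptyOverlapError("no input entity maps onto the network background")

    y = np.zeros(net.n_nodes)
    if method in ("raw", "z"):
        for entity in matched:
            y[index[entity]] = labels.entries[entity]
    else:
        positives = {e for e in matched if labels.entries[e] != 0} - matched_neg
        if method == "gm":
            n_pos, n_neg = len(positives), len(matched_neg)
            if n_pos + n_neg == 0:
                raise DegenerateInputError("gm bias constant undefined with no labeled nodes")
            bias = (n_pos - n_neg) / (n_pos + n_neg)
            y[mask] = bias
        for entity in positives:
            y[index[entity]] = 1.0
        for entity in matched_neg:
            y[index[entity]] = -1.0
    return EncodedLabels(
        y=y,
        matched=matched | matched_neg,
        unmatched=unmatched,
        background=background,
        method=method,
        node_order=net.node_order,
        background_mask=mask,
    )


@dataclass
class ScoreResult:
    """Per-node diffusion scores with provenance.

    ``undefined`` flags nodes whose score could not be computed (zero
    permutation variance for z); their entries are NaN, never a silent zero.
    ``null_mean`` / ``null_var`` hold the analytic permutation-null moments
    (z method only).
    """

    scores: np.ndarray
    method: str
    node_order: tuple[str, ...]
    undefined: np.ndarray
    null_mean: np.ndarray | None = None
    null_var: np.ndarray | None = None
    kernel_name: str = ""
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.scores.tolist()))


def _check_alignment(kernel: KernelMatrix, enc: EncodedLabels) -> None:
    if tuple(kernel.node_order) != tuple(enc.node_order):
        raise AlignmentError("kernel and encoded labels are bound to different node orders")


def _kernel_product(kernel: KernelMatrix, enc: EncodedLabels) -> np.ndarray:
    _check_alignment(kernel, enc)
    return kernel.matrix @ enc.y


def score_raw(kernel: KernelMatrix, enc: EncodedLabels) -> ScoreResult:
    """Classical diffusion score f = K @ y."""
    f = _kernel_product(kernel, enc)
    return ScoreResult(f, "raw", enc.node_order, np.zeros(len(f), dtype=bool),
                       kernel_name=kernel.kernel_name, params=dict(kernel.params))


def score_ml(kernel: KernelMatrix, enc: EncodedLabels) -> ScoreResult:
    """Diffusion of the signed +1/-1/0 encoding."""
    if enc.method != "ml":
        raise ParameterError(f"score_ml needs an ml encoding, got {enc.method!r}")
    f = _kernel_product(kernel, enc)
    return ScoreResult(f, "ml", enc.node_order, np.zeros(len(f), dtype=bool),
                       kernel_name=kernel.kernel_name, params=dict(kernel.params))


def score_gm(kernel: KernelMatrix, enc: EncodedLabels) -> ScoreResult:
    """Diffusion of the signed encoding with the class-imbalance bias constant."""
    if enc.method != "gm":
        raise ParameterError(f"score_gm needs a gm encoding, got {enc.method!r}")
    f = _kernel_product(kernel, enc)
    return ScoreResult(f, "gm", enc.node_order, np.zeros(len(f), dtype=bool),
                       kernel_name=kernel.kernel_name, params=dict(kernel.params))


def permutation_null_moments(
    kernel: KernelMatrix, y: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and variance of ``f_i = (K @ y)_i`` under uniform
    permutation of ``y`` restricted to the background ``mask``."""
    k = kernel.matrix
    if mask is None:
        mask = np.ones(k.shape[0], dtype=bool)
    yb = y[mask]
    n = int(mask.sum())
    if n < 2:
        raise DegenerateInputError("permutation null needs at least 2 background nodes")
    s1 = k[:, mask].sum(axis=1)
    s2 = (k[:, mask] ** 2).sum(axis=1)
    sy, sy2 = yb.sum(), (yb**2).sum()
    mean = s1 * (sy / n)
    var = (n * sy2 - sy**2) * (n * s2 - s1**2) / (n**2 * (n - 1))
    return mean, np.maximum(var, 0.0)


def score_z(kernel: KernelMatrix, enc: EncodedLabels) -> ScoreResult:
    """Statistically normalized score z = (f - E[f]) / sd[f] under the exact
    permutation null.  Nodes with zero null variance are flagged undefined."""
    f = _kernel_product(kernel, enc)
    yb = enc.y[enc.background_mask]
    if np.allclose(yb, yb[0], rtol=0.0, atol=0.0):
        raise DegenerateInputError("label vector is constant over the background; z is undefined")
    mean, var = permutation_null_moments(kernel, enc.y, enc.background_mask)
    undefined = var <= _VAR_FLOOR
    z = np.full(len(f), np.nan)
    z[~undefined] = (f[~undefined] - mean[~undefined]) / np.sqrt(var[~undefined])
    if undefined.any():
        logger.warning("z undefined for %d node(s) with zero permutation variance",
                       int(undefined.sum()))
    return ScoreResult(z, "z", enc.node_order, undefined, null_mean=mean, null_var=var,
                       kernel_name=kernel.kernel_name, params=dict(kernel.params))


def score_z_montecarlo(
    kernel: KernelMatrix, enc: EncodedLabels, n_samples: int = 10_000, seed: int = 0
) -> ScoreResult:
    """Monte-Carlo counterpart of :func:`score_z` (sampled permutation null).

    Exists as an independent cross-check of the analytic moments; the
    analytic score is the one to use.
    """
    f = _kernel_product(kernel, enc)
    rng = np.random.default_rng(seed)
    mask = enc.background_mask
    yb = enc.y[mask]
    perms = rng.permuted(np.tile(yb, (n_samples, 1)), axis=1)
    null = perms @ kernel.matrix[:, mask].T  # (n_samples, n_nodes)
    mean = null.mean(axis=0)
    var = null.var(axis=0, ddof=1)
    undefined = var <= _VAR_FLOOR
    z = np.full(len(f), np.nan)
    z[~undefined] = (f[~undefined] - mean[~undefined]) / np.sqrt(var[~undefined])
    return ScoreResult(z, "z", enc.node_order, undefined, null_mean=mean, null_var=var,
                       kernel_name=kernel.kernel_name, params=dict(kernel.params))


_SCORERS = {"raw": score_raw, "ml": score_ml, "gm": score_gm, "z": score_z}


def diffuse(
    labels: LabelInput,
    net: Network | None = None,
    *,
    kernel: KernelMatrix | None = None,
    method: str = "raw",
    kernel_name: str = "regularized_laplacian",
    kernel_params: dict | None = None,
    negatives: LabelInput | set | None = None,
    background_modality: str | None = None,
) -> ScoreResult:
    """One-call pipeline: encode labels, compute (or reuse) a kernel, score.

    Provide either ``net`` (a kernel is computed with ``kernel_name``)
    or a precomputed ``kernel`` plus ``net`` for the node annotations.
    """
    from .kernels import compute_kernel  # local import avoids cycle at import time

    if net is None:
        raise NetpropError("diffuse() requires the network (for node annotations)")
    if kernel is None:
        kernel = compute_kernel(net, kernel_name, **(kernel_params or {}))
    enc = encode_labels(labels, net, method, negatives=negatives,
                        background_modality=background_modality)
    return _SCORERS[method](kernel, enc)


def rank_nodes(
    result: ScoreResult,
    net: Network | None = None,
    restrict_to: str | None = None,
) -> list[tuple[str, float, float]]:
    """Rank nodes by descending score with mid-rank ties.

    ``restrict_to`` limits the ranking to one modality (requires ``net``).
    Returns ``(node id, score, rank)`` tuples, best first.
    """
    if restrict_to is not None:
        if net is None:
            raise ParameterError("restrict_to requires the network for modality lookup")
        keep = [i for i, node in enumerate(result.node_order)
                if net.modality_of(node) == restrict_to]
    else:
        keep = list(range(len(result.node_order)))
    if not keep:
        raise DegenerateInputError(f"no nodes to rank (restriction {restrict_to!r} is empty)")
    scores = result.scores[keep]
    if not np.all(np.isfinite(scores)):
        raise DegenerateInputError(
            "scores contain undefined entries on the ranked set; drop or restrict them first"
        )
    ranks = rankdata(-scores, method="average")
    rows = [(result.node_order[i], float(scores[j]), float(ranks[j]))
            for j, i in enumerate(keep)]
    rows.sort(key=lambda r: (r[2], r[0]))
    return rows
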