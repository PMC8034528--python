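"""Repeated-holdout AUROC evaluation of diffusion scores.

The experiment repeatedly hides a fraction of the positive labels, diffuses
the remaining (training) positives through the network, and asks how well the
resulting scores rank the hidden (test) positives above negatives.  Each
repeat yields one AUROC, computed by the Mann-Whitney pair-counting
formulation with mid-rank tie correction:

    AUROC = (# (pos, neg) pairs with pos > neg  +  0.5 * ties) / (|pos| * |neg|)

Repeats use seeds ``base_seed + r``, so evaluating several networks with the
same base seed gives paired AUROC lists and a meaningful per-repeat
difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateInputError, EmptyOverlapError, NetpropError
from .kernels import KernelMatrix, compute_kernel
from .network import Network
from .scores import SCORE_METHODS, LabelInput, ScoreResult, diffuse

logger = logging.getLogger(__name__)


def _score_lookup(scores) -> Mapping[str, float]:
    if isinstance(scores, ScoreResult):
        return scores.as_dict()
    return scores


def auroc(scores, positives: set[str], negatives: set[str]) -> float:
    """Area under the ROC curve of ``scores`` for positives vs negatives.

    ``scores`` is a :class:`ScoreResult` or a node -> score mapping and must
    be finite on both classes; the classes must be non-empty and disjoint.
    """
    lookup = _score_lookup(scores)
    positives, negatives = set(positives), set(negatives)
    if not positives or not negatives:
        raise DegenerateInputError("AUROC needs non-empty positive and negative classes")
    if positives & negatives:
        raise NetpropError(f"positive/negative classes overlap: {sorted(positives & negatives)[:5]}")
    pos = np.array([lookup[node] for node in sorted(positives)], dtype=float)
    neg = np.array([lookup[node] for node in sorted(negatives)], dtype=float)
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise DegenerateInputError("AUROC inputs contain undefined scores")
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class HoldoutSplit:
    """One train/test partition of the positive labels, plus the negatives."""

    train_positives: set[str]
    test_positives: set[str]
    negatives: set[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_positives & self.test_positives:
            raise NetpropError("train and test positives overlap")
        if (self.train_positives | self.test_positives) & self.negatives:
            raise NetpropError("negatives overlap the positive set")


def default_negatives(net: Network, positives: set[str]) -> set[str]:
    """All non-positive nodes sharing a modality with some positive node."""
    modalities = {net.modality_of(node) for node in positives}
    return {
        node for node in net.node_order
        if net.modality_of(node) in modalities and node not in positives
    }


def holdout_split(
    positives: set[str],
    fraction_test: float,
    net: Network,
    seed: int,
    negatives: set[str] | None = None,
) -> HoldoutSplit:
    """Sample ``ceil(fraction_test * |positives|)`` test positives without
    replacement under ``seed``; remaining positives train.  Negatives default
    to every same-modality non-positive node."""
    if not 0 < fraction_test < 1:
        raise NetpropError(f"fraction_test must lie in (0, 1), got {fraction_test}")
    positives = set(positives)
    missing = positives - set(net.node_order)
    if missing:
        raise NetpropError(f"positives not in network: {sorted(missing)[:5]}")
    if len(positives) < 2:
        raise DegenerateInputError("holdout needs at least 2 positives")
    rng = np.random.default_rng(seed)
    ordered = sorted(positives)
    n_test = math.ceil(fraction_test * len(ordered))
    test = set(rng.choice(ordered, size=n_test, replace=False).tolist())
    if negatives is None:
        negatives = default_negatives(net, positives)
    else:
        negatives = set(negatives) - positives
    return HoldoutSplit(positives - test, test, negatives, seed)


@dataclass
class EvaluationResult:
    """Per-repeat AUROCs of one repeated-holdout experiment."""

    aurocs: list[float]
    n_repeats: int
    holdout_fraction: float
    method: str
    kernel_name: str
    params: dict = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, float]:
        a = np.asarray(self.aurocs)
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        return {
            "mean": float(a.mean()),
            "median": float(med),
            "iqr": float(q3 - q1),
            "min": float(a.min()),
            "max": float(a.max()),
        }


def repeated_holdout(
    net: Network,
    labels: LabelInput,
    method: str = "raw",
    n_repeats: int = 100,
    fraction_test: float = 0.2,
    base_seed: int = 0,
    *,
    kernel: KernelMatrix | None = None,
    kernel_name: str = "regularized_laplacian",
    kernel_params: dict | None = None,
    negatives: set[str] | None = None,
) -> EvaluationResult:
    """Run the repeated-holdout experiment on one network.

    Repeat ``r`` splits with seed ``base_seed + r``, diffuses the training
    positives only (test positives never enter the input), and computes the
    AUROC of the test positives against the negatives.
    """
    if method not in SCORE_METHODS:
        raise NetpropError(f"unknown score method {method!r}")
    positives = {e for e, v in labels.entries.items() if v != 0} & set(net.node_order)
    if not positives:
        raise EmptyOverlapError("no positive label maps onto the network")
    if kernel is None:
        kernel = compute_kernel(net, kernel_name, **(kernel_params or {}))
    aurocs = []
    for r in range(n_repeats):
        split = holdout_split(positives, fraction_test, net, base_seed + r, negatives)
        if not split.test_positives:
            raise DegenerateInputError(f"repeat {r}: empty test set (seed {split.seed})")
        train = LabelInput.from_ids(split.train_positives)
        result = diffuse(train, net, kernel=kernel, method=method)
        aurocs.append(auroc(result, split.test_positives, split.negatives))
    return EvaluationResult(
        aurocs=aurocs,
        n_repeats=n_repeats,
        holdout_fraction=fraction_test,
        method=method,
        kernel_name=kernel.kernel_name,
        params=dict(kernel.params),
    )


@dataclass
class ComparisonResult:
    """Paired repeated-holdout results over a collection of networks."""

    results: dict[str, EvaluationResult]
    errors: dict[str, str]
    table: pd.DataFrame  # long format: network, repeat, auroc
    paired_median_delta: dict[str, float]  # vs the first (reference) network


def compare_networks(
    collection: Sequence[tuple[str, Network]],
    labels: LabelInput,
    method: str = "raw",
    n_repeats: int = 100,
    fraction_test: float = 0.2,
    base_seed: int = 0,
    **kwargs,
) -> ComparisonResult:
    """Evaluate several networks with identical split seeds (paired design).

    The first network is the reference for the paired median AUROC
    difference.  A network whose label overlap is empty is recorded as an
    error and the run continues.
    """
    if len(collection) < 2:
        raise NetpropError("network comparison needs at least 2 networks")
    results: dict[str, EvaluationResult] = {}
    errors: dict[str, str] = {}
    rows = []
    for name, net in collection:
        try:
            res = repeated_holdout(net, labels, method, n_repeats, fraction_test,
                                   base_seed, **kwargs)
        except (EmptyOverlapError, DegenerateInputError) as exc:
            errors[name] = str(exc)
            logger.warning("network %r skipped: %s", name, exc)
            continue
        results[name] = res
        rows.extend({"network": name, "repeat": r, "auroc": a}
                    for r, a in enumerate(res.aurocs))
    table = pd.DataFrame(rows, columns=["network", "repeat", "auroc"])
    ref_name = collection[0][0]
    deltas: dict[str, float] = {}
    if ref_name in results:
        ref = np.asarray(results[ref_name].aurocs)
        for name, res in results.items():
            if name != ref_name:
                deltas[name] = float(np.median(ref - np.asarray(res.aurocs)))
    return ComparisonResult(results=results, errors=errors, table=table,
                            paired_median_delta=deltas)
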