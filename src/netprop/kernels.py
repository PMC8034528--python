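"""The five graph kernels used for label diffusion.

All kernels are symmetric positive semi-definite node-similarity matrices
derived from the graph Laplacian spectrum:

==========================  ===============================  =============
kernel                      formula                          Laplacian
==========================  ===============================  =============
regularized_laplacian       K = (I + sigma2 * L)^-1          unnormalized
diffusion (heat)            K = exp(-t * L)                  unnormalized
p_step                      K = (a*I - L~)^p,  a >= 2        normalized
commute_time                K = L+   (Moore-Penrose)         unnormalized
inverse_cosine              K = cos(L~ * pi / 4)             normalized
==========================  ===============================  =============

Matrix functions (exp, cos, pseudo-inverse) are evaluated through a symmetric
eigendecomposition rather than series expansions, which makes every kernel
checkable against an independent spectral oracle.  Everything is dense; the
practical ceiling is networks of roughly 20k nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .exceptions import NetworkFormatError, ParameterError
from .network import LaplacianMatrix, Network, laplacian

logger = logging.getLogger(__name__)

KERNEL_NAMES = (
    "regularized_laplacian",
    "diffusion",
    "p_step",
    "commute_time",
    "inverse_cosine",
)

#: Default kernel parameters (classical convention of the diffusion-score
#: literature): sigma2=1 regularization, unit diffusion time, a=2 / p=5 steps.
DEFAULT_PARAMS = {"sigma2": 1.0, "t": 1.0, "a": 2.0, "p": 5}


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix bound to a node ordering."""

    matrix: np.ndarray
    kernel_name: str
    params: dict = field(default_factory=dict)
    node_order: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _require_variant(lap: LaplacianMatrix, variant: str, kernel: str) -> np.ndarray:
    if lap.variant != variant:
        raise ParameterError(f"{kernel} kernel requires the {variant} Laplacian, got {lap.variant}")
    return np.asarray(lap.matrix, dtype=float)


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def regularized_laplacian_kernel(lap: LaplacianMatrix, sigma2: float = 1.0) -> KernelMatrix:
    """K = (I + sigma2*L)^-1.  Rows sum to one because L has zero row sums."""
    l = _require_variant(lap, "unnormalized", "regularized_laplacian")
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ParameterError(f"sigma2 must be a finite positive real, got {sigma2!r}")
    n = l.shape[0]
    k = scipy.linalg.solve(np.eye(n) + sigma2 * l, np.eye(n), assume_a="pos")
    return KernelMatrix(_symmetrize(k), "regularized_laplacian", {"sigma2": sigma2}, lap.node_order)


def diffusion_kernel(lap: LaplacianMatrix, t: float = 1.0) -> KernelMatrix:
    """Heat kernel K = exp(-t*L), computed spectrally.  Rows sum to one."""
    l = _require_variant(lap, "unnormalized", "diffusion")
    if not np.isfinite(t) or t <= 0:
        raise ParameterError(f"diffusion time t must be a finite positive real, got {t!r}")
    w, v = scipy.linalg.eigh(l)
    k = (v * np.exp(-t * w)) @ v.T
    return KernelMatrix(_symmetrize(k), "diffusion", {"t": t}, lap.node_order)


def p_step_kernel(lap: LaplacianMatrix, a: float = 2.0, p: int = 5) -> KernelMatrix:
    """p-step random-walk kernel K = (a*I - L~)^p.

    ``a >= 2`` guarantees positive semi-definiteness because the normalized
    Laplacian spectrum lies in [0, 2].
    """
    l = _require_variant(lap, "normalized", "p_step")
    if not np.isfinite(a) or a < 2:
        raise ParameterError(f"p-step parameter a must be >= 2, got {a!r}")
    if not float(p).is_integer() or p < 1:
        raise ParameterError(f"p must be a positive integer, got {p!r}")
    p = int(p)
    k = np.linalg.matrix_power(a * np.eye(l.shape[0]) - l, p)
    return KernelMatrix(_symmetrize(k), "p_step", {"a": a, "p": p}, lap.node_order)


def commute_time_kernel(lap: LaplacianMatrix) -> KernelMatrix:
    """Commute-time kernel K = L+ (Moore-Penrose pseudo-inverse of L).

    Row sums vanish on every connected component, since the component
    indicator spans the Laplacian null space.
    """
    l = _require_variant(lap, "unnormalized", "commute_time")
    k = scipy.linalg.pinvh(l)
    return KernelMatrix(_symmetrize(k), "commute_time", {}, lap.node_order)


def inverse_cosine_kernel(lap: LaplacianMatrix) -> KernelMatrix:
    """Inverse-cosine kernel K = cos(L~ * pi/4), applied to the spectrum.

    Eigenvalues of L~ lie in [0, 2], so eigenvalues of K lie in [0, 1].
    """
    l = _require_variant(lap, "normalized", "inverse_cosine")
    w, v = scipy.linalg.eigh(l)
    k = (v * np.cos(w * np.pi / 4.0)) @ v.T
    return KernelMatrix(_symmetrize(k), "inverse_cosine", {}, lap.node_order)


#: kernel name -> (function, Laplacian variant, admissible parameter names)
_DISPATCH = {
    "regularized_laplacian": (regularized_laplacian_kernel, "unnormalized", ("sigma2",)),
    "diffusion": (diffusion_kernel, "unnormalized", ("t",)),
    "p_step": (p_step_kernel, "normalized", ("a", "p")),
    "commute_time": (commute_time_kernel, "unnormalized", ()),
    "inverse_cosine": (inverse_cosine_kernel, "normalized", ()),
}


def compute_kernel(net: Network, name: str = "regularized_laplacian", **params) -> KernelMatrix:
    """Compute a named kernel directly from a network.

    Chooses the Laplacian variant the kernel requires and fills unspecified
    parameters from :data:`DEFAULT_PARAMS`.
    """
    if name not in _DISPATCH:
        raise ParameterError(f"unknown kernel {name!r}; choose one of {KERNEL_NAMES}")
    func, variant, keys = _DISPATCH[name]
    unknown = set(params) - set(keys)
    if unknown:
        raise ParameterError(f"kernel {name!r} does not accept parameter(s) {sorted(unknown)}")
    kwargs = {key: params.get(key, DEFAULT_PARAMS[key]) for key in keys}
    return func(laplacian(net, variant), **kwargs)


# ---------------------------------------------------------------------------
# Kernel TSV serialization
# ---------------------------------------------------------------------------


def write_kernel(kernel: KernelMatrix, path: str | Path) -> None:
    """Write a labeled kernel TSV (header row + first column of node ids).

    Values are written with :func:`repr` so they parse back bit-exactly.
    """
    m = kernel.matrix
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(kernel.node_order):
        raise NetworkFormatError("kernel matrix must be square and match node_order length")
    with open(path, "w") as handle:
        handle.write("node\t" + "\t".join(kernel.node_order) + "\n")
        for node, row in zip(kernel.node_order, m):
            handle.write(node + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_kernel(path: str | Path, kernel_name: str = "precomputed") -> KernelMatrix:
    """Read a kernel TSV produced by :func:`write_kernel` (or compatible)."""
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "node":
            raise NetworkFormatError(f"{path}: first header cell must be 'node'")
        order = tuple(header[1:])
        rows, labels = [], []
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(order) + 1:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected {len(order) + 1} fields, got {len(fields)}"
                )
            labels.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: non-numeric kernel value") from exc
    if tuple(labels) != order:
        raise NetworkFormatError(
            f"{path}: row labels do not match header order (matrix must be labeled symmetrically)"
        )
    return KernelMatrix(np.array(rows, dtype=float), kernel_name, {}, order)
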