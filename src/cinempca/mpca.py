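"""Multilinear principal component analysis (MPCA) for third-order tensors.

MPCA generalises PCA to tensor-valued samples: instead of one eigenvector
of length I*J*K per feature, it learns three per-mode projection matrices
U1 (I x P), U2 (J x Q), U3 (K x R) with orthonormal columns that maximise
the total variation captured by the projected P x Q x R feature tensors.
Each feature (p, q, r) corresponds to a rank-one *eigentensor*
``u1_p o u2_q o u3_r`` with only I + J + K parameters, and equals the
Frobenius inner product of the centred sample with that eigentensor.

Fitting follows the standard alternating scheme: centre the samples,
initialise each mode from the eigenvectors of its full mode-wise scatter
matrix, truncate each mode at the smallest dimension whose eigenvalue mass
reaches the per-mode variance threshold, then alternately re-solve each
mode's partial scatter (samples projected through the other two modes)
until the captured variation stops improving. Captured variation is
non-decreasing across updates. Everything is deterministic; eigenvector
signs are fixed by making each column's largest-magnitude entry positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CinempcaError, CineTensor

_MODES = (1, 2, 3)


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-k unfolding: rows index mode ``k``; remaining axes are flattened
    row-major in their original order (for mode 2 of an (I, J, K) tensor the
    columns run over (i, k) with k fastest)."""
    if mode not in _MODES:
        raise CinempcaError(f"mode must be one of {_MODES}, got {mode}")
    t = np.asarray(tensor)
    return np.moveaxis(t, mode - 1, 0).reshape(t.shape[mode - 1], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for the given full tensor ``shape``."""
    if mode not in _MODES:
        raise CinempcaError(f"mode must be one of {_MODES}, got {mode}")
    rest = [s for ax, s in enumerate(shape) if ax != mode - 1]
    return np.moveaxis(np.asarray(matrix).reshape([shape[mode - 1]] + rest), 0, mode - 1)


@dataclass
class MPCAModel:
    """Fitted MPCA model: mean tensor, per-mode projections and eigenvalues.

    ``projections[k]`` has orthonormal columns; ``mode_eigenvalues[k]`` is
    the full descending eigenvalue list of mode ``k``'s final partial
    scatter matrix (its leading ``d_k`` entries sum to the captured
    variation). Feature tensors flatten row-major over (p, q, r):
    ``flat = p * Q * R + q * R + r``.
    """

    mean_tensor: np.ndarray
    projections: tuple[np.ndarray, np.ndarray, np.ndarray]
    mode_eigenvalues: tuple[np.ndarray, np.ndarray, np.ndarray]
    variance_threshold: float
    n_train: int
    psi_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return self.mean_tensor.shape

    @property
    def feature_shape(self) -> tuple[int, int, int]:
        return tuple(u.shape[1] for u in self.projections)

    @property
    def n_features(self) -> int:
        return int(np.prod(self.feature_shape))


def _as_array(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray) and samples.ndim == 4:
        return np.asarray(samples, dtype=float)
    arrs = [s.voxels if isinstance(s, CineTensor) else np.asarray(s, float) for s in samples]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise CinempcaError(f"samples have inconsistent shapes: {sorted(shapes)}")
    return np.stack(arrs).astype(float)

def _scatter(xc: np.ndarray, mode: int) -> np.ndarray:
    axes = [ax for ax in range(1, 4) if ax != mode]
    return np.tensordot(xc, xc, axes=([0] + axes, [0] + axes))


def _eigh_desc(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh((s + s.T) / 2)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0.0, None), v[:, order]


def _fix_signs(u: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def _project_other_modes(xc: np.ndarray, us: list[np.ndarray], mode: int) -> np.ndarray:
    y = xc
    for other in range(3):
        if other == mode:
            continue
        y = np.moveaxis(
            np.tensordot(y, us[other], axes=([other + 1], [0])), -1, other + 1
        )
    return y


def mpca_fit(
    samples,
    variance_threshold: float = 0.97,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> MPCAModel:
    """Fit MPCA to ``N`` same-shaped tensors (N >= 2).

    ``variance_threshold`` is the per-mode eigenvalue-mass fraction used to
    pick P, Q, R at initialisation (1.0 keeps every mode full, making the
    projection an exact rotation). ``tol`` is the relative improvement in
    captured variation below which alternation stops.
    """
    x = _as_array(samples)
    n = x.shape[0]
    if n < 2:
        raise CinempcaError(f"MPCA requires at least 2 samples, got {n}")
    if not 0 < variance_threshold <= 1.0:
        raise CinempcaError("variance_threshold must lie in (0, 1]")
    mean = x.mean(axis=0)
    xc = x - mean
    total = float((xc**2).sum())
    shape = mean.shape

    if total < 1e-12:
        warnings.warn("zero-variance training data: all MPCA features will be zero")
        us = tuple(np.eye(s, 1) for s in shape)
        eigs = tuple(np.zeros(s) for s in shape)
        return MPCAModel(mean, us, eigs, variance_threshold, n, np.zeros(0))

    us: list[np.ndarray] = []
    dims: list[int] = []
    for mode in range(3):
        w, v = _eigh_desc(_scatter(xc, mode + 1))
        mass = np.cumsum(w)
        if mass[-1] <= 0:
            d = 1
        else:
            d = int(np.searchsorted(mass / mass[-1], variance_threshold - 1e-12) + 1)
        d = min(d, len(w))
        dims.append(d)
        us.append(v[:, :d])

    eigs: list[np.ndarray] = [np.zeros(s) for s in shape]
    psi_history: list[float] = []
    prev_psi = None
    for _ in range(max_iter):
        for mode in range(3):
            y = _project_other_modes(xc, us, mode)
            w, v = _eigh_desc(_scatter(y, mode + 1))
            us[mode] = v[:, : dims[mode]]
            eigs[mode] = w
            psi_history.append(float(w[: dims[mode]].sum()))
        psi = psi_history[-1]
        if prev_psi is not None and psi - prev_psi <= tol * max(prev_psi, 1e-300):
            break
        prev_psi = psi

    us = [_fix_signs(u) for u in us]
    return MPCAModel(
        mean_tensor=mean,
        projections=tuple(us),
        mode_eigenvalues=tuple(eigs),
        variance_threshold=variance_threshold,
        n_train=n,
        psi_history=np.asarray(psi_history),
    )


def mpca_project(model: MPCAModel, sample) -> np.ndarray:
    """Project one sample to its P x Q x R feature tensor.

    Centres by the training mean, then contracts each mode with the
    corresponding projection transposed; linear in the sample.
    """
    arr = sample.voxels if isinstance(sample, CineTensor) else np.asarray(sample, float)
    if arr.shape != model.input_shape:
        raise CinempcaError(
            f"sample shape {arr.shape} does not match model input {model.input_shape}"
        )
    u1, u2, u3 = model.projections
    return np.einsum("ijk,ip,jq,kr->pqr", arr - model.mean_tensor, u1, u2, u3, optimize=True)


def features_matrix(model: MPCAModel, samples) -> np.ndarray:
    """Stack flattened feature tensors for N samples into an (N, P*Q*R) matrix.

    The flattening is row-major over (p, q, r) — identical for every
    sample, train or test.
    """
    x = _as_array(samples)
    if x.shape[1:] != model.input_shape:
        raise CinempcaError(
            f"sample shape {x.shape[1:]} does not match model input {model.input_shape}"
        )
    u1, u2, u3 = model.projections
    feats = np.einsum(
        "nijk,ip,jq,kr->npqr", x - model.mean_tensor, u1, u2, u3, optimize=True
    )
    return feats.reshape(x.shape[0], -1)


def mpca_reconstruct(model: MPCAModel, features: np.ndarray) -> np.ndarray:
    """Map a P x Q x R feature tensor back to input space (plus the mean)."""
    u1, u2, u3 = model.projections
    return (
        np.einsum("pqr,ip,jq,kr->ijk", np.asarray(features, float), u1, u2, u3, optimize=True)
        + model.mean_tensor
    )


@dataclass
class Eigentensor:
    """Rank-one tensor ``u1_p o u2_q o u3_r`` for feature index (p, q, r),
    stored by its three factor vectors (I + J + K parameters)."""

    index: tuple[int, int, int]
    factors: tuple[np.ndarray, np.ndarray, np.ndarray]

    def dense(self) -> np.ndarray:
        a, b, c = self.factors
        return np.einsum("i,j,k->ijk", a, b, c)


def eigentensor(model: MPCAModel, index: tuple[int, int, int]) -> Eigentensor:
    p, q, r = index
    pp, qq, rr = model.feature_shape
    if not (0 <= p < pp and 0 <= q < qq and 0 <= r < rr):
        raise CinempcaError(f"eigentensor index {index} out of range {(pp, qq, rr)}")
    u1, u2, u3 = model.projections
    return Eigentensor(index=(p, q, r), factors=(u1[:, p].copy(), u2[:, q].copy(), u3[:, r].copy()))


def save_model(model: MPCAModel, path: str | Path) -> None:
    """Serialise the model to a single ``.npz`` container (bit-exact round trip).

    The file records the flattening order ("row-major over (p, q, r)") so
    downstream consumers can interpret flat feature indices.
    """
    np.savez(
        path,
        mean_tensor=model.mean_tensor,
        u1=model.projections[0],
        u2=model.projections[1],
        u3=model.projections[2],
        eig1=model.mode_eigenvalues[0],
        eig2=model.mode_eigenvalues[1],
        eig3=model.mode_eigenvalues[2],
        variance_threshold=np.float64(model.variance_threshold),
        n_train=np.int64(model.n_train),
        psi_history=model.psi_history,
        flattening_order=np.bytes_(b"row-major (p,q,r): flat = p*Q*R + q*R + r"),
    )


def load_model(path: str | Path) -> MPCAModel:
    with np.load(path) as z:
        return MPCAModel(
            mean_tensor=z["mean_tensor"],
            projections=(z["u1"], z["u2"], z["u3"]),
            mode_eigenvalues=(z["eig1"], z["eig2"], z["eig3"]),
            variance_threshold=float(z["variance_threshold"]),
            n_train=int(z["n_train"]),
            psi_history=z["psi_history"],
        )
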