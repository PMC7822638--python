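"""Linear classifiers on selected MPCA features and voxel-wise feature maps.

Two interpretable linear models are supported: a linear-kernel soft-margin
SVM and L2-regularised logistic regression. Features are standardised on
the training data and the standardisation is folded back into the stored
weights, so ``score = beta . f + b`` holds in original feature units.

Because the whole chain (centering -> multilinear projection -> feature
selection -> linear model) is linear, the classifier weights can be
back-projected through the eigentensors into a dense voxel-wise weight
tensor W with ``<W, x - mean> + b`` equal to the decision score of sample
``x``. Positive W favours the disease class (rendered red), negative the
control class (green).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .core import CinempcaError
from .mpca import MPCAModel, eigentensor

KINDS = ("svm", "lr")


@dataclass
class LinearModel:
    """Affine decision rule ``score = beta . f + b`` over selected features.

    ``selected`` holds the flat MPCA feature indices the model was trained
    on (None when trained on a plain feature matrix); ``beta`` and ``bias``
    are in original (unstandardised) feature units.
    """

    kind: str
    beta: np.ndarray
    bias: float
    selected: np.ndarray | None = None
    C: float = 1.0

    @property
    def n_features(self) -> int:
        return self.beta.size


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "svm",
    C: float = 1.0,
    seed: int = 0,
    selected: np.ndarray | None = None,
) -> LinearModel:
    """Fit a linear SVM or logistic regression on an (N, S) feature matrix.

    Class encoding: 1 = disease (positive scores), 0 = control. Training
    standardises features internally; the returned weights are folded back
    to original units. Deterministic given the inputs and seed.
    """
    if kind not in KINDS:
        raise CinempcaError(f"classifier kind must be one of {KINDS}, got {kind!r}")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        raise CinempcaError("features and labels disagree on sample count")
    if len(np.unique(y)) < 2:
        raise CinempcaError("training labels contain a single class")

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    xs = (x - mu) / sd

    if kind == "svm":
        est = SVC(kernel="linear", C=C, random_state=int(seed) % (2**31))
    else:
        est = LogisticRegression(C=C, max_iter=2000, random_state=int(seed) % (2**31))
    est.fit(xs, y)
    w = est.coef_.ravel()
    b0 = float(est.intercept_.ravel()[0])
    beta = w / sd
    bias = b0 - float((w * mu / sd).sum())
    return LinearModel(
        kind=kind,
        beta=beta,
        bias=bias,
        selected=None if selected is None else np.asarray(selected, dtype=int),
        C=C,
    )


def decision_scores(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Continuous decision scores ``beta . f + b``, one per sample."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.n_features:
        raise CinempcaError(
            f"feature count {x.shape[1]} does not match model ({model.n_features})"
        )
    return x @ model.beta + model.bias


def probabilities(model: LinearModel, features: np.ndarray) -> np.ndarray:
    """Disease-class probabilities (logistic models only); the monotone
    sigmoid of the decision score, so score and probability order samples
    identically."""
    if model.kind != "lr":
        raise CinempcaError("probabilities are defined for logistic regression only")
    s = decision_scores(model, features)
    return 1.0 / (1.0 + np.exp(-s))


@dataclass
class FeatureMap:
    """Dense voxel-wise weight tensor W (I x J x K).

    Sign convention: positive weights indicate the disease class (red in
    overlays), negative the control class (green); |W| is the amplitude.
    ``bias`` completes the affine identity ``<W, x - mean> + bias = score``.
    """

    weights: np.ndarray
    bias: float


def feature_map(model: LinearModel, mpca_model: MPCAModel) -> FeatureMap:
    """Back-project classifier weights through eigentensors to voxel space.

    ``W = sum_s beta_s * E_s`` over the selected flat feature indices,
    where ``E_s`` is the eigentensor at the (p, q, r) index of flat index
    ``s`` under the model's row-major flattening.
    """
    if model.selected is None:
        raise CinempcaError("model has no selected MPCA feature indices")
    if model.selected.size != model.n_features:
        raise CinempcaError("selected index count does not match weight count")
    shape = mpca_model.feature_shape
    if model.selected.size and model.selected.max() >= int(np.prod(shape)):
        raise CinempcaError("selected feature index out of range for this MPCA model")
    w = np.zeros(mpca_model.input_shape)
    for beta_s, flat in zip(model.beta, model.selected):
        idx = np.unravel_index(int(flat), shape)
        w += beta_s * eigentensor(mpca_model, idx).dense()
    return FeatureMap(weights=w, bias=model.bias)


def contribution_map(fmap: FeatureMap, sample: np.ndarray, mpca_model: MPCAModel) -> np.ndarray:
    """Per-subject contribution map ``W * (x - mean)`` (elementwise): how each
    voxel of this subject pushes the decision score."""
    arr = np.asarray(sample, dtype=float)
    if arr.shape != mpca_model.input_shape:
        raise CinempcaError("sample shape does not match the MPCA model")
    return fmap.weights * (arr - mpca_model.mean_tensor)


def render_overlays(
    fmap: FeatureMap,
    mpca_model: MPCAModel,
    out_dir: str | Path,
    prefix: str = "featuremap",
) -> list[Path]:
    """Write one PNG per frame: signed W on a red(+)/green(-) diverging scale
    over the mean image, with an amplitude colour bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmap = LinearSegmentedColormap.from_list("gr", ["green", "#00000000", "red"])
    vmax = float(np.abs(fmap.weights).max()) or 1.0
    paths = []
    for k in range(fmap.weights.shape[2]):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(mpca_model.mean_tensor[:, :, k], cmap="gray")
        im = ax.imshow(
            fmap.weights[:, :, k],
            cmap=cmap,
            norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax),
            alpha=0.6,
        )
        ax.set_axis_off()
        fig.colorbar(im, ax=ax, label="feature amplitude")
        p = out_dir / f"{prefix}_frame{k:02d}.png"
        fig.savefig(p, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
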