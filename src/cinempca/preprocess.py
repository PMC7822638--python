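"""Landmark registration, elliptical masking and rescaling of cine sequences.

The preprocessing pipeline has a fixed order: register each subject's
sequence to a reference subject via three paired landmarks, zero out
everything outside an elliptical heart mask defined once in reference
space, then downsample to the analysis grid. All geometry uses the package
coordinate convention (x = column, y = row, 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .core import (
    CineTensor,
    DegenerateLandmarksError,
    LandmarkSet,
    NotAnEllipseError,
    CinempcaError,
)

ALLOWED_SCALES = (32, 64, 128, 256, 512)

# reflection about the vertical axis (x -> -x), applied before rotation
_FLIP = np.array([[-1.0, 0.0], [0.0, 1.0]])
_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass
class SimilarityTransform:
    """2-D similarity transform: ``q = s * R(rotation) * F * p + translation``.

    ``F`` is a left-right reflection when ``reflect`` is true, identity
    otherwise. ``rotation`` is in degrees, counter-clockwise in (x, y)
    coordinates. ``residual`` stores the RMS landmark misfit when the
    transform came from :func:`fit_similarity`.
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    reflect: bool = False
    residual: float | None = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise CinempcaError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part ``s * R * F``."""
        th = np.deg2rad(self.rotation)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = self.scale * r
        if self.reflect:
            m = m @ _FLIP
        return m

    @property
    def homogeneous(self) -> np.ndarray:
        h = np.eye(3)
        h[:2, :2] = self.matrix
        h[:2, 2] = self.translation
        return h

    @classmethod
    def from_matrix(cls, h: np.ndarray, residual: float | None = None) -> "SimilarityTransform":
        h = np.asarray(h, dtype=float)
        m = h[:2, :2]
        det = np.linalg.det(m)
        if abs(det) < 1e-300:
            raise CinempcaError("non-invertible transform matrix")
        reflect = det < 0
        mr = m @ _FLIP if reflect else m
        scale = float(np.sqrt(np.linalg.det(mr)))
        rotation = float(np.degrees(np.arctan2(mr[1, 0], mr[0, 0])))
        return cls(
            rotation=rotation,
            scale=scale,
            translation=(float(h[0, 2]), float(h[1, 2])),
            reflect=bool(reflect),
            residual=residual,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` points (x, y) through the transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.homogeneous))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        return SimilarityTransform.from_matrix(self.homogeneous @ other.homogeneous)


@dataclass
class RegistrationQA:
    """Per-landmark residual distances (px) after warping, and their maximum."""

    residuals: np.ndarray
    max_residual: float
    threshold: float
    flagged: bool


def fit_similarity(moving: LandmarkSet, reference: LandmarkSet) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``moving`` onto ``reference``.

    Closed-form orthogonal Procrustes with isotropic scale over the three
    point pairs; both the rotation (det +1) and reflection (det -1)
    branches are solved and the reflection is kept only when it strictly
    lowers the residual.
    """
    if moving.role != "registration3" or reference.role != "registration3":
        raise DegenerateLandmarksError("fit_similarity requires registration3 landmark sets")
    x = moving.points
    y = reference.points
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    xnorm2 = float((xc**2).sum())
    if xnorm2 < 1e-18:
        raise DegenerateLandmarksError("moving landmarks are coincident")
    h = xc.T @ yc
    u, sig, vt = np.linalg.svd(h)
    duv = np.sign(np.linalg.det(u) * np.linalg.det(vt))

    best: SimilarityTransform | None = None
    for want_det in (1.0, -1.0):
        z = np.eye(2)
        if want_det * duv < 0:
            z[1, 1] = -1.0
        q = vt.T @ z @ u.T
        s = float(np.trace(z * np.diag(sig)) / xnorm2)
        if s <= 0:
            continue
        t = my - s * (q @ mx)
        pred = x @ (s * q).T + t
        res = float(np.sqrt(((pred - y) ** 2).sum(axis=1).mean()))
        hmat = np.eye(3)
        hmat[:2, :2] = s * q
        hmat[:2, 2] = t
        cand = SimilarityTransform.from_matrix(hmat, residual=res)
        if best is None or res < best.residual:
            best = cand
    if best is None:
        raise DegenerateLandmarksError("could not fit a similarity transform")
    return best


def warp_sequence(
    seq: CineTensor, t: SimilarityTransform, reference_shape: tuple[int, int] | None = None
) -> CineTensor:
    """Resample every frame of ``seq`` through ``t`` into reference space.

    ``t`` maps moving coordinates to reference coordinates (as returned by
    :func:`fit_similarity`); the output frame is
    ``out(q) = seq(t^{-1}(q))`` with bilinear interpolation and zeros
    outside the field of view. Landmarks are labelled on frame 1 only, so
    the same in-plane transform is applied to all K frames.
    """
    if reference_shape is None:
        reference_shape = seq.voxels.shape[:2]
    hinv = np.linalg.inv(t.homogeneous)
    # convert the (x, y) inverse map to scipy's (row, col) convention
    a_rc = _SWAP @ hinv[:2, :2] @ _SWAP
    off_rc = hinv[:2, 2][::-1]
    k = seq.n_frames
    out = np.empty(tuple(reference_shape) + (k,), dtype=float)
    for f in range(k):
        out[:, :, f] = ndimage.affine_transform(
            seq.voxels[:, :, f],
            a_rc,
            offset=off_rc,
            output_shape=tuple(reference_shape),
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    return seq.with_voxels(out, frame_of_reference="registered")


def registration_qa(
    warped: LandmarkSet | np.ndarray,
    reference: LandmarkSet | np.ndarray,
    threshold: float = 20.0,
) -> RegistrationQA:
    """Euclidean residuals between warped and reference landmarks.

    The default flag threshold of 20 px refers to a 512-grid; callers
    working at other grids should scale it proportionally.
    """
    wp = warped.points if isinstance(warped, LandmarkSet) else np.atleast_2d(warped)
    rp = reference.points if isinstance(reference, LandmarkSet) else np.atleast_2d(reference)
    if wp.shape != rp.shape:
        raise CinempcaError(f"mismatched landmark counts: {wp.shape} vs {rp.shape}")
    res = np.linalg.norm(wp - rp, axis=1)
    mx = float(res.max())
    return RegistrationQA(residuals=res, max_residual=mx, threshold=threshold, flagged=mx > threshold)


@dataclass
class EllipseMask:
    """Elliptical heart mask as a conic ``A x^2 + B xy + C y^2 + D x + E y + F = 0``.

    The conic is normalised so the interior has negative sign. ``variant``
    is ``"small"`` (conic through the five boundary landmarks) or
    ``"large"`` (small ellipse dilated about its centre).
    """

    conic: np.ndarray
    variant: str = "small"

    def __post_init__(self) -> None:
        self.conic = np.asarray(self.conic, dtype=float)
        a, b, c = self.conic[:3]
        if not b * b - 4 * a * c < 0:
            raise NotAnEllipseError("conic is not an ellipse (B^2 - 4AC >= 0)")

    @property
    def _matrix(self) -> np.ndarray:
        a, b, c, d, e, f = self.conic
        return np.array([[a, b / 2, d / 2], [b / 2, c, e / 2], [d / 2, e / 2, f]])

    @property
    def center(self) -> np.ndarray:
        a, b, c, d, e, _ = self.conic
        return np.linalg.solve(np.array([[2 * a, b], [b, 2 * c]]), [-d, -e])

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths, descending."""
        a, b, c, *_ = self.conic
        q2 = np.array([[a, b / 2], [b / 2, c]])
        k = float(self.evaluate(self.center[None, :])[0])
        lam = np.linalg.eigvalsh(q2)
        with np.errstate(invalid="raise"):
            axes = np.sqrt(-k / lam)
        return np.sort(axes)[::-1]

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        x, y = p[:, 0], p[:, 1]
        a, b, c, d, e, f = self.conic
        return a * x * x + b * x * y + c * y * y + d * x + e * y + f

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points) <= 0

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean (rows, cols) grid of interior pixels (evaluated at pixel centres)."""
        rows, cols = shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        a, b, c, d, e, f = self.conic
        return a * xx * xx + b * xx * yy + c * yy * yy + d * xx + e * yy + f <= 0

    def dilated(self, factor: float) -> "EllipseMask":
        """Ellipse scaled about its centre by ``factor`` (> 1 enlarges)."""
        if not factor > 0:
            raise CinempcaError("dilation factor must be positive")
        cx, cy = self.center
        # substitute p -> c + (p - c)/factor in the homogeneous conic matrix
        h = np.array(
            [[1 / factor, 0, cx * (1 - 1 / factor)], [0, 1 / factor, cy * (1 - 1 / factor)], [0, 0, 1]]
        )
        m = h.T @ self._matrix @ h
        conic = np.array([m[0, 0], 2 * m[0, 1], m[1, 1], 2 * m[0, 2], 2 * m[1, 2], m[2, 2]])
        return EllipseMask(conic=conic, variant="large" if factor > 1 else self.variant)


def ellipse_from_landmarks(points: LandmarkSet) -> EllipseMask:
    """Unique conic through the five boundary landmarks, verified elliptical.

    Five points in general position determine a conic up to scale: the
    coefficient vector spans the null space of the 5x6 design matrix with
    rows ``(x^2, xy, y^2, x, y, 1)``. Degenerate configurations (e.g.
    collinear points) and non-elliptical conics are rejected.
    """
    if points.role != "boundary5":
        raise NotAnEllipseError("ellipse_from_landmarks requires a boundary5 landmark set")
    p = points.points
    x, y = p[:, 0], p[:, 1]
    design = np.column_stack([x * x, x * y, y * y, x, y, np.ones(5)])
    _, sig, vt = np.linalg.svd(design)
    # 5 rows in 6 unknowns: the null space is 1-D iff the design has rank 5
    if sig[-1] < 1e-8 * sig[0]:
        raise NotAnEllipseError("degenerate boundary configuration (conic not unique)")
    conic = vt[-1]
    a, b, c = conic[:3]
    if not b * b - 4 * a * c < 0:
        raise NotAnEllipseError("the conic through the boundary points is not an ellipse")
    mask = EllipseMask(conic=conic, variant="small")
    # orient so that the interior (ellipse centre) has negative sign
    if mask.evaluate(mask.center[None, :])[0] > 0:
        mask = EllipseMask(conic=-conic, variant="small")
    return mask


def apply_mask(seq: CineTensor, mask: EllipseMask) -> CineTensor:
    """Zero all voxels outside the ellipse, in every frame."""
    raster = mask.raster(seq.voxels.shape[:2])
    return seq.with_voxels(seq.voxels * raster[:, :, None])


def pixel_spacing_mm(target: int, fov_mm: float = 480.0) -> float:
    """Pixel spacing of a square grid of side ``target`` covering ``fov_mm``."""
    if target <= 0:
        raise CinempcaError("target grid size must be positive")
    return fov_mm / target


def rescale(seq: CineTensor, target: int) -> CineTensor:
    """Spatially downsample each frame to ``target`` x ``target`` (K unchanged).

    Uses exact block-averaging when ``target`` divides the source side,
    area-weighted anti-aliased resampling otherwise. Pixel spacing is
    updated to field-of-view / target.
    """
    rows, cols, k = seq.voxels.shape
    if rows != cols:
        raise CinempcaError(f"rescale requires square frames, got {rows}x{cols}")
    if target not in ALLOWED_SCALES:
        raise CinempcaError(f"target must be one of {ALLOWED_SCALES}, got {target}")
    if target > rows:
        raise CinempcaError(f"upsampling {rows} -> {target} is not supported")
    fov = seq.pixel_spacing * rows
    if rows % target == 0:
        f = rows // target
        vox = seq.voxels.reshape(target, f, target, f, k).mean(axis=(1, 3))
    else:
        vox = _sk_resize(
            seq.voxels, (target, target, k), order=1, anti_aliasing=True, preserve_range=True
        )
    return seq.with_voxels(vox, pixel_spacing=fov / target)


def preprocess_dataset(
    sequences: dict[str, CineTensor],
    landmarks3: dict[str, LandmarkSet],
    boundary5: LandmarkSet | None,
    reference_id: str,
    mask_variant: str = "small",
    scale: int = 64,
    dilation_factor: float = 1.5,
    qa_threshold: float | None = None,
) -> tuple[dict[str, CineTensor], pd.DataFrame]:
    """Register -> mask -> rescale every subject against the reference.

    The elliptical mask is built once from the reference subject's five
    boundary landmarks and reused for the whole cohort. Returns the
    processed sequences (insertion order preserved) and a QA table with
    per-landmark registration residuals.
    """
    if reference_id not in sequences:
        raise CinempcaError(f"reference subject {reference_id!r} not in dataset")
    if mask_variant not in ("small", "large", "none"):
        raise CinempcaError(f"unknown mask variant {mask_variant!r}")
    ref_lm = landmarks3[reference_id]
    ref_shape = sequences[reference_id].voxels.shape[:2]
    if qa_threshold is None:
        qa_threshold = 20.0 * ref_shape[0] / 512.0

    mask = None
    if mask_variant != "none":
        if boundary5 is None:
            raise CinempcaError("boundary landmarks required for elliptical masking")
        mask = ellipse_from_landmarks(boundary5)
        if mask_variant == "large":
            mask = mask.dilated(dilation_factor)

    out: dict[str, CineTensor] = {}
    qa_rows = []
    for sid, seq in sequences.items():
        t = fit_similarity(landmarks3[sid], ref_lm)
        warped = warp_sequence(seq, t, ref_shape)
        qa = registration_qa(t.apply(landmarks3[sid].points), ref_lm.points, qa_threshold)
        if mask is not None:
            warped = apply_mask(warped, mask)
        out[sid] = rescale(warped, scale)
        qa_rows.append(
            {
                "subject_id": sid,
                "residual_1": qa.residuals[0],
                "residual_2": qa.residuals[1],
                "residual_3": qa.residuals[2],
                "max_residual": qa.max_residual,
                "flagged": qa.flagged,
            }
        )
    return out, pd.DataFrame(qa_rows)
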