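"""Shared containers and errors.

Coordinate convention used throughout the package: pixel coordinates,
0-based, ``x`` = column, ``y`` = row, origin at the top-left pixel centre.
A cine sequence is stored as a rows x cols x frames array (I, J, K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CinempcaError(Exception):
    """Base class for package errors."""


class DegenerateLandmarksError(CinempcaError):
    """Landmark configuration does not determine the requested fit."""


class NotAnEllipseError(CinempcaError):
    """The conic through the boundary points is not an ellipse."""


class FormatError(CinempcaError):
    """A file did not match the expected on-disk format."""


class ValidationError(CinempcaError):
    """An input table failed schema validation."""


REGISTRATION_POINT_NAMES = ("hinge_inferior", "hinge_superior", "freewall_inflection")
BOUNDARY_POINT_NAMES = ("b1", "b2", "b3", "b4", "b5")


@dataclass
class CineTensor:
    """One subject's grayscale cine sequence.

    Parameters
    ----------
    voxels
        ``(I, J, K)`` array: rows ``I``, columns ``J``, frames ``K``.
    pixel_spacing
        In-plane pixel spacing in millimetres (isotropic).
    frame_of_reference
        ``"native"`` before registration, ``"registered"`` after.
    subject_id
        Free-form identifier.
    """

    voxels: np.ndarray
    pixel_spacing: float
    frame_of_reference: str = "native"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"cine sequence must be 3-D (rows, cols, frames); "
                f"got {self.voxels.ndim} dimensions"
            )
        if min(self.voxels.shape) < 1:
            raise FormatError(f"empty cine dimensions {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("cine sequence contains non-finite voxels")
        if not self.pixel_spacing > 0:
            raise FormatError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[2]

    def with_voxels(self, voxels: np.ndarray, **updates) -> "CineTensor":
        kwargs = dict(
            pixel_spacing=self.pixel_spacing,
            frame_of_reference=self.frame_of_reference,
            subject_id=self.subject_id,
        )
        kwargs.update(updates)
        return CineTensor(voxels=voxels, **kwargs)


@dataclass
class LandmarkSet:
    """Ordered landmark points on frame 1 of a sequence.

    ``role`` is ``"registration3"`` (3 paired registration points) or
    ``"boundary5"`` (5 heart-boundary points on the reference subject).
    Points are ``(x, y)`` pixel coordinates.
    """

    points: np.ndarray
    role: str = "registration3"

    _EXPECTED = {"registration3": 3, "boundary5": 5}

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.role not in self._EXPECTED:
            raise ValidationError(f"unknown landmark role {self.role!r}")
        n = self._EXPECTED[self.role]
        if self.points.shape != (n, 2):
            raise ValidationError(
                f"{self.role} requires {n} (x, y) points, got array of shape "
                f"{self.points.shape}"
            )
        d = np.linalg.norm(self.points[:, None] - self.points[None, :], axis=-1)
        if np.any(d[np.triu_indices(n, k=1)] < 1e-9):
            raise DegenerateLandmarksError("coincident landmark points")

    def __len__(self) -> int:
        return len(self.points)
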