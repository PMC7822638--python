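"""File formats: NIfTI-1 cine sequences, landmark/label CSV tables, run config.

Cine sequences are stored as 3-D NIfTI-1 volumes (rows x cols x frames)
with the in-plane pixel spacing on the first two pixdim entries; a
directory of ordered 2-D image frames (PNG/TIFF, 8- or 16-bit grayscale,
rescaled to [0, 1]) is accepted as a fallback. Landmark CSVs use the
schema ``subject_id,point_name,x,y`` with the package coordinate
convention (x = column, y = row, 0-based); labels CSVs use
``subject_id,label`` with label in {0, 1}.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import (
    BOUNDARY_POINT_NAMES,
    REGISTRATION_POINT_NAMES,
    CineTensor,
    FormatError,
    LandmarkSet,
    ValidationError,
)
from .phantom import PhantomSubject

_IMG_SUFFIXES = (".png", ".tif", ".tiff")


def write_cine(seq: CineTensor, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([seq.pixel_spacing, seq.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(seq.voxels.astype(np.float64), affine)
    img.header.set_zooms((seq.pixel_spacing, seq.pixel_spacing, 1.0))
    nib.save(img, path)
    return path


def read_cine(path: str | Path, subject_id: str | None = None) -> CineTensor:
    """Read a cine sequence from a 3-D NIfTI file or a directory of frames."""
    path = Path(path)
    if path.is_dir():
        return _read_frame_dir(path, subject_id)
    try:
        img = nib.load(path)
    except Exception as exc:  # unreadable header or not a NIfTI
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3-D cine volume (rows, cols, frames); got "
            f"{data.ndim} dimensions (offending axis 4 of size "
            f"{data.shape[3] if data.ndim > 3 else '?'})"
            if data.ndim > 3
            else f"{path}: expected a 3-D cine volume, got {data.ndim}-D data"
        )
    zooms = img.header.get_zooms()
    return CineTensor(
        voxels=np.asarray(data, dtype=float),
        pixel_spacing=float(zooms[0]),
        subject_id=subject_id or path.stem.replace(".nii", ""),
    )


def _read_frame_dir(path: Path, subject_id: str | None) -> CineTensor:
    """Stack an ordered directory of 2-D grayscale frames; integer images
    are rescaled to [0, 1] by their dtype maximum."""
    from imageio.v3 import imread

    frames = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMG_SUFFIXES)
    if not frames:
        raise FormatError(f"{path}: no frame images found")
    arrs = []
    for p in frames:
        a = np.asarray(imread(p), dtype=float)
        if a.ndim == 3:  # collapse identical colour channels
            a = a.mean(axis=2)
        if a.ndim != 2:
            raise FormatError(f"{p}: frames must be 2-D grayscale images")
        arrs.append(a)
    stack = np.stack(arrs, axis=2)
    src = imread(frames[0])
    if np.issubdtype(np.asarray(src).dtype, np.integer):
        stack = stack / float(np.iinfo(np.asarray(src).dtype).max)
    return CineTensor(voxels=stack, pixel_spacing=1.0, subject_id=subject_id or path.name)


def write_landmarks(landmarks: dict[str, dict[str, np.ndarray]], path: str | Path) -> Path:
    """Write a landmarks table: ``landmarks[subject_id][point_name] = (x, y)``."""
    rows = [
        {"subject_id": sid, "point_name": name, "x": float(p[0]), "y": float(p[1])}
        for sid, pts in landmarks.items()
        for name, p in pts.items()
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmarks(
    path: str | Path,
) -> tuple[dict[str, LandmarkSet], dict[str, LandmarkSet]]:
    """Parse a landmarks CSV into registration and boundary landmark sets.

    Returns ``(registration3 by subject, boundary5 by subject)``; the
    boundary dict normally holds the reference subject only. Unknown point
    names are ignored with a warning; duplicated or missing required
    points raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    required_cols = {"subject_id", "point_name", "x", "y"}
    if not required_cols.issubset(df.columns):
        raise FormatError(f"{path}: landmarks CSV needs columns {sorted(required_cols)}")
    known = set(REGISTRATION_POINT_NAMES) | set(BOUNDARY_POINT_NAMES)
    unknown = sorted(set(df["point_name"]) - known)
    if unknown:
        warnings.warn(f"ignoring unknown landmark point names: {unknown}")
        df = df[df["point_name"].isin(known)]
    reg: dict[str, LandmarkSet] = {}
    bnd: dict[str, LandmarkSet] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        counts = grp["point_name"].value_counts()
        dup = counts[counts > 1]
        if len(dup):
            raise ValidationError(
                f"subject {sid}: duplicated landmark point(s) {sorted(dup.index)}"
            )
        pts = {r.point_name: (r.x, r.y) for r in grp.itertuples()}
        missing = [n for n in REGISTRATION_POINT_NAMES if n not in pts]
        if missing:
            raise ValidationError(f"subject {sid}: missing required point(s) {missing}")
        reg[str(sid)] = LandmarkSet(
            np.array([pts[n] for n in REGISTRATION_POINT_NAMES]), role="registration3"
        )
        have_b = [n for n in BOUNDARY_POINT_NAMES if n in pts]
        if have_b:
            if len(have_b) != 5:
                missing_b = [n for n in BOUNDARY_POINT_NAMES if n not in pts]
                raise ValidationError(
                    f"subject {sid}: incomplete boundary landmarks, missing {missing_b}"
                )
            bnd[str(sid)] = LandmarkSet(
                np.array([pts[n] for n in BOUNDARY_POINT_NAMES]), role="boundary5"
            )
    return reg, bnd


def write_labels(labels: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"subject_id": sid, "label": int(lab)} for sid, lab in labels.items()]
    ).to_csv(path, index=False)
    return path


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    if not {"subject_id", "label"}.issubset(df.columns):
        raise FormatError(f"{path}: labels CSV needs columns subject_id,label")
    bad = set(df["label"]) - {0, 1}
    if bad:
        raise ValidationError(f"{path}: labels must be 0/1, found {sorted(bad)}")
    return {str(r.subject_id): int(r.label) for r in df.itertuples()}


def write_phantom_dataset(subjects: list[PhantomSubject], out_dir: str | Path) -> Path:
    """Write a phantom cohort: one NIfTI per subject, labels.csv, landmarks.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels, lms = {}, {}
    for s in subjects:
        write_cine(s.sequence, out_dir / f"{s.subject_id}.nii.gz")
        labels[s.subject_id] = s.label
        pts = {
            name: s.landmarks3.points[i] for i, name in enumerate(REGISTRATION_POINT_NAMES)
        }
        if s.boundary5 is not None:
            pts.update(
                {name: s.boundary5.points[i] for i, name in enumerate(BOUNDARY_POINT_NAMES)}
            )
        lms[s.subject_id] = pts
    write_labels(labels, out_dir / "labels.csv")
    write_landmarks(lms, out_dir / "landmarks.csv")
    return out_dir


def read_dataset(
    in_dir: str | Path,
) -> tuple[dict[str, CineTensor], dict[str, LandmarkSet], dict[str, LandmarkSet], dict[str, int]]:
    """Read a dataset directory written by :func:`write_phantom_dataset`."""
    in_dir = Path(in_dir)
    labels = read_labels(in_dir / "labels.csv")
    reg, bnd = read_landmarks(in_dir / "landmarks.csv")
    seqs = {}
    for sid in labels:
        p = in_dir / f"{sid}.nii.gz"
        if not p.exists():
            p = in_dir / f"{sid}.nii"
        seqs[sid] = read_cine(p, subject_id=sid)
    return seqs, reg, bnd, labels


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; serialised beside outputs."""

    data_dir: str = ""
    out_dir: str = ""
    reference_id: str = ""
    mask_variant: str = "small"
    scale: int = 64
    classifier: str = "svm"
    variance_threshold: float = 0.97
    S_grid: list[int] | None = None
    C: float = 1.0
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0
    qa_threshold: float | None = None
    dilation_factor: float = 1.5

    def to_yaml(self, path: str | Path) -> Path:
        from . import __version__

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["cinempca_version"] = __version__
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload.pop("cinempca_version", None)
        return cls(**payload)


def write_metrics(metrics: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return path
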