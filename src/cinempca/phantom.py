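"""Synthetic two-class beating-heart cine phantom.

Emulates short-axis cine sequences of a left ventricle (bright blood pool
inside a myocardial ring), a crescent-shaped right ventricle sharing the
septal wall, and a smooth periodic contraction over the cardiac cycle with
end-systole at mid-cycle. The disease class differs from the control class
in two ways, both scaled by ``effect_size``:

* septal bowing — the septal arc of the LV wall is displaced toward the
  LV cavity, mimicking the septal-configuration change seen in pulmonary
  arterial hypertension;
* reduced RV radial contraction amplitude.

Each subject is independently posed by a similarity transform (translation,
rotation, isotropic scale, optional left-right flip) from the same family
the registration module fits, so registration is exactly invertible in the
noise-free limit. Images are produced by evaluating the analytic geometry
at inverse-posed pixel coordinates, so landmark correspondence is exact.
Pixel intensities lie in [0.15, 0.75] before additive Gaussian noise and
clipping to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BOUNDARY_POINT_NAMES,
    REGISTRATION_POINT_NAMES,
    CineTensor,
    CinempcaError,
    LandmarkSet,
)
from .preprocess import SimilarityTransform

# geometry as fractions of the image side
_LV_DX = 0.10  # LV centre offset from image centre, +x
_RV_DX = -0.08  # RV centre offset, -x (septal side)
_R_LV_OUT = 0.17  # LV epicardial radius at end-diastole
_LV_WALL = 0.05  # LV wall thickness at end-diastole
_LV_WALL_THICKEN = 0.02  # additional systolic wall thickness
_LV_RADIAL_CONTRACTION = 0.10  # fractional epicardial radius reduction at end-systole
_R_RV = 0.21  # RV epicardial radius at end-diastole
_RV_WALL = 0.03  # RV free-wall thickness
_RV_AMP_BASE = 0.35  # healthy RV radial contraction amplitude
_RV_AMP_DEFICIT = 0.55  # fraction of amplitude lost at effect_size = 1
_SEPTAL_BOW = 0.18  # fractional septal radius reduction at effect_size = 1
_BOW_WIDTH = 0.6  # angular width (rad) of the septal bowing bump
_ELLIPSE_AX = 0.34  # boundary-ellipse semi-axes (fractions of side)
_ELLIPSE_AY = 0.28
_ELLIPSE_ANGLES_DEG = (10.0, 80.0, 152.0, 224.0, 296.0)

_BG, _MYO, _BLOOD = 0.15, 0.45, 0.75
_EDGE_PX = 0.8  # soft-edge width for anti-aliased boundaries

FIELD_OF_VIEW_MM = 480.0


@dataclass
class PhantomConfig:
    """Study-condition parameters of the synthetic cohort.

    ``effect_size`` in [0, 1] scales both disease effects; 0 makes the two
    classes exchangeable, 1 the nominal disease. ``noise_sd`` is additive
    Gaussian noise on the [0, 1] intensity scale. Pose ranges bound the
    per-subject similarity transform.
    """

    n_per_class: int = 50
    image_size: int = 128
    n_frames: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.05
    max_translation: float = 6.0
    max_rotation: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise CinempcaError("n_per_class must be >= 1")
        if self.image_size < 16:
            raise CinempcaError("image_size must be >= 16")
        if self.n_frames < 2:
            raise CinempcaError("n_frames must be >= 2")
        if not 0.0 <= self.effect_size <= 1.0:
            raise CinempcaError("effect_size must lie in [0, 1]")
        if self.noise_sd < 0:
            raise CinempcaError("noise_sd must be >= 0")
        if not 0 < self.scale_range[0] <= self.scale_range[1]:
            raise CinempcaError("invalid scale_range")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise CinempcaError("flip_prob must lie in [0, 1]")

    @property
    def pixel_spacing(self) -> float:
        return FIELD_OF_VIEW_MM / self.image_size


@dataclass
class PhantomSubject:
    sequence: CineTensor
    label: int  # 0 = control, 1 = disease
    true_pose: SimilarityTransform
    landmarks3: LandmarkSet
    boundary5: LandmarkSet | None = None

    @property
    def subject_id(self) -> str:
        return self.sequence.subject_id


def _contraction(frame: int, n_frames: int) -> float:
    """Smooth 0->1->0 contraction over the cycle, end-systole at mid-cycle."""
    return float(np.sin(np.pi * frame / (n_frames - 1)) ** 2)


def _smooth(signed_dist: np.ndarray) -> np.ndarray:
    """Linear smoothstep: 1 well inside (positive distance), 0 well outside."""
    return np.clip(signed_dist / _EDGE_PX + 0.5, 0.0, 1.0)


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + np.pi) % (2 * np.pi) - np.pi


def _centres(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    lv = c + np.array([_LV_DX * size, 0.0])
    rv = c + np.array([_RV_DX * size, 0.0])
    return c, lv, rv


def render_frame(
    xs: np.ndarray, ys: np.ndarray, frame: int, config: PhantomConfig
) -> np.ndarray:
    """Evaluate the noiseless phantom at canonical coordinates ``(xs, ys)``."""
    size = config.image_size
    _, lv, rv = _centres(size)
    c = _contraction(frame, config.n_frames)
    eff = config.effect_size

    img = np.full(np.broadcast(xs, ys).shape, _BG, dtype=float)

    # right ventricle: epicardial disc, then cavity; later overpainted by LV
    rho_rv = np.hypot(xs - rv[0], ys - rv[1])
    amp = _RV_AMP_BASE * (1.0 - _RV_AMP_DEFICIT * eff)
    rr_out = _R_RV * size * (1.0 - amp * c)
    rr_in = rr_out - _RV_WALL * size
    for radius, value in ((rr_out, _MYO), (rr_in, _BLOOD)):
        alpha = _smooth(radius - rho_rv)
        img = img * (1 - alpha) + value * alpha

    # left ventricle: star-shaped boundary r(theta) with a septal bump at
    # theta = pi (the direction facing the RV)
    dxl, dyl = xs - lv[0], ys - lv[1]
    rho_lv = np.hypot(dxl, dyl)
    theta = np.arctan2(dyl, dxl)
    bump = np.exp(-(_wrap(theta - np.pi) / _BOW_WIDTH) ** 2)
    r_out = _R_LV_OUT * size * (1.0 - _LV_RADIAL_CONTRACTION * c) * (
        1.0 - _SEPTAL_BOW * eff * bump
    )
    wall = (_LV_WALL + _LV_WALL_THICKEN * c) * size
    r_in = np.maximum(r_out - wall, 1.0)
    for radius, value in ((r_out, _MYO), (r_in, _BLOOD)):
        alpha = _smooth(radius - rho_lv)
        img = img * (1 - alpha) + value * alpha
    return img


def canonical_landmarks(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Analytic landmark coordinates in canonical (unposed) space.

    Registration landmarks are the two septal hinge points (intersections
    of the nominal end-diastolic LV and RV epicardial circles) and the
    inflection point of the RV free wall (its leftmost point). Boundary
    points b1..b5 sit on an ellipse enclosing the whole heart. A pure
    function of the geometry; independent of class, pose and noise.
    """
    size = config.image_size
    centre, lv, rv = _centres(size)
    r1 = _R_LV_OUT * size
    r2 = _R_RV * size
    d = float(np.linalg.norm(lv - rv))
    # circle-circle intersection (LV outer vs RV outer, end-diastole)
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = np.sqrt(r1 * r1 - a * a)
    ex = (rv - lv) / d  # unit vector LV centre -> RV centre
    ey = np.array([-ex[1], ex[0]])
    base = lv + a * ex
    p_up = base + h * ey
    p_dn = base - h * ey
    hinge_superior, hinge_inferior = (p_up, p_dn) if p_up[1] < p_dn[1] else (p_dn, p_up)
    freewall = rv + np.array([-r2, 0.0])

    out = {
        "hinge_inferior": hinge_inferior,
        "hinge_superior": hinge_superior,
        "freewall_inflection": freewall,
    }
    for name, ang in zip(BOUNDARY_POINT_NAMES, _ELLIPSE_ANGLES_DEG):
        th = np.deg2rad(ang)
        out[name] = centre + np.array(
            [_ELLIPSE_AX * size * np.cos(th), _ELLIPSE_AY * size * np.sin(th)]
        )
    return out


def _landmark_sets(points: dict[str, np.ndarray]) -> tuple[LandmarkSet, LandmarkSet]:
    reg = LandmarkSet(
        np.array([points[n] for n in REGISTRATION_POINT_NAMES]), role="registration3"
    )
    bnd = LandmarkSet(np.array([points[n] for n in BOUNDARY_POINT_NAMES]), role="boundary5")
    return reg, bnd


def effect_region_mask(config: PhantomConfig, size: int | None = None) -> np.ndarray:
    """Boolean (rows, cols) mask of the region where the disease effect acts.

    Union of the RV neighbourhood (where the contraction deficit changes
    the wall position) and the septal sector of the LV (where the bowing
    bump is non-negligible), in canonical space. Outside this region the
    class-conditional mean images agree to below the noise floor when pose
    is disabled.
    """
    if size is None:
        size = config.image_size
    f = size / config.image_size
    _, lv, rv = _centres(config.image_size)
    lv, rv = lv * f, rv * f
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rv_zone = np.hypot(xx - rv[0], yy - rv[1]) <= (_R_RV * config.image_size + 3.0) * f
    dxl, dyl = xx - lv[0], yy - lv[1]
    theta = np.arctan2(dyl, dxl)
    septal = (np.hypot(dxl, dyl) <= (_R_LV_OUT * config.image_size + 3.0) * f) & (
        np.abs(_wrap(theta - np.pi)) <= 3.0 * _BOW_WIDTH
    )
    return rv_zone | septal


def _sample_pose(rng: np.random.Generator, config: PhantomConfig, size: int) -> SimilarityTransform:
    """Similarity transform about the image centre, within the pose ranges."""
    rot = rng.uniform(-config.max_rotation, config.max_rotation)
    scl = rng.uniform(*config.scale_range)
    tx, ty = rng.uniform(-config.max_translation, config.max_translation, size=2)
    flip = bool(rng.random() < config.flip_prob)
    centre = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    pivot = SimilarityTransform(rotation=rot, scale=scl, reflect=flip)
    # rotate/scale/flip about the centre, then translate
    trans = centre + np.array([tx, ty]) - pivot.matrix @ centre
    return SimilarityTransform(
        rotation=rot, scale=scl, translation=(float(trans[0]), float(trans[1])), reflect=flip
    )


def generate_subject(
    config: PhantomConfig,
    label: int,
    pose: SimilarityTransform,
    rng: np.random.Generator,
    subject_id: str,
    is_reference: bool = False,
) -> PhantomSubject:
    """Render one posed, noisy subject of the given class."""
    size, k = config.image_size, config.n_frames
    sub_cfg = dataclasses.replace(config, effect_size=config.effect_size * label)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    canon = pose.inverse().apply(grid)
    cx = canon[:, 0].reshape(size, size)
    cy = canon[:, 1].reshape(size, size)
    vox = np.empty((size, size, k))
    for f in range(k):
        vox[:, :, f] = render_frame(cx, cy, f, sub_cfg)
    if config.noise_sd > 0:
        vox = np.clip(vox + rng.normal(0.0, config.noise_sd, vox.shape), 0.0, 1.0)

    pts = canonical_landmarks(config)
    reg, bnd = _landmark_sets(pts)
    reg = LandmarkSet(pose.apply(reg.points), role="registration3")
    bnd_posed = LandmarkSet(pose.apply(bnd.points), role="boundary5") if is_reference else None
    seq = CineTensor(
        vox,
        pixel_spacing=config.pixel_spacing,
        frame_of_reference="native",
        subject_id=subject_id,
    )
    return PhantomSubject(
        sequence=seq, label=label, true_pose=pose, landmarks3=reg, boundary5=bnd_posed
    )


def generate_phantom(config: PhantomConfig) -> list[PhantomSubject]:
    """Generate the two-class cohort: ``n_per_class`` controls then diseases.

    The first control subject is the cohort reference: it carries the five
    boundary landmarks and an identity pose, so reference space coincides
    with canonical space. All other subjects are independently posed.
    Identical config (including seed) reproduces the cohort bit-exactly.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[PhantomSubject] = []
    for label, prefix in ((0, "ctrl"), (1, "dis")):
        for i in range(config.n_per_class):
            sid = f"{prefix}{i:03d}"
            is_ref = label == 0 and i == 0
            pose = (
                SimilarityTransform()
                if is_ref
                else _sample_pose(rng, config, config.image_size)
            )
            subjects.append(
                generate_subject(config, label, pose, rng, sid, is_reference=is_ref)
            )
    return subjects


def reference_subject(subjects: list[PhantomSubject]) -> PhantomSubject:
    for s in subjects:
        if s.boundary5 is not None:
            return s
    raise CinempcaError("no reference subject (boundary landmarks) in cohort")
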