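"""Socket rectification features: definition, application and extraction.

A prosthetist turns a residual-limb shape into a socket by a small set
of named local rectifications — carves (socket pressed into the limb at
load-tolerant regions, negative offsets) and builds (relief gaps over
bony or sensitive regions, positive offsets) — plus a gross volume
change.  This module represents each local feature as a fixed spatial
template (a compact raised-cosine bump anchored at anatomical
landmarks) scaled by a signed magnitude in mm, and the volume change as
a uniform radial scale applied after the local offsets:

    socket_r = sqrt(1 + v) * (limb_r + sum_f m_f * K_f)

where ``v`` is the signed volume-change fraction (sqrt because the
enclosed volume of a solid of revolution scales with the square of a
radial scale).  :func:`extract_rectifications` inverts this map by
sign-constrained least squares, which is how design features are
recovered from historical limb–socket pairs to train the evidence model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.optimize import lsq_linear

from .aop_io import LimbScan, enclosed_volume

__all__ = [
    "FEATURES",
    "LOCAL_FEATURES",
    "CARVE_FEATURES",
    "BUILD_FEATURES",
    "RectificationSet",
    "KernelSpec",
    "default_kernel_specs",
    "kernel_field",
    "apply_rectifications",
    "extract_rectifications",
    "OverCarveError",
]

#: Local features and their anchor landmarks.  Bilateral features
#: (paratibial, supracondylar) carry one scalar applied at both anchors.
_ANCHORS = {
    "patella_tendon_bar": ("PATELLAR_TENDON",),
    "paratibial": ("PARATIBIAL_MEDIAL", "PARATIBIAL_LATERAL"),
    "fibula_head": ("FIBULAR_HEAD",),
    "distal_end": ("DISTAL_END",),
    "distal_tibia": ("DISTAL_TIBIA",),
    "anterior_tibia": ("TIBIAL_CREST",),
    "supracondylar": ("SUPRACONDYLAR_MEDIAL", "SUPRACONDYLAR_LATERAL"),
}

CARVE_FEATURES = ("patella_tendon_bar", "paratibial", "supracondylar")
BUILD_FEATURES = ("fibula_head", "distal_end", "distal_tibia", "anterior_tibia")
LOCAL_FEATURES = tuple(_ANCHORS)
FEATURES = LOCAL_FEATURES + ("volume_change",)


@dataclass
class RectificationSet:
    """Signed design-feature magnitudes: the design vector Y.

    Carves are ≤ 0 mm, builds ≥ 0 mm; ``volume_change`` is a signed
    fraction of enclosed volume (−0.05 = 5% reduction), |v| < 0.5.
    """

    patella_tendon_bar: float = 0.0  # mm, carve
    paratibial: float = 0.0          # mm, carve (both paratibial anchors)
    fibula_head: float = 0.0         # mm, build
    distal_end: float = 0.0          # mm, build
    distal_tibia: float = 0.0        # mm, build
    anterior_tibia: float = 0.0      # mm, build
    supracondylar: float = 0.0       # mm, carve (both supracondylar anchors)
    volume_change: float = 0.0       # fraction

    def __post_init__(self) -> None:
        for name in CARVE_FEATURES:
            if getattr(self, name) > 0:
                raise ValueError(f"carve feature {name} must be <= 0")
        for name in BUILD_FEATURES:
            if getattr(self, name) < 0:
                raise ValueError(f"build feature {name} must be >= 0")
        if not abs(self.volume_change) < 0.5:
            raise ValueError("|volume_change| must be < 0.5")

    def as_array(self) -> np.ndarray:
        """Magnitudes in FEATURES order (volume_change last)."""
        return np.array([getattr(self, f) for f in FEATURES])

    @classmethod
    def from_array(cls, values) -> "RectificationSet":
        return cls(**dict(zip(FEATURES, np.asarray(values, dtype=float))))

    @classmethod
    def clip_to_feasible(cls, values) -> "RectificationSet":
        """Build a set from unconstrained values, clipping each to its sign range."""
        v = np.asarray(values, dtype=float).copy()
        for i, name in enumerate(FEATURES[:-1]):
            if name in CARVE_FEATURES:
                v[i] = min(v[i], 0.0)
            else:
                v[i] = max(v[i], 0.0)
        v[-1] = float(np.clip(v[-1], -0.499, 0.499))
        return cls.from_array(v)

    def to_json(self) -> str:
        return json.dumps({f.name: getattr(self, f.name) for f in dc_fields(self)})

    @classmethod
    def from_json(cls, text: str) -> "RectificationSet":
        return cls(**json.loads(text))

    @staticmethod
    def sign_bounds() -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) feasible bounds for the 7 local features."""
        lo = np.array([-np.inf if f in CARVE_FEATURES else 0.0 for f in LOCAL_FEATURES])
        hi = np.array([0.0 if f in CARVE_FEATURES else np.inf for f in LOCAL_FEATURES])
        return lo, hi


@dataclass(frozen=True)
class KernelSpec:
    """Spatial footprint of one local feature.

    A separable raised-cosine bump centred at each anchor landmark:
    value 1 at the anchor, falling to exactly 0 at the angular
    half-width (degrees, wrapped) and axial half-height (mm).  The
    distal-end feature instead uses an axial cap profile: weight 1 at
    the distal end over all angles, decaying to 0 at the half-height.
    """

    feature: str
    half_width_deg: float = 20.0
    half_height_mm: float = 20.0
    cap: bool = False

    def __post_init__(self) -> None:
        if self.feature not in _ANCHORS:
            raise ValueError(f"unknown local feature {self.feature!r}")
        if not (0.0 < self.half_width_deg <= 90.0):
            raise ValueError("half-width must be in (0, 90] degrees")
        if self.half_height_mm <= 0:
            raise ValueError("half-height must be positive")

    @property
    def anchors(self) -> tuple[str, ...]:
        return _ANCHORS[self.feature]


def default_kernel_specs() -> dict[str, KernelSpec]:
    """Default footprints (degrees / mm) for the 7 local features."""
    return {
        "patella_tendon_bar": KernelSpec("patella_tendon_bar", 25.0, 15.0),
        "paratibial": KernelSpec("paratibial", 20.0, 40.0),
        "fibula_head": KernelSpec("fibula_head", 20.0, 20.0),
        "distal_tibia": KernelSpec("distal_tibia", 25.0, 20.0),
        "anterior_tibia": KernelSpec("anterior_tibia", 15.0, 60.0),
        "supracondylar": KernelSpec("supracondylar", 30.0, 20.0),
        "distal_end": KernelSpec("distal_end", 90.0, 25.0, cap=True),
    }


def _raised_cosine(x: np.ndarray, half: float) -> np.ndarray:
    """0.5*(1+cos(pi*x/half)) inside |x| < half, exactly 0 outside."""
    w = np.zeros_like(x, dtype=float)
    inside = np.abs(x) < half
    w[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside] / half))
    return w


class OverCarveError(ValueError):
    """A rectification drove a socket radius non-positive."""


def kernel_field(spec: KernelSpec, scan: LimbScan) -> np.ndarray:
    """Weight matrix (n_slices × n_theta) in [0, 1] for one feature.

    Bumps at multiple anchors are max-combined, so the field is
    symmetric in the anchor order.  Raises ``KeyError`` if an anchor
    landmark is missing from the scan.
    """
    g = scan.grid
    theta = g.theta_deg
    z = g.slice_z
    field_w = np.zeros((g.n_slices, g.n_theta))
    for name in spec.anchors:
        if name not in scan.landmarks:
            raise KeyError(f"scan lacks anchor landmark {name!r} for {spec.feature}")
        si, ti = scan.landmarks[name]
        if spec.cap:
            # axial cap: weight depends on height above the distal end only
            wz = _raised_cosine(z - z[0], spec.half_height_mm)
            # include the cap edge exactly at z = z[0] (peak 1 across all theta)
            w = np.repeat(wz[:, None], g.n_theta, axis=1)
        else:
            dth = (theta - theta[ti] + 180.0) % 360.0 - 180.0
            dz = z - z[si]
            w = np.outer(_raised_cosine(dz, spec.half_height_mm),
                         _raised_cosine(dth, spec.half_width_deg))
        np.maximum(field_w, w, out=field_w)
    return field_w


def apply_rectifications(
    limb: LimbScan,
    rects: RectificationSet,
    specs: dict[str, KernelSpec] | None = None,
) -> LimbScan:
    """Apply a design vector to an aligned limb, producing the socket surface.

    socket_r = sqrt(1 + volume_change) * (limb_r + Σ m_f K_f).
    Landmarks are copied.  Raises :class:`OverCarveError` naming the
    worst feature and grid point if any socket radius would be ≤ 0.
    """
    specs = specs if specs is not None else default_kernel_specs()
    offset = np.zeros_like(limb.radii)
    for name in LOCAL_FEATURES:
        m = getattr(rects, name)
        if m != 0.0:
            offset += m * kernel_field(specs[name], limb)
    s = np.sqrt(1.0 + rects.volume_change)
    radii = s * (limb.radii + offset)
    if np.any(radii <= 0):
        i, j = np.unravel_index(np.argmin(radii), radii.shape)
        worst = min(
            (name for name in CARVE_FEATURES if getattr(rects, name) < 0),
            key=lambda n: getattr(rects, n),
            default="volume_change",
        )
        raise OverCarveError(
            f"non-positive socket radius at slice {i}, theta index {j} "
            f"(dominant carve: {worst})"
        )
    socket = limb.copy()
    socket.radii = radii
    socket.meta["rectified"] = "true"
    return socket


def extract_rectifications(
    limb: LimbScan,
    socket: LimbScan,
    specs: dict[str, KernelSpec] | None = None,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[RectificationSet, float]:
    """Recover the design vector from a limb–socket pair.

    The volume-change scale and the local magnitudes are estimated
    jointly by fixed-point iteration: the scale ŝ is set so the
    rectified limb's enclosed volume matches the socket's, and the
    local magnitudes are re-fit by sign-constrained least squares of
    the kernel fields against the de-scaled difference field
    ``socket/ŝ − limb``.  Returns the set and the residual RMS (mm) of
    the unexplained difference.
    """
    if limb.radii.shape != socket.radii.shape or not np.allclose(
        limb.grid.slice_z, socket.grid.slice_z
    ):
        raise ValueError("limb and socket must share an identical grid")
    specs = specs if specs is not None else default_kernel_specs()

    fields = np.stack(
        [kernel_field(specs[name], limb).ravel() for name in LOCAL_FEATURES], axis=1
    )
    lo, hi = RectificationSet.sign_bounds()
    v_limb = enclosed_volume(limb)
    v_socket = enclosed_volume(socket)

    s_hat = np.sqrt(v_socket / v_limb)
    coef = np.zeros(len(LOCAL_FEATURES))
    limb_flat = limb.radii.ravel()
    for _ in range(max_iter):
        target = socket.radii.ravel() / s_hat - limb_flat
        res = lsq_linear(fields, target, bounds=(lo, hi), tol=1e-14)
        coef = res.x
        # refine the scale against the volume of the locally rectified limb
        rect_radii = limb.radii + (fields @ coef).reshape(limb.radii.shape)
        rect_radii = np.maximum(rect_radii, 1e-9)
        v_rect = enclosed_volume(limb.with_radii(rect_radii))
        s_new = np.sqrt(v_socket / v_rect)
        if abs(s_new - s_hat) < tol:
            s_hat = s_new
            break
        s_hat = s_new

    target = socket.radii.ravel() / s_hat - limb_flat
    residual = target - fields @ coef
    rms = float(np.sqrt(np.mean(residual**2)))
    values = np.append(coef, s_hat**2 - 1.0)
    # squash numerical dust so exact round trips report exact zeros
    values[np.abs(values) < 1e-12] = 0.0
    return RectificationSet.clip_to_feasible(values), rms
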