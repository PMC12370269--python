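"""Cylindrically sampled limb/socket surfaces: file I/O and mesh export.

Residual-limb and socket shapes are represented on a cylindrical grid:
``n_slices`` horizontal slices (slice 0 distal-most), each sampled at
``n_theta`` equally spaced angles, storing the surface radius in mm at
every (slice, angle) node.  This mirrors the sampling used by clinical
CAD exports (at most 3 degrees angular spacing, at least 90 slices).

Shapes are persisted in an AAOP-style plain-text dialect documented in
:func:`write_aop`.  The dialect is this toolkit's own and is not
guaranteed byte-compatible with commercial exports.  Meshes are written
as binary STL via :func:`to_stl`.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "LANDMARK_NAMES",
    "CylindricalGrid",
    "LimbScan",
    "MeshSummary",
    "AopParseError",
    "read_aop",
    "write_aop",
    "to_stl",
    "surface_mesh",
    "enclosed_volume",
]

#: Anatomical landmark vocabulary for transtibial residua.  θ=0 is
#: anterior; θ increases toward the lateral side of a right limb.
LANDMARK_NAMES = (
    "PATELLAR_TENDON",
    "FIBULAR_HEAD",
    "TIBIAL_CREST",
    "DISTAL_TIBIA",
    "PARATIBIAL_MEDIAL",
    "PARATIBIAL_LATERAL",
    "SUPRACONDYLAR_MEDIAL",
    "SUPRACONDYLAR_LATERAL",
    "DISTAL_END",
)

_DIALECT = "AAOP1"


class AopParseError(ValueError):
    """Malformed AOP-style file; message carries the offending line number."""


@dataclass(frozen=True)
class CylindricalGrid:
    """Sampling lattice for a limb or socket surface.

    Parameters
    ----------
    slice_z
        Axial height of each slice in mm, strictly increasing;
        slice 0 is the distal-most slice.
    n_theta
        Number of angular samples per slice.  Samples sit at
        ``k * 360 / n_theta`` degrees for ``k = 0 .. n_theta - 1``.
    """

    slice_z: np.ndarray
    n_theta: int

    def __post_init__(self) -> None:
        z = np.asarray(self.slice_z, dtype=float)
        object.__setattr__(self, "slice_z", z)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("grid needs at least 2 slices")
        if not np.all(np.isfinite(z)) or np.any(np.diff(z) <= 0):
            raise ValueError("slice_z must be finite and strictly increasing")
        if self.n_theta < 3:
            raise ValueError("n_theta must be at least 3")

    @property
    def n_slices(self) -> int:
        return int(self.slice_z.size)

    @property
    def theta_step(self) -> float:
        """Angular spacing in degrees (exactly 360 / n_theta)."""
        return 360.0 / self.n_theta

    @property
    def theta_deg(self) -> np.ndarray:
        return np.arange(self.n_theta) * self.theta_step

    @classmethod
    def default(
        cls, length: float = 180.0, n_slices: int = 90, n_theta: int = 120
    ) -> "CylindricalGrid":
        """Grid satisfying the clinical sampling bound (θ step ≤ 3°, ≥ 90 slices)."""
        if n_slices < 90 or 360.0 / n_theta > 3.0:
            raise ValueError("default grid must have >=90 slices and <=3 deg spacing")
        return cls(np.linspace(0.0, length, n_slices), n_theta)

    def meets_sampling_bound(self) -> bool:
        return self.n_slices >= 90 and self.theta_step <= 3.0


@dataclass
class LimbScan:
    """A cylindrically sampled surface with named anatomical landmarks.

    ``radii`` is an (n_slices, n_theta) array of surface radii in mm;
    ``landmarks`` maps a landmark name to its (slice index, theta index)
    grid node.  ``side`` records limb laterality; internal processing
    mirrors left limbs into a right-limb frame (see :mod:`socketgen.ssm`).
    """

    grid: CylindricalGrid
    radii: np.ndarray
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)
    side: str = "right"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (self.grid.n_slices, self.grid.n_theta):
            raise ValueError(
                f"radii shape {self.radii.shape} does not match grid "
                f"({self.grid.n_slices}, {self.grid.n_theta})"
            )
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise ValueError("all radii must be positive and finite")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for name, (i, j) in self.landmarks.items():
            if name not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark {name!r}")
            if not (0 <= i < self.grid.n_slices and 0 <= j < self.grid.n_theta):
                raise ValueError(f"landmark {name} at ({i}, {j}) is off-grid")

    def copy(self) -> "LimbScan":
        return LimbScan(
            grid=self.grid,
            radii=self.radii.copy(),
            landmarks=dict(self.landmarks),
            side=self.side,
            meta=dict(self.meta),
        )

    def with_radii(self, radii: np.ndarray) -> "LimbScan":
        return replace(self, radii=np.asarray(radii, dtype=float))

    @property
    def length(self) -> float:
        """Axial extent (mm) from the distal end to the most proximal slice."""
        return float(self.grid.slice_z[-1] - self.grid.slice_z[0])


@dataclass(frozen=True)
class MeshSummary:
    n_vertices: int
    n_triangles: int
    volume_mm3: float


def read_aop(path) -> LimbScan:
    """Read an AOP-style text file (dialect of :func:`write_aop`).

    Raises :class:`AopParseError` naming the offending line on malformed
    headers, non-numeric radii, off-grid landmarks or fewer than 2 slices.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    def fail(lineno: int, msg: str):
        raise AopParseError(f"{path}: line {lineno}: {msg}")

    if not lines or lines[0].strip() != _DIALECT:
        fail(1, f"expected header {_DIALECT!r}")
    try:
        n_slices, n_theta = (int(t) for t in lines[1].split())
    except (IndexError, ValueError):
        fail(2, "expected '<n_slices> <n_theta>'")
    if n_slices < 2:
        fail(2, "fewer than 2 slices")
    toks = lines[2].split() if len(lines) > 2 else []
    if len(toks) != 2 or toks[0] != "SIDE" or toks[1] not in ("LEFT", "RIGHT"):
        fail(3, "expected 'SIDE LEFT|RIGHT'")
    side = toks[1].lower()

    landmarks: dict[str, tuple[int, int]] = {}
    k = 3
    while k < len(lines) and lines[k].startswith("LMK"):
        parts = lines[k].split()
        if len(parts) != 4:
            fail(k + 1, "expected 'LMK <name> <slice> <theta_index>'")
        name = parts[1]
        try:
            i, j = int(parts[2]), int(parts[3])
        except ValueError:
            fail(k + 1, "non-integer landmark indices")
        if name not in LANDMARK_NAMES:
            fail(k + 1, f"unknown landmark {name!r}")
        if not (0 <= i < n_slices and 0 <= j < n_theta):
            fail(k + 1, f"landmark {name} at ({i}, {j}) is off-grid")
        landmarks[name] = (i, j)
        k += 1

    slice_z = np.empty(n_slices)
    radii = np.empty((n_slices, n_theta))
    for s in range(n_slices):
        lineno = k + s
        if lineno >= len(lines):
            fail(lineno + 1, "unexpected end of file in slice data")
        parts = lines[lineno].split()
        if len(parts) != 1 + n_theta:
            fail(lineno + 1, f"expected 1 z value + {n_theta} radii, got {len(parts)} tokens")
        try:
            vals = np.array([float(t) for t in parts])
        except ValueError:
            fail(lineno + 1, "non-numeric value in slice data")
        slice_z[s] = vals[0]
        radii[s] = vals[1:]

    try:
        grid = CylindricalGrid(slice_z, n_theta)
        scan = LimbScan(grid, radii, landmarks, side)
    except ValueError as exc:
        raise AopParseError(f"{path}: {exc}") from exc
    scan.meta["source"] = str(path)
    scan.meta["dialect"] = _DIALECT
    return scan


def write_aop(scan: LimbScan, path) -> None:
    """Write ``scan`` as AOP-style text; byte-deterministic for equal input.

    Format (UTF-8, '.' decimal separator)::

        AAOP1
        <n_slices> <n_theta>
        SIDE LEFT|RIGHT
        LMK <name> <slice_index> <theta_index>     (one line per landmark)
        <z_mm> <r_0> <r_1> ... <r_{n_theta-1}>     (one line per slice)

    Radii and z are written with 9 significant digits (repr-stable well
    below the 1e-6 mm round-trip tolerance).
    """
    g = scan.grid
    out = [_DIALECT, f"{g.n_slices} {g.n_theta}", f"SIDE {scan.side.upper()}"]
    for name in sorted(scan.landmarks):
        i, j = scan.landmarks[name]
        out.append(f"LMK {name} {i} {j}")
    for s in range(g.n_slices):
        row = " ".join(f"{v:.9g}" for v in scan.radii[s])
        out.append(f"{g.slice_z[s]:.9g} {row}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def surface_mesh(scan: LimbScan) -> trimesh.Trimesh:
    """Closed 2-manifold mesh of the scan: grid side wall + fan caps.

    Triangle count is ``2*n_theta*(n_slices-1)`` for the wall plus
    ``2*n_theta`` for the two caps; normals point outward.
    """
    g = scan.grid
    if g.n_theta < 3:
        raise ValueError("degenerate grid: n_theta < 3")
    theta = np.deg2rad(g.theta_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # vertex (s, k) at index s*n_theta + k
    verts = np.empty((g.n_slices * g.n_theta + 2, 3))
    for s in range(g.n_slices):
        r = scan.radii[s]
        base = s * g.n_theta
        verts[base : base + g.n_theta, 0] = r * cos_t
        verts[base : base + g.n_theta, 1] = r * sin_t
        verts[base : base + g.n_theta, 2] = g.slice_z[s]
    c_bot = g.n_slices * g.n_theta
    c_top = c_bot + 1
    verts[c_bot] = (0.0, 0.0, g.slice_z[0])
    verts[c_top] = (0.0, 0.0, g.slice_z[-1])

    k = np.arange(g.n_theta)
    k2 = (k + 1) % g.n_theta
    faces = []
    for s in range(g.n_slices - 1):
        a = s * g.n_theta + k
        b = s * g.n_theta + k2
        c = (s + 1) * g.n_theta + k
        d = (s + 1) * g.n_theta + k2
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([b, d, c]))
    top = (g.n_slices - 1) * g.n_theta
    faces.append(np.column_stack([np.full(g.n_theta, c_bot), k2, k]))
    faces.append(np.column_stack([np.full(g.n_theta, c_top), top + k, top + k2]))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def enclosed_volume(scan: LimbScan) -> float:
    """Volume (mm³) enclosed by the scan's surface mesh."""
    return float(surface_mesh(scan).volume)


def to_stl(scan: LimbScan, path) -> MeshSummary:
    """Export a watertight binary STL of the scan surface.

    Byte output is deterministic for identical input (fixed zero header).
    Returns vertex count, triangle count and enclosed volume.
    """
    mesh = surface_mesh(scan)
    tris = mesh.triangles  # (n, 3, 3)
    normals = mesh.face_normals
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 80)
        fh.write(struct.pack("<I", len(tris)))
        rec = np.zeros((len(tris), 12), dtype="<f4")
        rec[:, 0:3] = normals
        rec[:, 3:12] = tris.reshape(len(tris), 9)
        buf = np.zeros(len(tris), dtype=np.dtype([("v", "<f4", 12), ("attr", "<u2")]))
        buf["v"] = rec
        fh.write(buf.tobytes())
    return MeshSummary(len(mesh.vertices), len(mesh.faces), float(mesh.volume))
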