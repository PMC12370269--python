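"""Statistical shape model of residual limbs: alignment, PCA, projection.

Correspondence between limbs is carried by the cylindrical grid itself:
after landmark-guided alignment (mirror left limbs, rotate the patellar
tendon to θ=0, zero the distal end) every scan is resampled to a shared
(n_slices × n_theta) lattice spanning its own length, so equal grid
indices mean equal proportional anatomical position.  Limb length is
appended as one extra scalar to the PCA data vector so the model spans
size as well as shape.

PCA is performed on raw radii in mm (covariance, not correlation), so
modes and mode scores stay in mm and are directly comparable with
rectification magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aop_io import CylindricalGrid, LimbScan

__all__ = ["ShapeModel", "align", "build_ssm", "project", "reconstruct"]


@dataclass
class ShapeModel:
    """Mean shape + orthonormal PCA modes of a limb training set.

    ``mean_shape`` and each column of ``modes`` have length
    n_slices·n_theta + 1: the flattened radius field (mm) plus the limb
    length (mm) as the final entry.  ``eigenvalues`` (mm²) are
    non-increasing; modes are orthonormal.
    """

    n_slices: int
    n_theta: int
    mean_shape: np.ndarray      # (p,) with p = n_slices*n_theta + 1
    modes: np.ndarray           # (p, n_modes), orthonormal columns
    eigenvalues: np.ndarray     # (n_modes,)
    total_variance: float       # sum of all training eigenvalues, mm²
    training_n: int

    def __post_init__(self) -> None:
        p = self.n_slices * self.n_theta + 1
        if self.mean_shape.shape != (p,) or self.modes.shape[0] != p:
            raise ValueError("mean/modes length must be n_slices*n_theta + 1")
        if self.modes.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per mode required")
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.n_modes), atol=1e-8):
            raise ValueError("modes must be orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10) or np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-increasing and >= 0")

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[1])

    def explained_variance_fraction(self) -> float:
        if self.total_variance == 0:
            return 1.0
        return float(self.eigenvalues.sum() / self.total_variance)

    def save(self, path) -> None:
        np.savez(
            path,
            n_slices=self.n_slices,
            n_theta=self.n_theta,
            mean_shape=self.mean_shape,
            modes=self.modes,
            eigenvalues=self.eigenvalues,
            total_variance=self.total_variance,
            training_n=self.training_n,
        )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(path) as d:
            return cls(
                n_slices=int(d["n_slices"]),
                n_theta=int(d["n_theta"]),
                mean_shape=d["mean_shape"],
                modes=d["modes"],
                eigenvalues=d["eigenvalues"],
                total_variance=float(d["total_variance"]),
                training_n=int(d["training_n"]),
            )


@dataclass
class ModeScores:
    """PCA coordinates (mm-scaled) of one aligned scan."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def _vectorize(scan: LimbScan) -> np.ndarray:
    return np.append(scan.radii.ravel(), scan.length)


def align(
    scan: LimbScan,
    n_slices: int | None = None,
    n_theta: int | None = None,
) -> LimbScan:
    """Bring a scan into the canonical right-limb frame on the reference grid.

    Left limbs are mirrored (θ → 360−θ); the scan is rotated so the
    PATELLAR_TENDON landmark sits at θ=0 and translated so the distal
    end is z=0; radii are then resampled (linear in z, bilinear with
    wrap-around in θ) onto a uniform grid of ``n_slices`` × ``n_theta``
    spanning the scan's own [0, length].  Landmarks are remapped to the
    nearest node of the new grid.  Requires PATELLAR_TENDON and
    DISTAL_END landmarks.
    """
    for req in ("PATELLAR_TENDON", "DISTAL_END"):
        if req not in scan.landmarks:
            raise ValueError(f"alignment requires the {req} landmark")
    g = scan.grid
    n_slices = n_slices or g.n_slices
    n_theta = n_theta or g.n_theta

    radii = scan.radii
    landmarks = dict(scan.landmarks)
    if scan.side == "left":
        # mirror: theta -> -theta; column k maps to (n-k) mod n
        k = np.arange(g.n_theta)
        radii = radii[:, (-k) % g.n_theta]
        landmarks = {name: (i, int((-j) % g.n_theta)) for name, (i, j) in landmarks.items()}

    # rotate the patellar tendon to theta index 0 (exact integer roll)
    j_pt = landmarks["PATELLAR_TENDON"][1]
    radii = np.roll(radii, -j_pt, axis=1)
    landmarks = {name: (i, int((j - j_pt) % g.n_theta)) for name, (i, j) in landmarks.items()}

    z = g.slice_z - g.slice_z[0]
    length = z[-1]

    # resample onto the reference lattice
    new_z = np.linspace(0.0, length, n_slices)
    new_theta = np.arange(n_theta) * (360.0 / n_theta)
    # linear in z
    rz = np.empty((n_slices, g.n_theta))
    for j in range(g.n_theta):
        rz[:, j] = np.interp(new_z, z, radii[:, j])
    # linear in theta with wrap
    old_theta = np.arange(g.n_theta) * g.theta_step
    ext_theta = np.append(old_theta, 360.0)
    new_radii = np.empty((n_slices, n_theta))
    for i in range(n_slices):
        row = np.append(rz[i], rz[i, 0])
        new_radii[i] = np.interp(new_theta, ext_theta, row)

    new_grid = CylindricalGrid(new_z, n_theta)
    new_landmarks = {}
    for name, (i, j) in landmarks.items():
        zi = int(np.argmin(np.abs(new_z - z[i])))
        tj = int(round(old_theta[j] / (360.0 / n_theta))) % n_theta
        new_landmarks[name] = (zi, tj)

    out = LimbScan(new_grid, new_radii, new_landmarks, side="right",
                   meta=dict(scan.meta))
    out.meta["aligned"] = "true"
    return out


def build_ssm(
    scans: list[LimbScan],
    variance_target: float | None = 0.95,
    n_modes: int | None = None,
) -> ShapeModel:
    """PCA shape model from aligned scans sharing one reference lattice.

    Retains either the requested number of modes or the smallest count
    whose cumulative eigenvalue fraction reaches ``variance_target``.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans")
    shape0 = scans[0].radii.shape
    for s in scans:
        if s.radii.shape != shape0:
            raise ValueError("mixed grids: all scans must share one lattice")
    X = np.stack([_vectorize(s) for s in scans])
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD: eigenvalues of the covariance are s^2 / (n-1)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = svals**2 / (n - 1)
    max_rank = min(n - 1, p)
    eig = eig[:max_rank]
    Vt = Vt[:max_rank]
    total = float(eig.sum())

    if n_modes is not None:
        k = int(n_modes)
        if not (1 <= k <= max_rank):
            raise ValueError(f"n_modes must be in [1, {max_rank}]")
    else:
        if not (0 < variance_target <= 1):
            raise ValueError("variance_target must be in (0, 1]")
        frac = np.cumsum(eig) / total if total > 0 else np.ones_like(eig)
        k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
        k = min(k, max_rank)

    return ShapeModel(
        n_slices=shape0[0],
        n_theta=shape0[1],
        mean_shape=mean,
        modes=Vt[:k].T,
        eigenvalues=eig[:k],
        total_variance=total,
        training_n=n,
    )


def project(model: ShapeModel, scan: LimbScan) -> ModeScores:
    """Mode scores of an aligned scan: modesᵀ·(x − mean)."""
    if scan.radii.shape != (model.n_slices, model.n_theta):
        raise ValueError(
            f"scan grid {scan.radii.shape} does not match model "
            f"({model.n_slices}, {model.n_theta})"
        )
    return ModeScores(model.modes.T @ (_vectorize(scan) - model.mean_shape))


def reconstruct(model: ShapeModel, scores: ModeScores | np.ndarray) -> LimbScan:
    """Shape at given mode coordinates: mean + modes·scores.

    Scores shorter than n_modes are zero-padded.  The returned scan has
    no landmarks; its grid spans [0, reconstructed length].
    """
    s = scores.scores if isinstance(scores, ModeScores) else np.asarray(scores, float)
    if s.size > model.n_modes:
        raise ValueError(f"got {s.size} scores for a {model.n_modes}-mode model")
    full = np.zeros(model.n_modes)
    full[: s.size] = s
    vec = model.mean_shape + model.modes @ full
    radii = vec[:-1].reshape(model.n_slices, model.n_theta)
    length = max(float(vec[-1]), 1.0)
    grid = CylindricalGrid(np.linspace(0.0, length, model.n_slices), model.n_theta)
    return LimbScan(grid, np.maximum(radii, 1e-6), {}, side="right",
                    meta={"reconstructed": "true"})
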