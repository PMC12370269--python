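"""Synthetic cohorts: residual limbs, covariates, expert sockets, trial scores.

No clinical scan archive is distributable, so every downstream module is
exercised on synthetic data with the demographic structure of a UK
transtibial prosthetics clinic population: predominantly men, median age
in the mid-60s, a spread of amputation causes dominated by infection/
diabetic foot and dysvascularity, and mostly household-to-community
activity levels.

Limb surfaces are smooth parametric shapes on the cylindrical grid: a
tapered, optionally elliptical profile with a rounded distal cap,
Gaussian bumps at the nine bony-prominence landmarks, and optional
low-order smooth surface noise.  "Expert" training sockets are produced
by a configurable linear ground-truth rule (:class:`ExpertRule`) mapping
covariates and shape parameters to rectification magnitudes plus
Gaussian noise — the known generative process that parameter-recovery
tests of the evidence model check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aop_io import LANDMARK_NAMES, CylindricalGrid, LimbScan
from .rectify import CARVE_FEATURES, FEATURES, RectificationSet
from .trialstats import TrialDataset

__all__ = [
    "PatientRecord",
    "LimbShapeParams",
    "ExpertRule",
    "CANONICAL_LANDMARKS",
    "REASONS",
    "ACTIVITY_LEVELS",
    "generate_limb",
    "generate_cohort",
    "expert_design",
    "simulate_trial",
    "cohort_to_csv",
]

REASONS = (
    "infection_diabetic",
    "dysvascularity",
    "trauma",
    "ischemia_clti",
    "sepsis",
    "neuropathy",
    "osteomyelitis",
)
ACTIVITY_LEVELS = ("A1", "A2", "A3", "A4")

#: Canonical landmark sites as (fractional height above the distal end,
#: angle in degrees) in the right-limb frame (θ=0 anterior, θ increasing
#: lateral).  The generator snaps each to the nearest grid node.
CANONICAL_LANDMARKS: dict[str, tuple[float, float]] = {
    "DISTAL_END": (0.00, 0.0),
    "DISTAL_TIBIA": (0.15, 0.0),
    "TIBIAL_CREST": (0.50, 0.0),
    "PATELLAR_TENDON": (0.85, 0.0),
    "FIBULAR_HEAD": (0.80, 100.0),
    "PARATIBIAL_LATERAL": (0.55, 30.0),
    "PARATIBIAL_MEDIAL": (0.55, 330.0),
    "SUPRACONDYLAR_LATERAL": (0.95, 80.0),
    "SUPRACONDYLAR_MEDIAL": (0.95, 280.0),
}


@dataclass
class PatientRecord:
    """Covariates collated alongside each limb scan."""

    age: float
    gender: str  # "woman" | "man"
    time_since_amputation: float  # years
    reason: str
    activity: str = "A2"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.time_since_amputation < 0:
            raise ValueError("time_since_amputation must be >= 0")
        if self.gender not in ("woman", "man"):
            raise ValueError("gender must be 'woman' or 'man'")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.activity not in ACTIVITY_LEVELS:
            raise ValueError(f"unknown activity level {self.activity!r}")


@dataclass
class LimbShapeParams:
    """Parametric description of one synthetic residual limb.

    ``taper`` is the distal/proximal radius ratio; ``bulbosity`` in
    (0, 1] controls distal-cap fullness (1 = no cap narrowing);
    ``cross_section_eccentricity`` flattens the cross-section
    anterio-posteriorly; ``bump_amplitudes`` (mm) set the prominence of
    each landmark bump; ``surface_noise`` (mm) scales a smooth random
    perturbation field.
    """

    length: float = 180.0
    proximal_radius: float = 55.0
    taper: float = 0.8
    bulbosity: float = 0.8
    bump_amplitudes: dict[str, float] = field(default_factory=dict)
    cross_section_eccentricity: float = 0.05
    surface_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.proximal_radius <= 0:
            raise ValueError("length and proximal_radius must be positive")
        if not (0 < self.taper <= 1.5):
            raise ValueError("taper must be in (0, 1.5]")
        if not (0 < self.bulbosity <= 1):
            raise ValueError("bulbosity must be in (0, 1]")
        for name in self.bump_amplitudes:
            if name not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark {name!r} in bump_amplitudes")


# ---------------------------------------------------------------------------
# limb geometry

_BUMP_SIGMA_DEG = 12.0   # angular SD of a landmark bump
_BUMP_SIGMA_MM = 12.0    # axial SD of a landmark bump
_CAP_FRACTION = 0.25     # distal cap occupies the bottom quarter of the limb


def _landmark_indices(params: LimbShapeParams, grid: CylindricalGrid) -> dict:
    z0 = grid.slice_z[0]
    length = grid.slice_z[-1] - z0
    out = {}
    for name, (frac, theta) in CANONICAL_LANDMARKS.items():
        si = int(np.argmin(np.abs(grid.slice_z - (z0 + frac * length))))
        ti = int(round(theta / grid.theta_step)) % grid.n_theta
        out[name] = (si, ti)
    return out


def generate_limb(
    params: LimbShapeParams, grid: CylindricalGrid | None = None, seed: int = 0
) -> LimbScan:
    """Synthesize a landmarked limb scan; deterministic given the seed.

    Radius field = tapered profile × distal-cap factor × elliptical
    cross-section factor + Gaussian landmark bumps + smooth noise.  Each
    landmark bump peaks exactly at its (snapped) grid node, so the
    radius there exceeds the bump-free surface by exactly its amplitude.
    """
    if grid is None:
        grid = CylindricalGrid.default(length=params.length)
    rng = np.random.default_rng(seed)
    z = grid.slice_z - grid.slice_z[0]
    length = z[-1]
    theta = np.deg2rad(grid.theta_deg)

    profile = params.proximal_radius * (
        params.taper + (1.0 - params.taper) * z / length
    )
    z_cap = _CAP_FRACTION * length
    cap = 1.0 - (1.0 - params.bulbosity) * np.clip(1.0 - z / z_cap, 0.0, None) ** 2
    ecc = 1.0 + params.cross_section_eccentricity * np.cos(2.0 * theta)
    radii = np.outer(profile * cap, ecc)

    landmarks = _landmark_indices(params, grid)
    for name, amp in params.bump_amplitudes.items():
        if amp == 0.0:
            continue
        si, ti = landmarks[name]
        dz = z - z[si]
        dth = (grid.theta_deg - grid.theta_deg[ti] + 180.0) % 360.0 - 180.0
        radii += amp * np.outer(
            np.exp(-0.5 * (dz / _BUMP_SIGMA_MM) ** 2),
            np.exp(-0.5 * (dth / _BUMP_SIGMA_DEG) ** 2),
        )

    if params.surface_noise > 0:
        # low-order Fourier field: smooth, zero at both ends axially
        field_sum = np.zeros_like(radii)
        n_axial, n_ang = 2, 3
        coefs = rng.normal(size=(n_axial, n_ang, 2))
        for p in range(1, n_axial + 1):
            axial = np.sin(np.pi * p * z / length)
            for q in range(1, n_ang + 1):
                a, b = coefs[p - 1, q - 1]
                field_sum += np.outer(axial, a * np.cos(q * theta) + b * np.sin(q * theta))
        rms = np.sqrt(np.mean(field_sum**2))
        if rms > 0:
            radii += params.surface_noise * field_sum / rms

    radii = np.maximum(radii, 1.0)
    return LimbScan(grid, radii, landmarks, side="right",
                    meta={"generator": "synthetic", "seed": str(seed)})


# ---------------------------------------------------------------------------
# cohorts

#: Default covariate distributions, mirroring the demographic profile of
#: a UK clinic population (mostly men, median age mid-60s).
DEFAULT_DEMOGRAPHICS = {
    "p_man": 16 / 17,
    "age_mean": 63.0,
    "age_sd": 14.0,
    "age_range": (30.0, 90.0),
    "tsa_log_mean": np.log(4.0),
    "tsa_log_sd": 0.8,
    "reason_probs": (6 / 19, 4 / 19, 3 / 19, 3 / 19, 1 / 19, 1 / 19, 1 / 19),
    "activity_probs": (1 / 15.5, 6 / 15.5, 8 / 15.5, 0.5 / 15.5),
}

#: Uniform sampling ranges for the limb shape parameters (mm / ratios).
DEFAULT_SHAPE_RANGES = {
    "length": (130.0, 220.0),
    "proximal_radius": (45.0, 62.0),
    "taper": (0.65, 0.95),
    "bulbosity": (0.65, 0.95),
    "cross_section_eccentricity": (0.0, 0.12),
    "bump_amplitude": (1.0, 5.0),
    "surface_noise": (0.2, 0.5),
}

#: Weak covariate→shape coupling: shape parameter shifted by
#: coeff × (standardized covariate) × (parameter range width), then
#: clipped to the range.  Keys: covariate name → {shape param: coeff}.
DEFAULT_COUPLING = {
    "age": {"taper": 0.08},
    "time_since_amputation": {"proximal_radius": -0.06},
}


def _draw_patient(rng: np.random.Generator, cfg: dict, i: int) -> PatientRecord:
    gender = "man" if rng.random() < cfg["p_man"] else "woman"
    lo, hi = cfg["age_range"]
    age = float(np.clip(rng.normal(cfg["age_mean"], cfg["age_sd"]), lo, hi))
    tsa = float(rng.lognormal(cfg["tsa_log_mean"], cfg["tsa_log_sd"]))
    reason = rng.choice(REASONS, p=cfg["reason_probs"])
    activity = rng.choice(ACTIVITY_LEVELS, p=cfg["activity_probs"])
    return PatientRecord(age, gender, tsa, str(reason), str(activity),
                         patient_id=f"SYN{i:04d}")


def _covariate_z(patient: PatientRecord) -> dict[str, float]:
    """Fixed-constant standardization of the continuous covariates."""
    return {
        "age": (patient.age - 60.0) / 15.0,
        "time_since_amputation": (patient.time_since_amputation - 5.0) / 5.0,
    }


def generate_cohort(
    n: int,
    demographics: dict | None = None,
    grid: CylindricalGrid | None = None,
    seed: int = 0,
    shape_ranges: dict | None = None,
    coupling: dict | None = None,
    generate_scans: bool = True,
) -> list[tuple[PatientRecord, LimbScan, LimbShapeParams]]:
    """Draw n (patient, limb scan, shape parameters) triples.

    Covariates follow the configured distributions; shape parameters are
    uniform over their ranges with a weak, configurable coupling to the
    covariates (pass ``coupling={}`` for full independence).  Fully
    deterministic per seed.  With ``generate_scans=False`` the scan slot
    is ``None`` — used by large statistical simulations that only need
    covariates and shape parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = {**DEFAULT_DEMOGRAPHICS, **(demographics or {})}
    ranges = {**DEFAULT_SHAPE_RANGES, **(shape_ranges or {})}
    coupling = DEFAULT_COUPLING if coupling is None else coupling
    if abs(sum(cfg["reason_probs"]) - 1) > 1e-9 or abs(sum(cfg["activity_probs"]) - 1) > 1e-9:
        raise ValueError("categorical probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        patient = _draw_patient(rng, cfg, i)
        zcov = _covariate_z(patient)
        vals = {}
        for name in ("length", "proximal_radius", "taper", "bulbosity",
                     "cross_section_eccentricity", "surface_noise"):
            lo, hi = ranges[name]
            v = rng.uniform(lo, hi)
            for cov, targets in coupling.items():
                if name in targets:
                    v += targets[name] * zcov.get(cov, 0.0) * (hi - lo)
            vals[name] = float(np.clip(v, lo, hi))
        blo, bhi = ranges["bump_amplitude"]
        bumps = {name: float(rng.uniform(blo, bhi)) for name in LANDMARK_NAMES}
        params = LimbShapeParams(bump_amplitudes=bumps, **vals)
        limb_seed = int(rng.integers(0, 2**31 - 1))
        scan = generate_limb(params, grid, seed=limb_seed) if generate_scans else None
        out.append((patient, scan, params))
    return out


def cohort_to_csv(cohort, path) -> None:
    """Emit covariates and shape parameters, one row per patient."""
    import pandas as pd

    rows = []
    for patient, _, params in cohort:
        row = {
            "patient_id": patient.patient_id,
            "age": patient.age,
            "gender": patient.gender,
            "time_since_amputation": patient.time_since_amputation,
            "reason": patient.reason,
            "activity": patient.activity,
            "length": params.length,
            "proximal_radius": params.proximal_radius,
            "taper": params.taper,
            "bulbosity": params.bulbosity,
            "eccentricity": params.cross_section_eccentricity,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# expert design rule (ground truth for parameter-recovery tests)

#: Order of the predictor vector used by :class:`ExpertRule`.
RULE_PREDICTORS = (
    "age_z", "gender_man", "tsa_z",
    "length_z", "proximal_radius_z", "taper_z", "bulbosity_z", "eccentricity_z",
)


def rule_predictor_vector(patient: PatientRecord, params: LimbShapeParams) -> np.ndarray:
    """Standardized predictors, in RULE_PREDICTORS order (no intercept)."""
    zcov = _covariate_z(patient)
    return np.array([
        zcov["age"],
        1.0 if patient.gender == "man" else 0.0,
        zcov["time_since_amputation"],
        (params.length - 175.0) / 26.0,
        (params.proximal_radius - 53.5) / 4.9,
        (params.taper - 0.80) / 0.087,
        (params.bulbosity - 0.80) / 0.087,
        (params.cross_section_eccentricity - 0.06) / 0.035,
    ])


@dataclass
class ExpertRule:
    """Linear ground-truth rule mapping predictors to design features.

    For each feature: magnitude = intercept + coeffs · predictors +
    N(0, noise_sd), then clipped to the feature's feasible sign range.
    ``coeffs[f]`` maps predictor names (RULE_PREDICTORS) to weights.
    """

    intercepts: dict[str, float]
    coeffs: dict[str, dict[str, float]]
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        for f in FEATURES:
            if f not in self.intercepts or f not in self.noise_sd:
                raise ValueError(f"rule must cover feature {f!r}")
            if self.noise_sd[f] < 0:
                raise ValueError("noise SD must be >= 0")
        for f, cmap in self.coeffs.items():
            for p in cmap:
                if p not in RULE_PREDICTORS:
                    raise ValueError(f"unknown predictor {p!r}")

    def coeff_matrix(self) -> np.ndarray:
        """(n_features × n_predictors) weight matrix in FEATURES order."""
        mat = np.zeros((len(FEATURES), len(RULE_PREDICTORS)))
        for i, f in enumerate(FEATURES):
            for j, p in enumerate(RULE_PREDICTORS):
                mat[i, j] = self.coeffs.get(f, {}).get(p, 0.0)
        return mat

    def linear_predictor(
        self, patient: PatientRecord, params: LimbShapeParams
    ) -> np.ndarray:
        x = rule_predictor_vector(patient, params)
        mu = np.array([self.intercepts[f] for f in FEATURES])
        return mu + self.coeff_matrix() @ x

    @classmethod
    def default(cls) -> "ExpertRule":
        """Plausible clinic practice: deeper carves for heavier, more
        conical limbs; larger distal builds soon after amputation."""
        intercepts = {
            "patella_tendon_bar": -4.0,
            "paratibial": -3.0,
            "fibula_head": 3.0,
            "distal_end": 5.0,
            "distal_tibia": 3.0,
            "anterior_tibia": 2.5,
            "supracondylar": -3.0,
            "volume_change": -0.05,
        }
        coeffs = {
            "patella_tendon_bar": {"taper_z": -0.4, "age_z": 0.3},
            "paratibial": {"proximal_radius_z": -0.3},
            "fibula_head": {"eccentricity_z": 0.3},
            "distal_end": {"tsa_z": -0.5, "bulbosity_z": 0.4},
            "distal_tibia": {"length_z": 0.3},
            "anterior_tibia": {"taper_z": 0.3},
            "supracondylar": {"gender_man": -0.4},
            "volume_change": {"tsa_z": -0.01},
        }
        noise_sd = {f: 0.5 for f in FEATURES}
        noise_sd["volume_change"] = 0.01
        return cls(intercepts, coeffs, noise_sd)

    @classmethod
    def constant(cls, values: dict[str, float], noise_sd: float = 0.0) -> "ExpertRule":
        """Rule with given intercepts, no covariate effects."""
        intercepts = {f: values.get(f, 0.0) for f in FEATURES}
        return cls(intercepts, {}, {f: noise_sd for f in FEATURES})


def expert_design(
    patient: PatientRecord,
    params: LimbShapeParams,
    rule: ExpertRule,
    seed: int = 0,
    clip: bool = True,
) -> RectificationSet:
    """Simulate a prosthetist's design vector for one limb.

    Linear predictor + per-feature Gaussian noise, clipped to feasible
    sign ranges (``clip=False`` returns the unclipped vector as a
    RectificationSet-ordered array inside a clip-free container — used
    for moment checks).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    mu = rule.linear_predictor(patient, params)
    sd = np.array([rule.noise_sd[f] for f in FEATURES])
    raw = mu + sd * rng.standard_normal(len(FEATURES))
    if not clip:
        return raw
    return RectificationSet.clip_to_feasible(raw)


# ---------------------------------------------------------------------------
# trial score simulation

def simulate_trial(
    n_pairs: int,
    median_control: float = 8.8,
    median_shift: float = -0.2,
    sd: float = 1.2,
    increment: float = 0.5,
    seed: int = 0,
    within_pair_corr: float = 0.7,
) -> TrialDataset:
    """Paired comfort scores for a crossover trial fixture.

    Control scores are N(median_control, sd²); EG scores share a
    within-subject component (correlation ``within_pair_corr``) and are
    shifted by ``median_shift``.  Scores are rounded to ``increment``
    (0 disables rounding) and clipped to [0, 10].
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not (0 <= within_pair_corr <= 1):
        raise ValueError("within_pair_corr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_pairs)
    rho = within_pair_corr
    e_c = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n_pairs)
    e_e = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n_pairs)
    control = median_control + sd * e_c
    eg = median_control + median_shift + sd * e_e
    if increment > 0:
        control = np.round(control / increment) * increment
        eg = np.round(eg / increment) * increment
    control = np.clip(control, 0.0, 10.0)
    eg = np.clip(eg, 0.0, 10.0)
    return TrialDataset(control_scs=control, eg_scs=eg)
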