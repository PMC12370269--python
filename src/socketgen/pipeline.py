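"""End-to-end socket generation: align → project → predict → apply → trim.

Also provides :func:`train_models`, which runs the full training
workflow on a cohort of limb–socket pairs: alignment, shape-model
construction, rectification extraction, and evidence-model fitting —
the same sequence a clinic archive would be processed with.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from .aop_io import CylindricalGrid, LimbScan, to_stl, write_aop
from .evidence import (
    DesignEvidenceModel,
    PriorSpec,
    build_design_matrix,
    fit_evidence_model,
    predict_rectifications,
)
from .rectify import (
    KernelSpec,
    RectificationSet,
    apply_rectifications,
    default_kernel_specs,
    extract_rectifications,
)
from .ssm import ModeScores, ShapeModel, align, build_ssm, project
from .synthetic_limb import ExpertRule, PatientRecord, expert_design

__all__ = [
    "SocketDesignResult",
    "StageError",
    "trim_brim",
    "generate_socket",
    "train_models",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SocketDesignResult:
    socket: LimbScan
    rects: RectificationSet
    intervals: dict[str, tuple[float, float]]
    mode_scores: np.ndarray
    brim_z: float
    provenance: dict


def trim_brim(socket: LimbScan, brim_z: float) -> LimbScan:
    """Cut the socket at the brim height.

    Slices above ``brim_z`` are removed; if ``brim_z`` falls between
    slices, a top slice is linearly interpolated exactly at that height.
    Landmarks above the brim are dropped.
    """
    z = socket.grid.slice_z
    if not (z[0] < brim_z <= z[-1]):
        raise ValueError(f"brim_z must lie in ({z[0]}, {z[-1]}]")
    if brim_z < z[1]:
        raise ValueError("brim_z below the second slice: socket would be degenerate")
    keep = z <= brim_z + 1e-9
    new_z = z[keep]
    new_radii = socket.radii[keep]
    if new_z[-1] < brim_z - 1e-9:
        k = int(np.searchsorted(z, brim_z)) - 1
        w = (brim_z - z[k]) / (z[k + 1] - z[k])
        top = (1 - w) * socket.radii[k] + w * socket.radii[k + 1]
        new_z = np.append(new_z, brim_z)
        new_radii = np.vstack([new_radii, top])
    n_keep = new_z.size
    landmarks = {
        name: (i, j) for name, (i, j) in socket.landmarks.items() if i < n_keep
    }
    return LimbScan(CylindricalGrid(new_z, socket.grid.n_theta), new_radii,
                    landmarks, side=socket.side, meta=dict(socket.meta))


def _config_hash(payload: dict) -> str:
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def generate_socket(
    evidence: DesignEvidenceModel,
    ssm_model: ShapeModel,
    patient: PatientRecord,
    scan: LimbScan,
    brim_z: float | None = None,
    specs: dict[str, KernelSpec] | None = None,
    stl_path=None,
    aop_path=None,
) -> SocketDesignResult:
    """Design a socket for a new patient from their limb scan.

    Runs align → project → predict → apply → trim; deterministic, and
    identical to calling the stages individually.  Errors carry the
    name of the failing stage.  ``brim_z`` defaults to 90% of limb
    length (a typical patellar-tendon-height brim).
    """
    specs = specs if specs is not None else default_kernel_specs()

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - relabelled with stage name
            raise StageError(stage, exc) from exc

    aligned = run("align", align, scan, ssm_model.n_slices, ssm_model.n_theta)
    scores = run("project", project, ssm_model, aligned)
    rects, intervals = run(
        "predict", predict_rectifications, evidence, patient, scores
    )
    socket = run("apply", apply_rectifications, aligned, rects, specs)
    if brim_z is None:
        brim_z = 0.9 * aligned.length
    socket = run("trim", trim_brim, socket, brim_z)

    provenance = {
        "patient_id": patient.patient_id,
        "ssm_modes": ssm_model.n_modes,
        "ssm_training_n": ssm_model.training_n,
        "evidence_training_n": evidence.training_n,
        "brim_z": brim_z,
        "kernel_specs": {
            k: (v.half_width_deg, v.half_height_mm, v.cap) for k, v in specs.items()
        },
    }
    provenance["config_hash"] = _config_hash(provenance)
    if stl_path is not None:
        run("export_stl", to_stl, socket, stl_path)
    if aop_path is not None:
        run("export_aop", write_aop, socket, aop_path)
    logger.info("designed socket for %s (config %s)",
                patient.patient_id, provenance["config_hash"])
    return SocketDesignResult(socket, rects, intervals,
                              scores.scores if isinstance(scores, ModeScores) else scores,
                              brim_z, provenance)


def train_models(
    cohort,
    rule: ExpertRule,
    specs: dict[str, KernelSpec] | None = None,
    variance_target: float = 0.95,
    n_modes: int | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
) -> tuple[ShapeModel, DesignEvidenceModel, list]:
    """Full training workflow on a synthetic cohort.

    For each (patient, limb, params) triple an expert socket is
    simulated with ``rule``, the limb is aligned, rectifications are
    extracted from the limb–socket pair, and the evidence model is fit
    on covariates + shape-mode scores.  Returns the shape model, the
    evidence model, and the per-subject training records
    (patient, aligned limb, true rects, extracted rects).
    """
    specs = specs if specs is not None else default_kernel_specs()
    rng = np.random.default_rng(seed)
    aligned_scans = [align(scan) for _, scan, _ in cohort]
    ssm_model = build_ssm(aligned_scans, variance_target=variance_target,
                          n_modes=n_modes)

    records = []
    patients, score_list, y_rows = [], [], []
    for (patient, _, params), aligned in zip(cohort, aligned_scans):
        true_rects = expert_design(patient, params, rule,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        socket = apply_rectifications(aligned, true_rects, specs)
        extracted, _ = extract_rectifications(aligned, socket, specs)
        scores = project(ssm_model, aligned)
        patients.append(patient)
        score_list.append(scores.scores)
        y_rows.append(extracted.as_array())
        records.append((patient, aligned, true_rects, extracted))

    X, spec_obj = build_design_matrix(patients, score_list, "fit")
    model = fit_evidence_model(X, np.stack(y_rows), prior=prior, spec=spec_obj)
    return ssm_model, model, records
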