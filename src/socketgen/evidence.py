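"""Bayesian regression linking patient covariates and limb shape to design.

Each of the 8 rectification features is modelled by an independent
Bayesian linear regression on an intercept, standardized continuous
covariates (age, time since amputation), one-hot categorical covariates
(gender, reason for amputation), and the leading statistical-shape-model
mode scores.  Inference is conjugate normal–inverse-gamma:

    y_f | β, σ² ~ N(X β, σ² I)
    β | σ²      ~ N(0, σ²/λ · I)      (ridge prior, precision λ per column)
    σ²          ~ Inv-Gamma(a0, b0)

giving a closed-form multivariate-t posterior for β and a Student-t
posterior predictive for a new design.  Point predictions are clipped to
each feature's feasible sign range; predictive intervals are reported
unclipped so they remain honest about the model's uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rectify import FEATURES, RectificationSet
from .synthetic_limb import REASONS, PatientRecord

__all__ = [
    "PriorSpec",
    "DesignMatrixSpec",
    "FeaturePosterior",
    "DesignEvidenceModel",
    "build_design_matrix",
    "fit_evidence_model",
    "predict_rectifications",
]

logger = logging.getLogger(__name__)

_REFERENCE_GENDER = "man"       # majority class in the training population
_REFERENCE_REASON = REASONS[0]  # infection_diabetic, the most common cause


@dataclass
class PriorSpec:
    """Zero-mean ridge prior with a weak inverse-gamma variance prior.

    ``precision`` is the prior precision λ on every non-intercept
    coefficient (unit scale on standardized columns by default);
    ``intercept_precision`` is deliberately small so the intercept is
    effectively unpenalized.
    """

    precision: float = 1.0
    intercept_precision: float = 1e-6
    a0: float = 1e-3
    b0: float = 1e-3

    def precision_diag(self, p: int) -> np.ndarray:
        lam = np.full(p, self.precision)
        lam[0] = self.intercept_precision
        return lam


@dataclass
class DesignMatrixSpec:
    """Column layout and standardization constants of the design matrix.

    Continuous covariates and mode scores are standardized with
    training-set means/SDs; categoricals are one-hot against a reference
    level.  Fitted once on training data and reused verbatim at predict
    time so train/predict encodings agree.
    """

    n_modes: int
    continuous: tuple[str, ...] = ("age", "time_since_amputation")
    col_names: list[str] = field(default_factory=list)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.means is not None:
            self.means = np.asarray(self.means, float)
            self.sds = np.asarray(self.sds, float)
            if not (np.all(np.isfinite(self.means)) and np.all(np.isfinite(self.sds))):
                raise ValueError("standardization constants must be finite")
            if np.any(self.sds <= 0):
                raise ValueError("standardization SDs must be positive")

    @property
    def fitted(self) -> bool:
        return self.means is not None


def _raw_row(patient: PatientRecord, scores: np.ndarray, spec: DesignMatrixSpec):
    """Unstandardized predictor row (continuous + one-hot + modes)."""
    row = [getattr(patient, c) for c in spec.continuous]
    onehot = [1.0 if patient.gender == "woman" else 0.0]
    reason = patient.reason
    if reason not in REASONS:
        logger.warning("unseen reason %r mapped to reference level", reason)
        reason = _REFERENCE_REASON
    onehot += [1.0 if reason == r else 0.0 for r in REASONS if r != _REFERENCE_REASON]
    s = np.zeros(spec.n_modes)
    s[: min(len(scores), spec.n_modes)] = scores[: spec.n_modes]
    return np.array(row), np.array(onehot), s


def build_design_matrix(
    patients: list[PatientRecord],
    scores: list[np.ndarray],
    spec: DesignMatrixSpec | str | int = "fit",
) -> tuple[np.ndarray, DesignMatrixSpec]:
    """Design matrix [1 | standardized continuous | one-hot | standardized modes].

    With ``spec="fit"`` (or an integer mode count) the standardization
    constants are computed from these rows; passing a fitted spec reuses
    its constants, guaranteeing identical encoding at predict time.
    """
    if len(patients) != len(scores):
        raise ValueError("patients and scores must have equal length")
    scores = [np.atleast_1d(np.asarray(getattr(s, "scores", s), float)) for s in scores]
    if isinstance(spec, str):
        if spec != "fit":
            raise ValueError("spec must be a DesignMatrixSpec, 'fit', or a mode count")
        spec_obj = DesignMatrixSpec(n_modes=len(scores[0]))
        fit = True
    elif isinstance(spec, int):
        spec_obj = DesignMatrixSpec(n_modes=spec)
        fit = True
    else:
        spec_obj = spec
        fit = not spec_obj.fitted

    cont_rows, onehot_rows, mode_rows = [], [], []
    for p, s in zip(patients, scores):
        c, o, m = _raw_row(p, s, spec_obj)
        cont_rows.append(c)
        onehot_rows.append(o)
        mode_rows.append(m)
    cont = np.array(cont_rows).reshape(len(patients), -1)
    onehot = np.array(onehot_rows)
    modes = np.array(mode_rows).reshape(len(patients), -1)
    std_cols = np.hstack([cont, modes])

    if fit:
        means = std_cols.mean(axis=0)
        sds = std_cols.std(axis=0, ddof=0)
        sds[sds == 0] = 1.0
        spec_obj.means = means
        spec_obj.sds = sds
        spec_obj.col_names = (
            ["intercept"]
            + list(spec_obj.continuous)
            + ["gender_woman"]
            + [f"reason_{r}" for r in REASONS if r != _REFERENCE_REASON]
            + [f"mode_{k}" for k in range(spec_obj.n_modes)]
        )
    n_cont = cont.shape[1]
    zc = (cont - spec_obj.means[:n_cont]) / spec_obj.sds[:n_cont]
    zm = (modes - spec_obj.means[n_cont:]) / spec_obj.sds[n_cont:]
    X = np.hstack([np.ones((len(patients), 1)), zc, onehot, zm])
    return X, spec_obj


@dataclass
class FeaturePosterior:
    """Conjugate NIG posterior for one feature's regression."""

    mean: np.ndarray        # posterior mean of beta
    precision: np.ndarray   # Lambda_n = Lambda_0 + X'X
    a_n: float
    b_n: float
    r2: float               # posterior-mean fit R^2 on training data

    @property
    def covariance(self) -> np.ndarray:
        """Marginal posterior covariance of beta (multivariate t scale)."""
        scale = self.b_n / self.a_n
        cov = scale * np.linalg.inv(self.precision)
        # symmetrize against round-off
        return 0.5 * (cov + cov.T)

    def coefficient_ci(self, level: float = 0.95) -> np.ndarray:
        """(p, 2) marginal credible intervals from the t posterior."""
        df = 2.0 * self.a_n
        t = stats.t.ppf(0.5 + level / 2.0, df)
        se = np.sqrt(np.diag(self.covariance))
        return np.column_stack([self.mean - t * se, self.mean + t * se])

    def predict(self, x: np.ndarray, level: float = 0.95):
        """Posterior predictive mean and central interval at row x."""
        x = np.asarray(x, float)
        mu = float(x @ self.mean)
        lam_inv_x = np.linalg.solve(self.precision, x)
        scale2 = (self.b_n / self.a_n) * (1.0 + float(x @ lam_inv_x))
        df = 2.0 * self.a_n
        t = stats.t.ppf(0.5 + level / 2.0, df)
        half = t * np.sqrt(scale2)
        return mu, (mu - half, mu + half)


@dataclass
class DesignEvidenceModel:
    """Per-feature regression posteriors plus the design-matrix encoding."""

    posteriors: dict[str, FeaturePosterior]
    prior: PriorSpec
    spec: DesignMatrixSpec | None
    training_n: int

    def save(self, path) -> None:
        arrays = {"training_n": np.array(self.training_n)}
        for f, post in self.posteriors.items():
            arrays[f"{f}__mean"] = post.mean
            arrays[f"{f}__precision"] = post.precision
            arrays[f"{f}__ab"] = np.array([post.a_n, post.b_n, post.r2])
        arrays["prior"] = np.array(
            [self.prior.precision, self.prior.intercept_precision,
             self.prior.a0, self.prior.b0]
        )
        if self.spec is not None:
            arrays["spec_means"] = self.spec.means
            arrays["spec_sds"] = self.spec.sds
            arrays["spec_n_modes"] = np.array(self.spec.n_modes)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DesignEvidenceModel":
        with np.load(path) as d:
            posteriors = {}
            for f in FEATURES:
                a_n, b_n, r2 = d[f"{f}__ab"]
                posteriors[f] = FeaturePosterior(
                    mean=d[f"{f}__mean"], precision=d[f"{f}__precision"],
                    a_n=float(a_n), b_n=float(b_n), r2=float(r2),
                )
            pr = d["prior"]
            prior = PriorSpec(*[float(v) for v in pr])
            spec = None
            if "spec_means" in d:
                spec = DesignMatrixSpec(n_modes=int(d["spec_n_modes"]))
                spec.means = d["spec_means"]
                spec.sds = d["spec_sds"]
            return cls(posteriors, prior, spec, int(d["training_n"]))


def fit_evidence_model(
    X: np.ndarray,
    Y,
    prior: PriorSpec | None = None,
    spec: DesignMatrixSpec | None = None,
) -> DesignEvidenceModel:
    """Fit independent conjugate regressions, one per design feature.

    ``Y`` is an (n × 8) array in FEATURES order or a list of
    RectificationSet.  X's first column must be the intercept.
    """
    prior = prior or PriorSpec()
    X = np.asarray(X, float)
    if isinstance(Y, (list, tuple)) and Y and isinstance(Y[0], RectificationSet):
        Y = np.stack([r.as_array() for r in Y])
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n or n < 2:
        raise ValueError("X and Y must have the same number of rows, n >= 2")
    if Y.shape[1] != len(FEATURES):
        raise ValueError(f"Y must have {len(FEATURES)} columns (FEATURES order)")

    lam0 = np.diag(prior.precision_diag(p))
    xtx = X.T @ X
    lam_n = lam0 + xtx
    posteriors = {}
    for j, f in enumerate(FEATURES):
        y = Y[:, j]
        mu_n = np.linalg.solve(lam_n, X.T @ y)
        a_n = prior.a0 + n / 2.0
        b_n = prior.b0 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
        b_n = max(b_n, 1e-300)
        resid = y - X @ mu_n
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        posteriors[f] = FeaturePosterior(mu_n, lam_n.copy(), a_n, b_n, r2)
    return DesignEvidenceModel(posteriors, prior, spec, n)


def predict_rectifications(
    model: DesignEvidenceModel,
    patient: PatientRecord,
    scores,
    level: float = 0.95,
) -> tuple[RectificationSet, dict[str, tuple[float, float]]]:
    """Posterior-predictive design for a new patient.

    Returns the sign-clipped point estimate and the per-feature
    unclipped central predictive intervals.
    """
    if model.spec is None:
        raise ValueError("model was fitted on a raw matrix; no design-matrix spec")
    X, _ = build_design_matrix([patient], [scores], model.spec)
    return predict_from_row(model, X[0], level=level)


def predict_from_row(
    model: DesignEvidenceModel, x: np.ndarray, level: float = 0.95
) -> tuple[RectificationSet, dict[str, tuple[float, float]]]:
    """Predict directly from a design-matrix row (intercept first)."""
    if not model.posteriors:
        raise ValueError("model is not fitted")
    means = np.empty(len(FEATURES))
    intervals: dict[str, tuple[float, float]] = {}
    for j, f in enumerate(FEATURES):
        mu, ci = model.posteriors[f].predict(x, level=level)
        means[j] = mu
        intervals[f] = ci
    return RectificationSet.clip_to_feasible(means), intervals
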