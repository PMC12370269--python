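"""Crossover noninferiority trial statistics for socket comfort scores.

Implements the paired analysis used to compare an automatically
generated socket against a clinician-designed control in a crossover
design: each participant wears both sockets and reports a 0–10 socket
comfort score (SCS) for each, giving paired within-subject differences.

Covers: Shapiro–Wilk normality check, the paired Wilcoxon signed-rank
test (exact enumeration-based null for small samples, tie-corrected
normal approximation otherwise), the standard effect size r = |Z|/√n,
percentile-bootstrap confidence intervals for medians, classification
of pairs against a noninferiority margin, and sample-size calculation
for a one-sided paired noninferiority t-test via the noncentral t
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialDataset",
    "TrialReport",
    "check_normality",
    "wilcoxon_paired",
    "effect_size_r",
    "bootstrap_median_ci",
    "classify_pairs",
    "noninferiority_n",
    "noninferiority_power",
    "summarize_trial",
    "plot_paired_chart",
]

logger = logging.getLogger(__name__)

#: Noninferiority margin: the SCS standard error of measurement, in points.
DEFAULT_MARGIN = 1.21


@dataclass
class TrialDataset:
    """Paired comfort scores, one row per socket fitting."""

    control_scs: np.ndarray
    eg_scs: np.ndarray
    participant_id: list[str] = field(default_factory=list)
    side: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.control_scs = np.asarray(self.control_scs, dtype=float)
        self.eg_scs = np.asarray(self.eg_scs, dtype=float)
        if self.control_scs.shape != self.eg_scs.shape or self.control_scs.ndim != 1:
            raise ValueError("control and EG score vectors must be equal-length 1-D")
        for x in (self.control_scs, self.eg_scs):
            if np.any(~np.isfinite(x)) or np.any((x < 0) | (x > 10)):
                raise ValueError("scores must be finite and within [0, 10]")
        n = self.control_scs.size
        if not self.participant_id:
            self.participant_id = [f"P{i + 1:02d}" for i in range(n)]
        if not self.side:
            self.side = ["right"] * n
        if len(self.participant_id) != n or len(self.side) != n:
            raise ValueError("id/side lists must match the number of pairs")

    @property
    def n(self) -> int:
        return int(self.control_scs.size)

    @property
    def differences(self) -> np.ndarray:
        """EG minus control, per fitting."""
        return self.eg_scs - self.control_scs

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "side": self.side,
                "control_scs": self.control_scs,
                "eg_scs": self.eg_scs,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        df = pd.read_csv(path)
        return cls(
            control_scs=df["control_scs"].to_numpy(),
            eg_scs=df["eg_scs"].to_numpy(),
            participant_id=[str(v) for v in df["participant_id"]],
            side=[str(v) for v in df.get("side", ["right"] * len(df))],
        )


@dataclass
class TrialReport:
    median_control: float
    median_eg: float
    ci_control: tuple[float, float]
    ci_eg: tuple[float, float]
    wilcoxon_w: float
    wilcoxon_z: float
    p_value: float
    effect_size: float
    n_higher: int
    n_same: int
    n_lower: int
    n: int

    def __post_init__(self) -> None:
        if self.n_higher + self.n_same + self.n_lower != self.n:
            raise ValueError("classification counts must sum to n")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median_eg": self.median_eg,
            "median_control": self.median_control,
            "ci_eg": list(self.ci_eg),
            "ci_control": list(self.ci_control),
            "wilcoxon_w": self.wilcoxon_w,
            "wilcoxon_z": self.wilcoxon_z,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "pairs_higher": self.n_higher,
            "pairs_same": self.n_same,
            "pairs_lower": self.n_lower,
        }

    def __str__(self) -> str:
        return (
            f"Paired crossover comparison, n={self.n} fittings\n"
            f"  median SCS  EG {self.median_eg:.1f} "
            f"(95% CI {self.ci_eg[0]:.1f}-{self.ci_eg[1]:.1f}), "
            f"control {self.median_control:.1f} "
            f"(95% CI {self.ci_control[0]:.1f}-{self.ci_control[1]:.1f})\n"
            f"  Wilcoxon signed-rank W={self.wilcoxon_w:.1f}, "
            f"P={self.p_value:.2f}, effect size r={self.effect_size:.2f}\n"
            f"  pairs: {self.n_higher} higher / {self.n_same} same / "
            f"{self.n_lower} lower (margin {DEFAULT_MARGIN})"
        )


def check_normality(x) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Requires 3 ≤ n ≤ 5000.

    A constant sample has no defined W; a ``ValueError`` is raised
    explicitly rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ under the null of random signs.

    Dynamic-programming convolution over the (possibly tie-averaged)
    rank multiset.  Ranks are doubled so average ranks become integers;
    exact rational arithmetic avoids any floating-point loss.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=object)
    dist[0] = 1
    for r in r2:
        new = dist.copy()
        new[r:] = new[r:] + dist[: total + 1 - r]
        dist = new
    denom = 2 ** len(r2)
    w2 = int(round(2 * w_plus))
    p_le = Fraction(int(sum(dist[: w2 + 1])), denom)
    p_ge = Fraction(int(sum(dist[w2:])), denom)
    return float(min(1, 2 * min(p_le, p_ge)))


def wilcoxon_paired(
    a, b, zero_method: str = "wilcox", mode: str = "auto"
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test of a vs b; returns (W, Z, p).

    W is min(W+, W−) of the signed ranks of the nonzero differences
    a − b; p is two-sided.  With ``mode='auto'`` the null is exact
    (sign-assignment enumeration via convolution) when at most 12
    nonzero differences remain, and a tie-corrected normal
    approximation otherwise; 'exact'/'approx' force either branch.
    Zero differences are dropped before ranking (``zero_method
    ='wilcox'``, the only supported variant) and their count logged.
    Z is always the (continuity-uncorrected) normal deviate, which
    feeds the effect size r.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need equal-length 1-D samples with n >= 1")
    if zero_method != "wilcox":
        raise ValueError("only zero_method='wilcox' (drop zeros) is supported")
    d = a - b
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("wilcoxon_paired: dropped %d zero difference(s)", n_zero)
    d = d[d != 0]
    m = d.size
    if m == 0:
        logger.info("wilcoxon_paired: all differences zero; p = 1")
        return 0.0, 0.0, 1.0

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    # tie-corrected normal deviate (used for p in the approx branch and
    # always reported for the effect size)
    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 == 0 else (w_plus - mu) / np.sqrt(sigma2)

    use_exact = mode == "exact" or (mode == "auto" and m <= 12)
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    if use_exact:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(2 * stats.norm.sf(abs(z))) if sigma2 > 0 else 1.0
    return w, float(z), min(p, 1.0)


def effect_size_r(z: float, n_pairs: int) -> float:
    """Wilcoxon effect size r = |Z| / sqrt(n_pairs)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return abs(float(z)) / np.sqrt(n_pairs)


def bootstrap_median_ci(
    x, n_boot: int = 10_000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI for the sample median; deterministic per seed."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def classify_pairs(
    data: TrialDataset, threshold: float = DEFAULT_MARGIN
) -> tuple[int, int, int]:
    """Count pairs with EG comfort higher / the same / lower than control.

    A pair is "the same" when |EG − control| ≤ threshold (inclusive
    boundary), "higher" when the difference exceeds +threshold, "lower"
    below −threshold.
    """
    d = data.differences
    higher = int(np.sum(d > threshold))
    lower = int(np.sum(d < -threshold))
    same = int(data.n - higher - lower)
    return higher, same, lower


def noninferiority_power(
    n: int, alpha: float, margin: float, sd: float, true_diff: float
) -> float:
    """Power of a one-sided paired noninferiority t-test with n pairs.

    ``sd`` is the per-condition SCS standard deviation; under
    within-pair independence the difference SD is sd*sqrt(2).  The test
    rejects H0: mean difference ≤ −margin when
    t = (d̄ + margin) / (s_d/√n) exceeds the one-sided critical value;
    power follows from the noncentral t distribution with
    noncentrality (true_diff + margin) / (sd√2/√n).
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd_diff = sd * np.sqrt(2.0)
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha, df)
    ncp = (true_diff + margin) / (sd_diff / np.sqrt(n))
    return float(1.0 - stats.nct.cdf(t_crit, df, ncp))


def noninferiority_n(
    power: float, alpha: float, margin: float, sd: float, true_diff: float = 0.0,
    max_n: int = 100_000,
) -> int:
    """Smallest number of pairs giving the target power (see above).

    Iterates n upward from 2 evaluating the noncentral-t power.  Raises
    if the margin is unreachable (true difference at or beyond −margin)
    or the target power is not attained by ``max_n``.
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    if margin <= 0 or sd <= 0:
        raise ValueError("margin and sd must be positive")
    if true_diff + margin <= 0:
        raise ValueError("unreachable: true difference at or beyond the margin")
    for n in range(2, max_n + 1):
        if noninferiority_power(n, alpha, margin, sd, true_diff) >= power:
            return n
    raise ValueError(f"target power not reached by n = {max_n}")


def summarize_trial(
    data: TrialDataset,
    seed: int | None = None,
    threshold: float = DEFAULT_MARGIN,
    n_boot: int = 10_000,
    chart_path=None,
) -> TrialReport:
    """Full paired analysis: medians with bootstrap CIs, Wilcoxon test,
    effect size, and pair classification; optionally renders the paired
    comparison chart."""
    if data.n < 3:
        raise ValueError("need at least 3 pairs")
    ss = np.random.SeedSequence(seed).spawn(2)
    ci_control = bootstrap_median_ci(
        data.control_scs, n_boot=n_boot, seed=ss[0].generate_state(1)[0]
    )
    ci_eg = bootstrap_median_ci(
        data.eg_scs, n_boot=n_boot, seed=ss[1].generate_state(1)[0]
    )
    w, z, p = wilcoxon_paired(data.eg_scs, data.control_scs)
    higher, same, lower = classify_pairs(data, threshold)
    report = TrialReport(
        median_control=float(np.median(data.control_scs)),
        median_eg=float(np.median(data.eg_scs)),
        ci_control=ci_control,
        ci_eg=ci_eg,
        wilcoxon_w=w,
        wilcoxon_z=z,
        p_value=p,
        effect_size=effect_size_r(z, data.n),
        n_higher=higher,
        n_same=same,
        n_lower=lower,
        n=data.n,
    )
    if chart_path is not None:
        plot_paired_chart(data, chart_path, threshold=threshold)
    return report


def plot_paired_chart(data: TrialDataset, path, threshold: float = DEFAULT_MARGIN):
    """Paired-comparison chart: one line per fitting, control → EG,
    coloured by whether the EG score is higher (green), the same (blue)
    or lower (purple) within the noninferiority threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c, e in zip(data.control_scs, data.eg_scs):
        d = e - c
        color = "tab:green" if d > threshold else ("tab:purple" if d < -threshold else "tab:blue")
        ax.plot([0, 1], [c, e], marker="o", color=color, alpha=0.7)
    ax.set_xticks([0, 1], ["Control", "EG"])
    ax.set_ylabel("Socket comfort score (0-10)")
    ax.set_ylim(-0.3, 10.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
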