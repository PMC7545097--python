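"""One-site saturation binding fits and plate-immunoassay statistics.

The binding model is the single-site isotherm

    y(x) = baseline + Bmax * x / (Kd + x)

with dose x in nM. Kd is estimated by nonlinear least squares with a
log-spaced multistart over Kd; for each candidate Kd the linear parameters
(Bmax, and optionally baseline) have an exact linear-least-squares solution,
which makes the start-point search cheap and the final polish robust.

Plate immunoassay (TR-FIA-style) results are normalized per experiment to
the wild-type construct (taken as 1.0), summarized with the population
standard deviation, and compared to wild-type with a pooled-variance
(homoscedastic) one-tailed two-sample t-test, with the conventional star
annotation at p < 0.05 / 0.025 / 0.01 / 0.005 / 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingCurve",
    "OneSiteFit",
    "TRFIAResult",
    "one_site",
    "subtract_control",
    "fit_one_site",
    "normalize_trfia",
    "ttest_homoscedastic_onetail",
    "assign_stars",
    "STAR_THRESHOLDS",
]

STAR_THRESHOLDS = ((0.001, "*****"), (0.005, "****"), (0.01, "***"),
                   (0.025, "**"), (0.05, "*"))


def one_site(x, kd, bmax, baseline=0.0):
    """Single-site binding isotherm."""
    x = np.asarray(x, dtype=float)
    return baseline + bmax * x / (kd + x)


@dataclass
class BindingCurve:
    """Dose–response data: doses in nM and one signal row per replicate.

    ``signals`` (and ``control_signals`` when present) have shape
    (n_replicates, n_doses).
    """

    doses: np.ndarray
    signals: np.ndarray
    control_signals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.doses.ndim != 1:
            raise ValueError("doses must be 1-D")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(self.doses) < 0):
            raise ValueError("doses must be ascending")
        if self.signals.shape[1] != self.doses.size:
            raise ValueError("signals and doses lengths differ")
        if self.control_signals is not None:
            self.control_signals = np.atleast_2d(
                np.asarray(self.control_signals, dtype=float))
            if self.control_signals.shape != self.signals.shape:
                raise ValueError("control series does not match doses/replicates")

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[0]


@dataclass
class OneSiteFit:
    """Fitted one-site parameters. ``extrapolated`` flags a Kd outside
    dose span x [1e-2, 1e2]; ``converged`` is False when every multistart
    failed and the grid optimum was returned as-is."""

    kd: float
    bmax: float
    baseline: float
    rss: float
    se_kd: float
    extrapolated: bool = False
    converged: bool = True


def subtract_control(curve: BindingCurve, clip_negative: bool = False) -> BindingCurve:
    """Subtract the matched control (e.g. GST background) series per dose
    and replicate. Negative differences are kept (with a warning) unless
    ``clip_negative``."""
    if curve.control_signals is None:
        raise ValueError("curve has no control series to subtract")
    corrected = curve.signals - curve.control_signals
    if np.any(corrected < 0):
        if clip_negative:
            corrected = np.clip(corrected, 0.0, None)
        else:
            warnings.warn("control exceeds signal at some doses; keeping "
                          "negative values", stacklevel=2)
    return BindingCurve(doses=curve.doses.copy(), signals=corrected)


def _solve_linear(x, y, kd, fit_baseline):
    """Exact least-squares (bmax[, baseline]) for fixed kd."""
    f = x / (kd + x)
    if fit_baseline:
        A = np.column_stack([f, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        bmax, baseline = coef
    else:
        denom = float(f @ f)
        bmax = float(f @ y) / denom if denom > 0 else 0.0
        baseline = 0.0
    resid = y - (baseline + bmax * f)
    return bmax, baseline, float(resid @ resid)


def fit_one_site(
    curve: BindingCurve,
    fit_baseline: bool = False,
    n_starts: int = 25,
) -> OneSiteFit:
    """Fit the one-site isotherm to all replicate points by least squares.

    Multistart: Kd candidates are log-spaced over the positive dose span
    widened by 100x on both sides; each candidate is scored with its exact
    linear solution for (Bmax, baseline), and the best is polished with a
    trust-region least-squares solver. ``se_kd`` is the asymptotic standard
    error from the Jacobian at the optimum.
    """
    x = np.tile(curve.doses, curve.n_replicates)
    y = curve.signals.ravel()
    if np.unique(curve.doses).size < 4:
        raise ValueError("need at least 4 distinct doses to fit")
    positive = curve.doses[curve.doses > 0]
    lo, hi = positive.min() / 100.0, positive.max() * 100.0
    grid = np.geomspace(lo, hi, n_starts)
    scored = [(_solve_linear(x, y, kd, fit_baseline), kd) for kd in grid]
    (gb, gb0, grss), gkd = min(scored, key=lambda s: s[0][2])

    def residuals(theta):
        kd, bmax = theta[0], theta[1]
        baseline = theta[2] if fit_baseline else 0.0
        return one_site(x, kd, bmax, baseline) - y

    theta0 = [gkd, gb] + ([gb0] if fit_baseline else [])
    lower = [1e-12, 0.0] + ([0.0] if fit_baseline else [])
    try:
        sol = optimize.least_squares(residuals, theta0, bounds=(lower, np.inf))
        converged = sol.success and sol.cost * 2 <= grss + 1e-12
    except Exception:
        sol, converged = None, False
    if sol is not None and converged:
        kd, bmax = float(sol.x[0]), float(sol.x[1])
        baseline = float(sol.x[2]) if fit_baseline else 0.0
        rss = float(2 * sol.cost)
        jac = sol.jac
    else:
        kd, bmax, baseline, rss = gkd, gb, gb0, grss
        eps = max(kd * 1e-6, 1e-12)
        jac = np.column_stack([
            (residuals([kd + eps, bmax] + ([baseline] if fit_baseline else []))
             - residuals([kd, bmax] + ([baseline] if fit_baseline else []))) / eps,
            x / (kd + x),
        ])
    se_kd = _se_from_jacobian(jac, rss, y.size)
    extrapolated = not (positive.min() * 1e-2 <= kd <= positive.max() * 1e2)
    return OneSiteFit(kd=kd, bmax=bmax, baseline=baseline, rss=rss,
                      se_kd=se_kd, extrapolated=extrapolated, converged=converged)


def _se_from_jacobian(jac, rss, n) -> float:
    p = jac.shape[1]
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        return float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        return float("nan")


# ---------------------------------------------------------------------------
# Plate immunoassay normalization and statistics

@dataclass
class TRFIAResult:
    """Per-construct normalized binding (wild-type = 1) with significance."""

    table: pd.DataFrame  # index construct; mean, sd, n, p_value, stars
    normalized: pd.DataFrame  # construct x experiment normalized values


def normalize_trfia(
    plate: pd.DataFrame,
    wild_type: str = "WT",
    construct_col: str = "construct",
    experiment_col: str = "experiment",
    signal_col: str = "signal",
    alternative: str = "less",
) -> TRFIAResult:
    """Normalize plate signals to wild-type per experiment and test mutants.

    Within each experiment every construct's (mean) signal is divided by
    that experiment's wild-type signal, so wild-type is 1.0 by construction.
    Across experiments the mean and population standard deviation (ddof=0)
    are reported, together with a pooled-variance one-tailed t-test of each
    mutant's normalized values against wild-type's (default direction:
    mutant < wild-type, the loss-of-binding hypothesis) and its stars.
    """
    means = (plate.groupby([construct_col, experiment_col])[signal_col]
             .mean().unstack(experiment_col))
    if wild_type not in means.index:
        raise ValueError(f"wild-type construct {wild_type!r} absent from plate")
    wt = means.loc[wild_type]
    if wt.isna().any():
        raise ValueError("wild-type missing from some experiment")
    if (wt == 0).any():
        raise ValueError("wild-type signal is zero in some experiment")
    normalized = means.divide(wt, axis=1)
    rows = []
    wt_values = normalized.loc[wild_type].dropna().to_numpy()
    for construct, series in normalized.iterrows():
        values = series.dropna().to_numpy()
        if construct == wild_type:
            p = None
        else:
            p = ttest_homoscedastic_onetail(values, wt_values,
                                            alternative=alternative)
        rows.append({
            "construct": construct,
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=0)),
            "n": int(values.size),
            "p_value": p,
            "stars": assign_stars(p) if p is not None else "",
        })
    table = pd.DataFrame(rows).set_index("construct")
    return TRFIAResult(table=table, normalized=normalized)


def ttest_homoscedastic_onetail(x, y, alternative: str = "less") -> float:
    """Pooled-variance two-sample t-test, one-tailed p.

    ``alternative="less"`` tests mean(x) < mean(y). With zero pooled
    variance and equal means the test is degenerate and p = 0.5 by
    convention; with zero variance and unequal means p is 0 or 1 according
    to the direction of the difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    nx, ny = x.size, y.size
    dof = nx + ny - 2
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / dof
    diff = x.mean() - y.mean()
    if pooled == 0:
        if diff == 0:
            return 0.5
        less = diff < 0
        return 0.0 if less == (alternative == "less") else 1.0
    t = diff / np.sqrt(pooled * (1 / nx + 1 / ny))
    p = stats.t.cdf(t, dof)
    return float(p if alternative == "less" else 1.0 - p)


def assign_stars(p: float) -> str:
    """Map a p-value to the star convention (strict inequalities)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"
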