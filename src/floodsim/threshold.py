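"""Critical-migration-threshold estimation from collapse-probability curves.

For each (mating penalty, paternity factor) condition the sweep yields a
dose-response curve: collapse probability as a function of the migration
fraction m. The critical migration fraction ``m_c`` is the point where that
curve crosses 0.5, estimated by fitting a two-parameter logistic

    P(m) = 1 / (1 + exp(-slope * (m - m_c)))

by binomial maximum likelihood on the per-cell (n_collapsed, n_reps) tallies.
Cells above ``m_max_fit`` (default 0.30) are excluded from fitting because
the response can turn non-monotonic at very high migration — migrant-derived
genotypes then carry so much fitness penalty that they fail to establish and
resident alleles persist again. That regime is characterized separately by
:func:`detect_high_m_persistence`.

When the likelihood has no interior maximum (perfectly separated curves,
common when the transition is sharp relative to the grid), the estimator
falls back to linear interpolation of the first 0.5-crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .sweep import CellResult

__all__ = [
    "CollapseCurve",
    "ThresholdEstimate",
    "ThresholdSummary",
    "RegimeReport",
    "NoThresholdError",
    "curves_from_cells",
    "fit_collapse_curve",
    "aggregate_thresholds",
    "detect_high_m_persistence",
    "REGIME_PERSISTENCE",
    "REGIME_COLLAPSE",
    "REGIME_MIGRANT_FAILURE",
]

REGIME_PERSISTENCE = "resident persistence"
REGIME_COLLAPSE = "resident collapse"
REGIME_MIGRANT_FAILURE = "migrant failure to establish"

#: Fitted logistic slopes at or above this cap are treated as evidence of
#: complete separation (no interior ML optimum); the interpolation fallback
#: is used instead.
_SLOPE_CAP = 2000.0


class NoThresholdError(ValueError):
    """The collapse curve never crosses 0.5 within the fitted range."""


@dataclass(frozen=True)
class CollapseCurve:
    """Collapse probability vs migration fraction for one condition."""

    condition: tuple[float, int]  # (mating penalty, paternity factor)
    m: tuple[float, ...]
    probability: tuple[float, ...]
    n_reps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.m) == len(self.probability) == len(self.n_reps)):
            raise ValueError("m, probability and n_reps must have equal length")
        ms = self.m
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("curve points must be sorted by m with unique m values")

    @property
    def n_collapsed(self) -> tuple[int, ...]:
        return tuple(
            int(round(p * n)) for p, n in zip(self.probability, self.n_reps)
        )


@dataclass(frozen=True)
class ThresholdEstimate:
    """Fitted critical migration fraction for one condition.

    ``method`` records whether the binomial-likelihood logistic fit was used
    or the interpolation fallback; ``ci_low``/``ci_high`` bound a bootstrap
    percentile interval (NaN when bootstrapping was disabled).
    """

    condition: tuple[float, int]
    m_c: float
    slope: float
    method: str  # "logistic" | "interpolation"
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ThresholdSummary:
    """Per-condition estimates with their sample mean and SD."""

    estimates: tuple[ThresholdEstimate, ...]
    mean_m_c: float
    sd_m_c: float


@dataclass(frozen=True)
class RegimeReport:
    """Non-monotonicity diagnosis for one collapse curve.

    ``flagged`` lists (m, probability drop, 2 x pooled binomial SE) for
    every m above the threshold whose collapse probability falls below the
    curve's maximum by more than twice the pooled SE; ``regimes`` labels
    every grid point with one of the three dynamical regimes.
    """

    condition: tuple[float, int]
    nonmonotonic: bool
    m_c: float | None
    max_probability: float
    flagged: tuple[tuple[float, float, float], ...]
    regimes: dict[float, str]


def curves_from_cells(cells: list[CellResult]) -> dict[tuple[float, int], CollapseCurve]:
    """Group sweep cells into per-condition collapse curves, sorted by m."""
    grouped: dict[tuple[float, int], list[CellResult]] = {}
    for cell in cells:
        grouped.setdefault((cell.penalty, cell.paternity), []).append(cell)
    curves = {}
    for condition, members in sorted(grouped.items()):
        members.sort(key=lambda c: c.m)
        curves[condition] = CollapseCurve(
            condition=condition,
            m=tuple(c.m for c in members),
            probability=tuple(c.collapse_probability for c in members),
            n_reps=tuple(c.n_reps for c in members),
        )
    return curves


def _interpolate_crossing(m: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """First 0.5-crossing by linear interpolation; returns (m_c, slope proxy).

    The slope proxy is the logistic slope whose derivative at P = 0.5
    matches the local secant (4 x dP/dm), so interpolation estimates remain
    comparable to likelihood fits.
    """
    above = p >= 0.5
    if not above.any() or p.min() >= 0.5:
        raise NoThresholdError(
            "no threshold in range: collapse probabilities do not cross 0.5 "
            f"within the fitted m range [{m[0]}, {m[-1]}]"
        )
    i = int(np.argmax(above))
    if i == 0 or p[i] == 0.5:
        return float(m[i]), np.inf if i == 0 else 4.0 * _secant(m, p, max(i, 1))
    m_c = m[i - 1] + (0.5 - p[i - 1]) / (p[i] - p[i - 1]) * (m[i] - m[i - 1])
    return float(m_c), 4.0 * _secant(m, p, i)


def _secant(m: np.ndarray, p: np.ndarray, i: int) -> float:
    return float((p[i] - p[i - 1]) / (m[i] - m[i - 1]))


def _logistic_nll(theta: np.ndarray, m: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    m_c, log_slope = theta
    z = np.exp(log_slope) * (m - m_c)
    prob = expit(z)
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-(k * np.log(prob) + (n - k) * np.log(1 - prob)).sum())


def _fit_mle(
    m: np.ndarray, k: np.ndarray, n: np.ndarray, m_c0: float
) -> tuple[float, float, bool]:
    """Binomial ML logistic fit; returns (m_c, slope, converged)."""
    span = max(m[-1] - m[0], 1e-6)
    best = None
    for s0 in (10.0, 40.0, 150.0):
        res = minimize(
            _logistic_nll,
            x0=np.array([m_c0, np.log(s0)]),
            args=(m, k, n),
            method="L-BFGS-B",
            bounds=[(m[0], m[-1]), (np.log(1e-2), np.log(_SLOPE_CAP))],
        )
        if best is None or res.fun < best.fun:
            best = res
    m_c, log_slope = best.x
    slope = float(np.exp(log_slope))
    converged = bool(best.success) and slope < 0.99 * _SLOPE_CAP
    # guard against the optimizer parking on a boundary of the m range
    if not (m[0] < m_c < m[-1]):
        converged = False
    _ = span
    return float(m_c), slope, converged


def fit_collapse_curve(
    curve: CollapseCurve,
    m_max_fit: float = 0.30,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ThresholdEstimate:
    """Estimate the critical migration fraction m_c for one condition.

    Fits the two-parameter logistic by binomial maximum likelihood on cells
    with ``m <= m_max_fit``. If the likelihood fit does not converge to an
    interior optimum (e.g. perfectly separated 0/1 curves), falls back to
    linear interpolation of the first 0.5-crossing. The confidence interval
    is a seeded percentile bootstrap over per-replicate collapse indicators
    within each cell.

    Raises
    ------
    NoThresholdError
        If the curve never crosses 0.5 within the fitted range.
    ValueError
        If fewer than 4 points fall at or below ``m_max_fit``.
    """
    mask = np.asarray(curve.m) <= m_max_fit + 1e-12
    m = np.asarray(curve.m, dtype=float)[mask]
    p = np.asarray(curve.probability, dtype=float)[mask]
    n = np.asarray(curve.n_reps, dtype=int)[mask]
    if m.size < 4:
        raise ValueError(
            f"need >= 4 curve points with m <= {m_max_fit}, got {m.size}"
        )
    k = np.rint(p * n).astype(int)
    m_c0, _ = _interpolate_crossing(m, p)  # raises NoThresholdError if flat

    m_c, slope, method = _fit_point(m, k, n, m_c0)

    ci_low = ci_high = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_bootstrap):
            k_b = rng.binomial(n, np.clip(k / n, 0, 1))
            p_b = k_b / n
            try:
                m_c0_b, _ = _interpolate_crossing(m, p_b)
            except NoThresholdError:
                continue
            m_c_b, _, _ = _fit_point(m, k_b, n, m_c0_b)
            draws.append(m_c_b)
        if draws:
            ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    return ThresholdEstimate(
        condition=curve.condition,
        m_c=float(m_c),
        slope=float(slope),
        method=method,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def _fit_point(
    m: np.ndarray, k: np.ndarray, n: np.ndarray, m_c0: float
) -> tuple[float, float, str]:
    m_c, slope, converged = _fit_mle(m, k, n, m_c0)
    if converged:
        return m_c, slope, "logistic"
    m_c_i, slope_i = _interpolate_crossing(m, k / n)
    return m_c_i, slope_i, "interpolation"


def aggregate_thresholds(estimates: list[ThresholdEstimate]) -> ThresholdSummary:
    """Sample mean and SD of per-condition m_c estimates (SD = 0 for one)."""
    if not estimates:
        raise ValueError("cannot aggregate an empty list of threshold estimates")
    values = np.array([e.m_c for e in estimates])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ThresholdSummary(
        estimates=tuple(estimates),
        mean_m_c=float(values.mean()),
        sd_m_c=sd,
    )


def detect_high_m_persistence(
    curve: CollapseCurve,
    estimate: ThresholdEstimate | None = None,
    m_max_fit: float = 0.30,
) -> RegimeReport:
    """Diagnose the non-monotonic high-migration persistence regime.

    Flags every m above the estimated threshold whose collapse probability
    sits below the curve's maximum by more than twice the pooled binomial
    standard error — the signature of migrants failing to establish when
    fitness penalties concentrate in migrant-derived genotypes at high
    release fractions. Points are labeled with the three regimes: resident
    persistence (below threshold), resident collapse, and migrant failure
    to establish (flagged high-m points).
    """
    m = np.asarray(curve.m, dtype=float)
    p = np.asarray(curve.probability, dtype=float)
    n = np.asarray(curve.n_reps, dtype=int)
    if estimate is None:
        try:
            estimate = fit_collapse_curve(
                curve, m_max_fit=m_max_fit, n_bootstrap=0
            )
        except (NoThresholdError, ValueError):
            estimate = None
    m_c = estimate.m_c if estimate is not None else None

    i_max = int(np.argmax(p))
    p_max = p[i_max]
    flagged: list[tuple[float, float, float]] = []
    if m_c is not None:
        # compare each point against the maximum attained at *smaller* m, so
        # points on the rising limb of a monotone curve are never flagged
        for j in range(1, m.size):
            if m[j] <= m_c:
                continue
            i_ref = int(np.argmax(p[:j]))
            p_ref, n_ref = p[i_ref], n[i_ref]
            pooled_se = np.sqrt(
                p_ref * (1 - p_ref) / n_ref + p[j] * (1 - p[j]) / n[j]
            )
            drop = p_ref - p[j]
            if drop > 2 * pooled_se:
                flagged.append((float(m[j]), float(drop), float(2 * pooled_se)))
    flagged_ms = {f[0] for f in flagged}
    regimes: dict[float, str] = {}
    for j in range(m.size):
        if m[j] in flagged_ms:
            regimes[float(m[j])] = REGIME_MIGRANT_FAILURE
        elif m_c is not None and m[j] >= m_c:
            regimes[float(m[j])] = REGIME_COLLAPSE
        else:
            regimes[float(m[j])] = REGIME_PERSISTENCE
    return RegimeReport(
        condition=curve.condition,
        nonmonotonic=bool(flagged),
        m_c=m_c,
        max_probability=float(p_max),
        flagged=tuple(flagged),
        regimes=regimes,
    )
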