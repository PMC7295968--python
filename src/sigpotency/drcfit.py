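"""Constrained dose-response fitting and potency reporting.

Three candidate fits are computed for every percent-activity series:

parametric
    Four-parameter logistic ``A(c) = A0 + (Ainf − A0)/(1 + (AC50/c)^hill)``
    under box constraints: A0, Ainf ∈ [−50, 500] % of the AC effect, hill
    ∈ [0.1, 10], and AC50 within one log unit of the tested concentration
    range.  Fitted by bounded nonlinear least squares with five starts.
nonparametric
    Local quadratic (tricube-weighted) smoother over log10 concentration,
    evaluated on a dense grid; its potency is the lowest concentration at
    which the smooth crosses 50% activity.  It also detects bell-shaped
    curves (interior maximum with the top-concentration value falling
    below half of the maximum).
constant
    Mean activity level.  Potency is censored one log unit outside the
    tested range: above 50% mean activity → lowest tested /10 (already
    fully active), otherwise → highest tested ×10 (inactive).

Selection order: an unusable nonparametric fit (r² < 0.5) forces a
constant fit; a bell shape reports the nonparametric crossing; a weak
parametric fit (r² < 0.5 or in-range amplitude |amin − amax| < 30) falls
back to constant; otherwise the parametric AC50 is reported.  Parametric
fits whose Ainf stays below 50% are additionally censored one log unit
above the highest tested concentration, on the grounds that such a weak
plateau is unlikely to share the active control's mode of action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import ConcentrationGrid

__all__ = [
    "FitConstraints",
    "DoseResponseFit",
    "four_pl",
    "fit_parametric",
    "fit_nonparametric",
    "fit_constant",
    "select_fit",
    "apply_low_ainf_rule",
    "fit_dose_response",
    "DoseResponseCurve",
]

#: r² below which a fit family is considered unusable
R2_MIN = 0.5
#: minimum in-range amplitude |amin − amax| for a reportable parametric fit
MIN_AMPLITUDE = 30.0
#: grid resolution of the nonparametric smoother
SMOOTH_GRID_N = 200
#: tricube span of the local quadratic smoother
SMOOTH_SPAN = 0.75


@dataclass(frozen=True)
class FitConstraints:
    """Box constraints of the parametric fit, in % of the AC effect / µM."""

    a0_min: float = -50.0
    ainf_max: float = 500.0
    hill_min: float = 0.1
    hill_max: float = 10.0

    def __post_init__(self) -> None:
        if not self.a0_min < self.ainf_max:
            raise ValueError("a0_min must be < ainf_max")
        if not 0 < self.hill_min < self.hill_max:
            raise ValueError("need 0 < hill_min < hill_max")

    def potency_bounds_uM(self, grid: ConcentrationGrid) -> tuple[float, float]:
        """One log unit outside the tested range."""
        return grid.min_uM / 10.0, grid.max_uM * 10.0


@dataclass
class DoseResponseFit:
    """One candidate or selected dose-response fit."""

    fit_type: str  # parametric | nonparametric | constant
    reported_potency_uM: float | None
    r2: float
    a0: float | None = None
    ainf: float | None = None
    hill: float | None = None
    ac50_uM: float | None = None
    amin: float | None = None  # fitted extremes within the tested range
    amax: float | None = None
    bell_shaped: bool = False
    censoring: str = "none"  # none | above_range | below_range | low_ainf
    valid: bool = True
    curve: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def four_pl(
    conc: np.ndarray, a0: float, ainf: float, ac50: float, hill: float
) -> np.ndarray:
    """Four-parameter logistic in concentration; direction is carried by the
    sign of (Ainf − A0), the hill slope is always positive."""
    conc = np.asarray(conc, dtype=float)
    return a0 + (ainf - a0) / (1.0 + (ac50 / conc) ** hill)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    y = np.asarray(y, float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _check_series(concs, activities):
    concs = np.asarray(concs, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if concs.shape != activities.shape or concs.ndim != 1:
        raise ValueError("concs and activities must be 1-D and equal length")
    if np.any(concs <= 0) or not np.all(np.isfinite(concs)):
        raise ValueError("concentrations must be finite and > 0")
    if not np.all(np.isfinite(activities)):
        raise ValueError("activities must be finite")
    order = np.argsort(concs)
    return concs[order], activities[order]


# ---------------------------------------------------------------------------
# parametric
# ---------------------------------------------------------------------------
def fit_parametric(
    concs,
    activities,
    constraints: FitConstraints = FitConstraints(),
    grid: ConcentrationGrid | None = None,
) -> DoseResponseFit:
    """Constrained 4PL least-squares fit with multi-start.

    AC50 starts are seeded at quantiles of the tested log-concentration
    range, hill at 1; the best of five converged starts is kept.  An
    optimizer failure returns an invalid candidate so selection can fall
    through to the constant fit.
    """
    concs, y = _check_series(concs, activities)
    if len(np.unique(concs)) < 4:
        raise ValueError("parametric fit needs >= 4 distinct concentrations")
    if grid is None:
        grid = ConcentrationGrid(tuple(np.unique(concs)))
    pmin, pmax = constraints.potency_bounds_uM(grid)
    logc = np.log10(concs)

    lo = np.array(
        [constraints.a0_min, constraints.a0_min, np.log10(pmin), constraints.hill_min]
    )
    hi = np.array(
        [constraints.ainf_max, constraints.ainf_max, np.log10(pmax), constraints.hill_max]
    )

    def resid(theta):
        a0, ainf, logac50, hill = theta
        pred = a0 + (ainf - a0) / (1.0 + 10.0 ** (hill * (logac50 - logc)))
        return pred - y

    clip = lambda v, a, b: float(np.clip(v, a, b))
    a0_start = clip(y[np.argsort(logc)[:2]].mean(), lo[0], hi[0])
    ainf_start = clip(y[np.argsort(logc)[-2:]].mean(), lo[1], hi[1])
    best = None
    for q in (0.1, 0.3, 0.5, 0.7, 0.9):
        x0 = np.array(
            [a0_start, ainf_start, np.quantile(logc, q), 1.0]
        )
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseFit(
            fit_type="parametric", reported_potency_uM=None, r2=-np.inf, valid=False
        )

    a0, ainf, logac50, hill = best.x
    ac50 = float(10.0 ** logac50)
    pred = four_pl(concs, a0, ainf, ac50, hill)
    ends = four_pl(np.array([grid.min_uM, grid.max_uM]), a0, ainf, ac50, hill)
    return DoseResponseFit(
        fit_type="parametric",
        reported_potency_uM=ac50,
        r2=_r2(y, pred),
        a0=float(a0),
        ainf=float(ainf),
        hill=float(hill),
        ac50_uM=ac50,
        amin=float(ends.min()),  # 4PL is monotone: extremes at range ends
        amax=float(ends.max()),
    )


# ---------------------------------------------------------------------------
# nonparametric
# ---------------------------------------------------------------------------
def _loess_quadratic(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                     span: float = SMOOTH_SPAN) -> np.ndarray:
    """Local quadratic regression with tricube weights over nearest
    ``span`` fraction of points."""
    n = len(x)
    k = max(3, int(np.ceil(span * n)))
    out = np.empty_like(x_eval)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argsort(d)[:k]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
        w = np.maximum(w, 1e-6)
        X = np.vander(x[idx] - x0, N=3, increasing=True)  # [1, dx, dx^2]
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = coef[0]
    return out


def fit_nonparametric(concs, activities) -> DoseResponseFit:
    """Smooth the series over log10 concentration and report the lowest
    concentration at which the smooth crosses 50% activity.

    The bell-shape flag is set when the smoothed maximum lies at an
    interior grid concentration and the smoothed value at the highest
    tested concentration has fallen below half of that maximum.
    """
    concs, y = _check_series(concs, activities)
    if len(np.unique(concs)) < 4:
        raise ValueError("nonparametric fit needs >= 4 distinct concentrations")
    logc = np.log10(concs)
    grid = np.linspace(logc.min(), logc.max(), SMOOTH_GRID_N)
    smooth = _loess_quadratic(logc, y, grid)
    pred = _loess_quadratic(logc, y, logc)
    r2 = _r2(y, pred)

    imax = int(np.argmax(smooth))
    smax = float(smooth[imax])
    bell = (
        0 < imax < len(grid) - 1
        and smax > 0
        and float(smooth[-1]) < 0.5 * smax
    )

    potency = None
    crossing = (smooth[:-1] - 50.0) * (smooth[1:] - 50.0) <= 0
    hit = np.flatnonzero(crossing & (smooth[:-1] != smooth[1:]))
    if smooth[0] == 50.0:
        potency = float(10.0 ** grid[0])
    elif hit.size:
        j = hit[0]
        frac = (50.0 - smooth[j]) / (smooth[j + 1] - smooth[j])
        potency = float(10.0 ** (grid[j] + frac * (grid[j + 1] - grid[j])))

    return DoseResponseFit(
        fit_type="nonparametric",
        reported_potency_uM=potency,
        r2=r2,
        amin=float(smooth.min()),
        amax=smax,
        bell_shaped=bell,
        curve=(10.0 ** grid, smooth),
    )


# ---------------------------------------------------------------------------
# constant
# ---------------------------------------------------------------------------
def fit_constant(
    concs, activities, grid: ConcentrationGrid | None = None
) -> DoseResponseFit:
    """Constant-level fit with the censored-potency assignment.

    Mean activity above 50% → the compound is already fully active below
    the tested range: potency = lowest tested /10 (``below_range``).
    Mean activity at or below 50% → inactive in range: potency = highest
    tested ×10 (``above_range``).
    """
    concs, y = _check_series(concs, activities)
    if grid is None:
        grid = ConcentrationGrid(tuple(np.unique(concs)))
    level = float(np.mean(y))
    if level > 50.0:
        potency, censoring = grid.min_uM / 10.0, "below_range"
    else:
        potency, censoring = grid.max_uM * 10.0, "above_range"
    pred = np.full_like(y, level)
    return DoseResponseFit(
        fit_type="constant",
        reported_potency_uM=potency,
        r2=_r2(y, pred),
        a0=level,
        ainf=level,
        amin=level,
        amax=level,
        censoring=censoring,
    )


# ---------------------------------------------------------------------------
# selection & censoring
# ---------------------------------------------------------------------------
def select_fit(
    parametric: DoseResponseFit,
    nonparametric: DoseResponseFit,
    constant: DoseResponseFit,
) -> DoseResponseFit:
    """Apply the reporting decision logic, in order:

    1. nonparametric r² < 0.5 → data unsuitable for curve fitting: constant;
    2. bell-shaped curve → nonparametric crossing potency;
    3. parametric r² < 0.5 or |amin − amax| < 30 → constant;
    4. otherwise → parametric.
    """
    if nonparametric.r2 < R2_MIN:
        return constant
    if nonparametric.bell_shaped:
        if nonparametric.reported_potency_uM is None:
            # bell never reaches 50%: no crossing to report; treat as
            # unfittable and fall back to the constant assignment
            out = constant
            out.bell_shaped = True
            return out
        return nonparametric
    if (
        not parametric.valid
        or parametric.r2 < R2_MIN
        or abs(parametric.amin - parametric.amax) < MIN_AMPLITUDE
    ):
        return constant
    return parametric


def apply_low_ainf_rule(
    fit: DoseResponseFit, grid: ConcentrationGrid
) -> DoseResponseFit:
    """Censor parametric fits whose plateau stays below 50% activity.

    Such an effect is assumed not to share the active control's mode of
    action; the potency is set one log unit above the highest tested
    concentration (strict inequality: Ainf = 50 exactly is kept).
    """
    if fit.fit_type == "parametric" and fit.ainf is not None and fit.ainf < 50.0:
        fit.reported_potency_uM = grid.max_uM * 10.0
        fit.censoring = "low_ainf"
    return fit


def fit_dose_response(
    concs,
    activities,
    constraints: FitConstraints = FitConstraints(),
    grid: ConcentrationGrid | None = None,
) -> DoseResponseFit:
    """Full pipeline: three candidate fits, selection, low-Ainf censoring."""
    concs, y = _check_series(concs, activities)
    if grid is None:
        grid = ConcentrationGrid(tuple(np.unique(concs)))
    try:
        par = fit_parametric(concs, y, constraints, grid)
    except ValueError:
        par = DoseResponseFit(
            fit_type="parametric", reported_potency_uM=None, r2=-np.inf, valid=False
        )
    nonpar = fit_nonparametric(concs, y)
    const = fit_constant(concs, y, grid)
    chosen = select_fit(par, nonpar, const)
    return apply_low_ainf_rule(chosen, grid)


class DoseResponseCurve(BaseEstimator, RegressorMixin):
    """Scikit-learn style dose-response estimator.

    ``fit(C, y)`` takes concentrations (µM; 1-D or a single column) and
    percent activities, runs the parametric / nonparametric / constant
    family and the selection and censoring rules, and exposes the result
    as fitted attributes.

    Attributes
    ----------
    fit_type_ : str
        ``"parametric"``, ``"nonparametric"`` or ``"constant"``.
    a0_, ainf_, hill_, ac50_uM_ : float or None
        4PL parameters (parametric fits).
    r2_ : float
    reported_potency_uM_ : float
    censoring_ : str
        ``"none"``, ``"above_range"``, ``"below_range"`` or ``"low_ainf"``.
    bell_shaped_ : bool
    result_ : DoseResponseFit
        The full selected candidate.
    """

    def __init__(
        self,
        a0_min: float = -50.0,
        ainf_max: float = 500.0,
        hill_min: float = 0.1,
        hill_max: float = 10.0,
        grid: ConcentrationGrid | None = None,
    ):
        self.a0_min = a0_min
        self.ainf_max = ainf_max
        self.hill_min = hill_min
        self.hill_max = hill_max
        self.grid = grid

    def _constraints(self) -> FitConstraints:
        return FitConstraints(
            a0_min=self.a0_min,
            ainf_max=self.ainf_max,
            hill_min=self.hill_min,
            hill_max=self.hill_max,
        )

    def fit(self, C, y):
        concs = np.asarray(C, dtype=float).reshape(-1)
        result = fit_dose_response(concs, y, self._constraints(), self.grid)
        self.result_ = result
        self.fit_type_ = result.fit_type
        self.a0_ = result.a0
        self.ainf_ = result.ainf
        self.hill_ = result.hill
        self.ac50_uM_ = result.ac50_uM
        self.r2_ = result.r2
        self.reported_potency_uM_ = result.reported_potency_uM
        self.censoring_ = result.censoring
        self.bell_shaped_ = result.bell_shaped
        self._train_ = (concs, np.asarray(y, dtype=float).reshape(-1))
        return self

    def predict(self, C) -> np.ndarray:
        """Selected curve evaluated at concentrations ``C`` (µM)."""
        concs = np.asarray(C, dtype=float).reshape(-1)
        r = self.result_
        if r.fit_type == "parametric":
            return four_pl(concs, r.a0, r.ainf, r.ac50_uM, r.hill)
        if r.fit_type == "constant":
            return np.full(concs.shape, r.a0)
        x, y = self._train_
        return _loess_quadratic(np.log10(x), y, np.log10(concs))
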