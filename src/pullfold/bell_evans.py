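"""Bell-Evans force-dependent kinetics and straight-line log-rate fits.

In the Bell-Evans (BE) picture a two-state molecule crosses a single barrier
whose height falls linearly with force, so the rates vary exponentially:

    k_unfold(f) = exp(log_k0_unfold + beta * f * x_dagger)
    k_fold(f)   = exp(log_k0_fold   - beta * f * x_star)

``x_dagger`` and ``x_star`` are the distances from the barrier top to the
native (N) and unfolded (U) wells along the molecular extension coordinate.
The attempt rate and the barrier heights appear only through the two
zero-force log-prefactors, the identifiable combinations
log_k0_unfold = ln(ka) - beta*dG_dagger and
log_k0_fold = ln(ka) - beta*(dG_star - dG_0); the package stores and fits
only these, since straight-line fits to log-rates cannot separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import RateCurve
from .thermal import ThermalContext

__all__ = [
    "BellEvansParams",
    "BEFitResult",
    "unfold_rate",
    "fold_rate",
    "coexistence_force",
    "fit_be",
    "combine_fits",
    "predicted_fold_rate_moving_ts",
]


@dataclass(frozen=True)
class BellEvansParams:
    """Bell-Evans parameters: barrier distances (nm) and log-prefactors
    (ln of a rate in 1/s at zero force)."""

    x_dagger: float
    x_star: float
    log_k0_unfold: float
    log_k0_fold: float

    def __post_init__(self) -> None:
        if not self.x_dagger > 0 or not self.x_star > 0:
            raise ValueError("barrier distances x_dagger and x_star must be > 0")
        if not (np.isfinite(self.log_k0_unfold) and np.isfinite(self.log_k0_fold)):
            raise ValueError("log-prefactors must be finite")

    @property
    def x_m(self) -> float:
        """Apparent molecular extension x_dagger + x_star, nm."""
        return self.x_dagger + self.x_star


def unfold_rate(f, p: BellEvansParams, ctx: ThermalContext):
    """Unfolding rate k->(f) in 1/s; strictly increasing in force."""
    f = np.asarray(f, dtype=float)
    out = np.exp(p.log_k0_unfold + ctx.beta * f * p.x_dagger)
    return out if f.ndim else float(out)


def fold_rate(f, p: BellEvansParams, ctx: ThermalContext):
    """Folding rate k<-(f) in 1/s; strictly decreasing in force."""
    f = np.asarray(f, dtype=float)
    out = np.exp(p.log_k0_fold - ctx.beta * f * p.x_star)
    return out if f.ndim else float(out)


def coexistence_force(p: BellEvansParams, ctx: ThermalContext) -> float:
    """Force fc where k->(fc) = k<-(fc), in pN (closed form)."""
    denom = ctx.beta * (p.x_dagger + p.x_star)
    if denom == 0:
        raise ZeroDivisionError("degenerate model: x_dagger + x_star = 0")
    return (p.log_k0_fold - p.log_k0_unfold) / denom


@dataclass
class BEFitResult:
    """Result of fitting both BE branches to measured log-rates."""

    params: BellEvansParams
    se: dict[str, float]
    coexistence_force: float
    x_m_exp: float
    diagnostics: dict = field(default_factory=dict)


def _fit_branch(curve: RateCurve, weighted: bool):
    f = np.asarray(curve.force, dtype=float)
    k = np.asarray(curve.rate, dtype=float)
    if f.size < 2:
        raise ValueError(f"need >= 2 rate points on the {curve.direction} branch, got {f.size}")
    if np.any(k <= 0):
        raise ValueError("rates must be positive to fit in log space")
    y = np.log(k)
    se_log = None if curve.se_log_rate is None else np.asarray(curve.se_log_rate, dtype=float)
    if se_log is not None:
        finite = np.isfinite(se_log) & (se_log > 0)
        if np.any(finite):
            # bins without a bootstrap error get the weight of the worst bin
            se_log = np.where(finite, se_log, se_log[finite].max())
        else:
            se_log = None
    if weighted and se_log is not None:
        w = 1.0 / se_log
        coef, cov = np.polyfit(f, y, 1, w=w, cov="unscaled")
    else:
        if f.size > 2:
            coef, cov = np.polyfit(f, y, 1, cov=True)
        else:
            coef = np.polyfit(f, y, 1)
            cov = np.full((2, 2), np.nan)
    slope, intercept = coef
    resid = y - np.polyval(coef, f)
    return slope, intercept, np.sqrt(np.diag(cov)), float(np.sum(resid**2)), f.size


def fit_be(unfold: RateCurve, fold: RateCurve, ctx: ThermalContext) -> BEFitResult:
    """Weighted least-squares fit of ln k vs f on each branch.

    The unfolding slope is beta*x_dagger and the folding slope -beta*x_star;
    intercepts are the log-prefactors. Weights are the inverse squared
    standard errors of ln k when available, otherwise the fit is unweighted.
    The coexistence force comes from the closed form on the fitted params.
    """
    su, iu, (se_su, se_iu), rss_u, n_u = _fit_branch(unfold, weighted=True)
    sf, if_, (se_sf, se_if), rss_f, n_f = _fit_branch(fold, weighted=True)
    if su <= 0:
        raise ValueError("unfolding branch has non-positive log-slope; not BE-like")
    if sf >= 0:
        raise ValueError("folding branch has non-negative log-slope; not BE-like")
    params = BellEvansParams(
        x_dagger=su / ctx.beta,
        x_star=-sf / ctx.beta,
        log_k0_unfold=iu,
        log_k0_fold=if_,
    )
    se = {
        "x_dagger": se_su / ctx.beta,
        "x_star": se_sf / ctx.beta,
        "log_k0_unfold": se_iu,
        "log_k0_fold": se_if,
    }
    fc = coexistence_force(params, ctx)
    return BEFitResult(
        params=params,
        se=se,
        coexistence_force=fc,
        x_m_exp=params.x_m,
        diagnostics={
            "n_unfold": n_u,
            "n_fold": n_f,
            "rss_unfold": rss_u,
            "rss_fold": rss_f,
        },
    )


def combine_fits(fits: list[BEFitResult], ctx: ThermalContext) -> BEFitResult:
    """Average per-molecule fits; errors are the standard statistical error
    (standard error of the mean) across molecules."""
    if not fits:
        raise ValueError("no fits to combine")
    if len(fits) == 1:
        return fits[0]
    fields = ("x_dagger", "x_star", "log_k0_unfold", "log_k0_fold")
    vals = {name: np.array([getattr(f.params, name) for f in fits]) for name in fields}
    mean = {name: float(v.mean()) for name, v in vals.items()}
    sem = {name: float(v.std(ddof=1) / np.sqrt(len(fits))) for name, v in vals.items()}
    params = BellEvansParams(**mean)
    return BEFitResult(
        params=params,
        se=sem,
        coexistence_force=coexistence_force(params, ctx),
        x_m_exp=params.x_m,
        diagnostics={"n_molecules": len(fits)},
    )


def predicted_fold_rate_moving_ts(
    f_grid,
    ts,
    anchor_force: float,
    anchor_rate: float,
    ctx: ThermalContext,
    integral: bool = True,
) -> RateCurve:
    """Folding-rate prediction when the barrier-to-U distance moves with force.

    With a force-dependent x*(f) the fold branch is no longer a straight line
    in ln k vs f. The default (thermodynamically consistent) form integrates
    the local slope, d ln k<- / df = -beta * x*(f):

        ln k<-(f) = ln k(anchor) - beta * int_{f_a}^{f} x*(f') df'

    evaluated by the trapezoid rule on the profile grid; it reduces to the
    constant-x* BE expression when x* does not vary. With ``integral=False``
    the direct substitution ln k<-(f) = ln k(anchor) - beta*(f*x*(f) -
    f_a*x*(f_a)) is used instead.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    # ts is any transition-state profile with .force and .x_star grids
    ts_force = np.asarray(ts.force, dtype=float)
    ts_x_star = np.asarray(ts.x_star, dtype=float)
    if not (ts_force[0] <= anchor_force <= ts_force[-1]):
        raise ValueError("anchor_force lies outside the transition-state profile grid")
    if np.any(f_grid < ts_force[0]) or np.any(f_grid > ts_force[-1]):
        raise ValueError("f_grid extends beyond the transition-state profile grid")
    if not anchor_rate > 0:
        raise ValueError("anchor_rate must be > 0")

    if integral:
        cum = np.concatenate(
            ([0.0], np.cumsum(0.5 * (ts_x_star[1:] + ts_x_star[:-1]) * np.diff(ts_force)))
        )
        integral_at = np.interp(f_grid, ts_force, cum) - np.interp(anchor_force, ts_force, cum)
        log_k = np.log(anchor_rate) - ctx.beta * integral_at
    else:
        xs_f = np.interp(f_grid, ts_force, ts_x_star)
        xs_a = np.interp(anchor_force, ts_force, ts_x_star)
        log_k = np.log(anchor_rate) - ctx.beta * (f_grid * xs_f - anchor_force * xs_a)
    return RateCurve(force=f_grid, rate=np.exp(log_k), direction="fold")
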