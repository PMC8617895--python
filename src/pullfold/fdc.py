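"""Event detection on force-distance curves (FDCs).

A pulling cycle records force versus trap position lambda. While the
molecule is folded the force follows a linear baseline f = k_eff * lambda
set by the effective stiffness of trap plus tether; an unfolding event is a
sudden force drop off that baseline, a folding event a sudden force rise
back onto it (only ~0.5 pN at the low forces where proteins refold).

The detection chain is: running median filter -> folded-baseline fit ->
two-component Gaussian (Bayesian) classification of the baseline residuals
into native (N) and unfolded (U) -> first-transition force, with folding
forces below a cutoff reported as censored because not all of them are
detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "PullingTrace",
    "FoldedBaseline",
    "StateLabels",
    "RuptureEvent",
    "DegenerateModelError",
    "median_filter",
    "fit_folded_baseline",
    "classify_states",
    "first_transition_force",
]

N_STATE = 0
U_STATE = 1


class DegenerateModelError(RuntimeError):
    """The classification model is degenerate (zero noise, distinct residuals)."""


@dataclass
class PullingTrace:
    """One pulling half-cycle: equal-length time / trap-position / force
    channels sampled uniformly, with the sweep direction and loading rate."""

    time: np.ndarray  # s
    lam: np.ndarray  # trap-pipette distance, nm
    force: np.ndarray  # pN
    direction: str  # "unfold" (force ramps up) | "fold" (ramps down)
    loading_rate: float  # pN/s
    sampling_rate: float  # Hz
    molecule_id: str = "mol0"
    cycle_id: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.size == self.lam.size == self.force.size):
            raise ValueError("time, lambda and force channels must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.direction not in ("unfold", "fold"):
            raise ValueError(f"direction must be 'unfold' or 'fold', got {self.direction!r}")
        if self.force.size >= 2:
            trend = self.force[-1] - self.force[0]
            if trend != 0 and (self.direction == "unfold") != (trend > 0):
                raise ValueError("direction inconsistent with the force trend")


@dataclass(frozen=True)
class FoldedBaseline:
    """Linear folded-branch model f(lambda) = k_eff * lambda + intercept."""

    k_eff: float  # pN/nm
    intercept: float  # pN
    sigma: float  # robust residual scale, pN
    n_points: int

    def predict(self, lam):
        return self.k_eff * np.asarray(lam, dtype=float) + self.intercept


@dataclass
class StateLabels:
    """Per-sample N/U labels with posterior probability of N and the indices
    where the debounced label changes."""

    states: np.ndarray  # 0 = N, 1 = U
    posterior_n: np.ndarray
    transitions: list[tuple[int, int, int]] = field(default_factory=list)  # (index, from, to)


@dataclass(frozen=True)
class RuptureEvent:
    """First transition of a trace; ``censored`` marks folding events below
    the reporting cutoff."""

    force: float
    index: int
    censored: bool = False


def median_filter(trace: PullingTrace, window: int = 11) -> PullingTrace:
    """Running median of the force channel; edges use a shrinking window.

    ``window`` must be odd; window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    f = trace.force
    if window == 1 or f.size <= 1:
        return replace(trace, force=f.copy())
    half = window // 2
    out = np.empty_like(f)
    if f.size >= window:
        core = np.lib.stride_tricks.sliding_window_view(f, window)
        out[half:-half] = np.median(core, axis=-1)
        edge = half
    else:
        edge = f.size  # whole trace handled by the shrinking-window loop
    # edges: symmetric shrinking window, so monotone data is a fixed point
    for i in range(min(edge, f.size)):
        h = min(i, f.size - 1 - i, half)
        out[i] = np.median(f[i - h : i + h + 1])
        j = f.size - 1 - i
        h = min(j, f.size - 1 - j, half)
        out[j] = np.median(f[j - h : j + h + 1])
    return replace(trace, force=out)


def fit_folded_baseline(
    trace: PullingTrace,
    region: tuple[float, float] | None = None,
    fit_intercept: bool = False,
    baseline_fraction: float = 0.2,
) -> FoldedBaseline:
    """Least-squares fit of the folded branch f(lambda) = k_eff * lambda.

    ``region`` is a (lambda_min, lambda_max) window; by default the lowest
    ``baseline_fraction`` of the lambda range is used, where an unfolding
    trace is still folded. The residual scale is the MAD-based robust sigma.
    """
    if region is None:
        lo = trace.lam.min()
        region = (lo, lo + baseline_fraction * (trace.lam.max() - lo))
    mask = (trace.lam >= region[0]) & (trace.lam <= region[1])
    lam, f = trace.lam[mask], trace.force[mask]
    if lam.size < 10:
        raise ValueError(f"baseline region holds {lam.size} samples; need >= 10")
    if fit_intercept:
        A = np.column_stack([lam, np.ones_like(lam)])
        (k_eff, intercept), *_ = np.linalg.lstsq(A, f, rcond=None)
    else:
        k_eff = float(np.dot(lam, f) / np.dot(lam, lam))
        intercept = 0.0
    resid = f - (k_eff * lam + intercept)
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return FoldedBaseline(k_eff=float(k_eff), intercept=float(intercept), sigma=sigma, n_points=int(lam.size))


def classify_states(
    trace: PullingTrace,
    baseline: FoldedBaseline,
    expected_jump: Callable[[np.ndarray], np.ndarray] | float,
    debounce: int = 5,
    commit_posterior: float = 0.9,
) -> StateLabels:
    """Classify each sample as native or unfolded from baseline residuals.

    The residual Delta_i = k_eff*lambda_i + b - f_i is modelled as a
    two-component Gaussian mixture with equal priors: N centred at 0, U at
    the expected force jump at the local force, both with the baseline noise
    sigma. Samples take the maximum-posterior label; a state change is only
    committed after ``debounce`` consecutive samples of the new state whose
    mean posterior exceeds ``commit_posterior``. The posterior requirement
    matters because median filtering correlates neighbouring samples: a
    marginal noise excursion can hold the wrong label for several samples,
    but only a genuine branch change carries saturated posteriors.
    """
    resid = baseline.predict(trace.lam) - trace.force
    f_local = baseline.predict(trace.lam)
    jump = expected_jump(f_local) if callable(expected_jump) else np.full_like(resid, float(expected_jump))
    jump = np.asarray(jump, dtype=float)

    if baseline.sigma <= 0:
        on_n = np.isclose(resid, 0.0, atol=1e-9)
        on_u = np.isclose(resid, jump, atol=1e-9)
        if not np.all(on_n | on_u):
            raise DegenerateModelError(
                "baseline sigma is zero but residuals do not sit on the component means"
            )
        post_n = np.where(np.abs(resid) <= np.abs(resid - jump), 1.0, 0.0)
    else:
        # log-space posterior of N under equal priors
        log_n = -0.5 * (resid / baseline.sigma) ** 2
        log_u = -0.5 * ((resid - jump) / baseline.sigma) ** 2
        post_n = 1.0 / (1.0 + np.exp(np.clip(log_u - log_n, -700, 700)))
    raw = (post_n < 0.5).astype(np.int8)

    # debounce: commit a new state only after `debounce` consecutive samples
    m = max(1, int(debounce))
    states = np.empty_like(raw)
    transitions: list[tuple[int, int, int]] = []
    current = int(raw[0]) if raw.size else N_STATE
    i = 0
    n = raw.size
    while i < n:
        if raw[i] != current and i + m <= n and np.all(raw[i : i + m] == raw[i]):
            post_new = post_n[i : i + m] if raw[i] == N_STATE else 1.0 - post_n[i : i + m]
            if float(np.mean(post_new)) >= commit_posterior:
                transitions.append((i, current, int(raw[i])))
                current = int(raw[i])
        states[i] = current
        i += 1
    return StateLabels(states=states, posterior_n=post_n, transitions=transitions)


def first_transition_force(
    labels: StateLabels,
    trace: PullingTrace,
    direction: str | None = None,
    fold_cutoff: float = 2.0,
    baseline: FoldedBaseline | None = None,
) -> RuptureEvent | None:
    """Force of the first rupture event, or None if no transition occurred.

    Unfolding traces report the first N->U transition, folding traces the
    first U->N. The force is read off the folded-baseline model at the
    transition index when a baseline is given (the measured force sits on
    that branch on the folded side of either event), otherwise the measured
    force at that index.

    Below ``fold_cutoff`` the N/U force jump shrinks toward the noise floor
    and the two states cannot be resolved reliably. Folding events found
    there are returned with ``censored=True`` (detectable but not
    exhaustively so — they must not enter rupture-force densities);
    apparent *unfolding* transitions there are classification noise and are
    skipped in favour of the first transition inside the resolvable range.
    """
    direction = direction or trace.direction
    want = (N_STATE, U_STATE) if direction == "unfold" else (U_STATE, N_STATE)
    for idx, src, dst in labels.transitions:
        if (src, dst) == want:
            force = float(baseline.predict(trace.lam[idx])) if baseline else float(trace.force[idx])
            if force < fold_cutoff:
                if direction == "fold":
                    return RuptureEvent(force=force, index=idx, censored=True)
                continue  # unresolvable region on the unfolding sweep
            return RuptureEvent(force=force, index=idx, censored=False)
    return None
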