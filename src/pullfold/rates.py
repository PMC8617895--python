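"""Kinetic rates from first-rupture forces and from hopping dwell times.

In a constant-loading-rate pulling protocol the first-rupture force is a
random variable whose density rho(f) and survival probability relate to the
force-dependent hazard through k(f) = r * rho(f) / S(f), with r = |df/dt|.
This module builds the empirical chain

    rupture forces -> histogram density -> survival curve -> rate curve

for both sweep directions (unfolding: force increasing, survival of the
native state N; folding: force decreasing, survival of the unfolded state U),
and extracts rates from two-level hopping traces via mean state lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RuptureForceSample",
    "EmpiricalDistribution",
    "SurvivalCurve",
    "RateCurve",
    "apply_fold_cutoff",
    "rupture_density",
    "survival_from_density",
    "rates_from_survival",
    "dwell_rates_from_labels",
]

_NORM_TOL = 1e-9


@dataclass
class RuptureForceSample:
    """First-rupture forces of one direction, one (or pooled) molecule(s).

    ``n_censored`` counts folding events that were detected but fell below
    the reporting cutoff; they reduce the effective event count but never
    enter the density.
    """

    direction: str  # "unfold" | "fold"
    forces: np.ndarray  # pN
    loading_rate: float  # pN/s
    window: tuple[float, float] = (-np.inf, np.inf)
    n_censored: int = 0
    molecule_id: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("unfold", "fold"):
            raise ValueError(f"direction must be 'unfold' or 'fold', got {self.direction!r}")
        if not self.loading_rate > 0:
            raise ValueError("loading_rate must be > 0")
        if self.n_censored < 0:
            raise ValueError("n_censored must be >= 0")
        self.forces = np.asarray(self.forces, dtype=float)
        lo, hi = self.window
        if self.forces.size and (self.forces.min() < lo or self.forces.max() > hi):
            raise ValueError("forces outside the sample window")


@dataclass
class EmpiricalDistribution:
    """Histogram estimate of the rupture-force density rho(f)."""

    bin_edges: np.ndarray  # pN, len = n_bins + 1
    density: np.ndarray  # 1/pN
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges)
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")
        if abs(float(np.sum(self.density * widths)) - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1 over its bins")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class SurvivalCurve:
    """Survival probability on the bin-edge force grid.

    Unfolding sweeps report P_N(f) (probability the molecule is still folded
    at force f, non-increasing); folding sweeps report P_U(f) (still unfolded,
    non-decreasing toward high force).
    """

    force: np.ndarray  # pN, bin edges
    prob: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any(self.prob < -_NORM_TOL) or np.any(self.prob > 1 + _NORM_TOL):
            raise ValueError("survival probabilities must lie in [0, 1]")
        self.prob = np.clip(self.prob, 0.0, 1.0)


@dataclass
class RateCurve:
    """Force-dependent kinetic rate estimates; bins failing the retention
    thresholds are absent, not zero."""

    force: np.ndarray  # pN (bin midpoints)
    rate: np.ndarray  # 1/s
    direction: str
    se_log_rate: np.ndarray | None = None
    n_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.rate <= 0):
            raise ValueError("rates must be > 0 where defined")


def apply_fold_cutoff(sample: RuptureForceSample, cutoff: float = 2.0) -> RuptureForceSample:
    """Censor folding forces below ``cutoff`` (pN).

    Folding events at very low force are not all detectable, so retaining the
    detected ones would bias the density; they are moved to ``n_censored``.
    Unfolding samples pass through unchanged.
    """
    if sample.direction != "fold":
        return sample
    keep = sample.forces >= cutoff
    return RuptureForceSample(
        direction=sample.direction,
        forces=sample.forces[keep],
        loading_rate=sample.loading_rate,
        window=(max(sample.window[0], cutoff), sample.window[1]),
        n_censored=sample.n_censored + int(np.sum(~keep)),
        molecule_id=sample.molecule_id,
    )


def rupture_density(sample: RuptureForceSample, bin_width: float = 0.5) -> EmpiricalDistribution:
    """Histogram density of first-rupture forces, normalized over the
    observed window; bin edges aligned to multiples of ``bin_width``."""
    if sample.forces.size == 0:
        raise ValueError("cannot build a density from an empty sample")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    lo = np.floor(sample.forces.min() / bin_width) * bin_width
    hi = np.ceil(sample.forces.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(sample.forces, bins=edges)
    density = counts / (sample.forces.size * bin_width)
    return EmpiricalDistribution(bin_edges=edges, density=density, counts=counts)


def survival_from_density(dist: EmpiricalDistribution, direction: str) -> SurvivalCurve:
    """Survival probability on the bin edges by cumulative integration.

    Unfolding: P_N(f) = 1 - integral of rho from f_min to f, equal to 1 at
    the lowest edge. Folding: P_U(f) = 1 - integral of rho from f to f_max,
    equal to 1 at the highest edge. The integral of a histogram density is
    exact (piecewise linear in f).
    """
    widths = np.diff(dist.bin_edges)
    mass = dist.density * widths
    if abs(float(mass.sum()) - 1.0) > 1e-6:
        raise ValueError("input density is not normalized")
    if direction == "unfold":
        prob = 1.0 - np.concatenate(([0.0], np.cumsum(mass)))
    elif direction == "fold":
        prob = 1.0 - np.concatenate(([0.0], np.cumsum(mass[::-1])))[::-1]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    prob = np.clip(prob, 0.0, 1.0)
    return SurvivalCurve(force=dist.bin_edges.copy(), prob=prob, direction=direction)


def _rates_on_bins(density, prob_edges, r):
    p_mid = 0.5 * (prob_edges[:-1] + prob_edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * density / p_mid
    return k, p_mid


def rates_from_survival(
    dist: EmpiricalDistribution,
    surv: SurvivalCurve,
    loading_rate: float,
    min_survival: float = 0.05,
    min_count: int = 5,
    n_bootstrap: int = 200,
    seed: int | np.random.Generator | None = None,
) -> RateCurve:
    """Kinetic rate per bin, k(f) = r * rho(f) / S(f) at bin midpoints.

    Bins where the survival probability falls below ``min_survival`` or with
    fewer than ``min_count`` events are dropped (there the ratio blows up on
    noise). ``se_log_rate`` is estimated by a multinomial bootstrap over
    events (``n_bootstrap`` resamples of the bin counts).
    """
    if not loading_rate > 0:
        raise ValueError("loading_rate must be > 0")
    if dist.bin_edges.shape != surv.force.shape or not np.allclose(dist.bin_edges, surv.force):
        raise ValueError("density and survival curves must share the same force grid")
    k, p_mid = _rates_on_bins(dist.density, surv.prob, loading_rate)
    keep = (p_mid >= min_survival) & (dist.counts >= min_count) & (dist.density > 0)
    if not np.any(keep):
        raise ValueError("no bins pass the retention thresholds")

    se = None
    n_total = int(dist.counts.sum())
    if n_bootstrap and n_total > 0:
        rng = np.random.default_rng(seed)
        p = dist.counts / n_total
        widths = np.diff(dist.bin_edges)
        boot_counts = rng.multinomial(n_total, p, size=n_bootstrap)
        boot_density = boot_counts / (n_total * widths)
        log_k = np.full((n_bootstrap, dist.counts.size), np.nan)
        for b in range(n_bootstrap):
            mass = boot_density[b] * widths
            if surv.direction == "unfold":
                prob = 1.0 - np.concatenate(([0.0], np.cumsum(mass)))
            else:
                prob = 1.0 - np.concatenate(([0.0], np.cumsum(mass[::-1])))[::-1]
            kb, pb = _rates_on_bins(boot_density[b], np.clip(prob, 0, 1), loading_rate)
            ok = (kb > 0) & (pb > 0)
            log_k[b, ok] = np.log(kb[ok])
        log_k = log_k[:, keep]
        n_ok = np.sum(np.isfinite(log_k), axis=0)
        centred = log_k - np.where(n_ok > 0, np.nansum(log_k, axis=0) / np.maximum(n_ok, 1), 0.0)
        ss = np.nansum(np.where(np.isfinite(centred), centred**2, 0.0), axis=0)
        se = np.where(n_ok >= 2, np.sqrt(ss / np.maximum(n_ok - 1, 1)), np.nan)

    return RateCurve(
        force=dist.midpoints[keep],
        rate=k[keep],
        direction=surv.direction,
        se_log_rate=se,
        n_events=dist.counts[keep],
    )


def dwell_rates_from_labels(labels, times) -> tuple[float, float]:
    """Kinetic rates from a two-state hopping trace as inverse mean dwells.

    ``labels`` is a per-sample state sequence (0/'N' = folded, 1/'U' =
    unfolded) on the uniformly sampled ``times`` grid. The first and last
    dwells are censored (their true duration is unknown) and excluded.

    Returns (k_unfold, k_fold): the escape rates from N and from U, 1/s.
    """
    lab = np.asarray(labels)
    if lab.dtype.kind in "US":
        lab = (lab == "U").astype(int)
    else:
        lab = lab.astype(int)
    t = np.asarray(times, dtype=float)
    if lab.size != t.size or lab.size < 2:
        raise ValueError("labels and times must be equal-length, size >= 2")
    dt = float(np.median(np.diff(t)))
    for state_val, name in ((0, "N"), (1, "U")):
        if not np.any(lab == state_val):
            raise ValueError(f"state {name} is never visited in the trace")

    change = np.flatnonzero(np.diff(lab) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lab.size]))
    states = lab[starts]
    durations = (ends - starts) * dt
    # censor incomplete first/last dwells
    states, durations = states[1:-1], durations[1:-1]

    out = []
    for state_val, name in ((0, "N"), (1, "U")):
        d = durations[states == state_val]
        if d.size == 0:
            raise ValueError(f"no completed dwell observed in state {name}")
        out.append(1.0 / float(d.mean()))
    return out[0], out[1]
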