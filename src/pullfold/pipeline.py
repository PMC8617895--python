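"""End-to-end orchestration: simulate -> detect -> rates -> fit -> TS map.

Each stage consumes the previous stage's table, so the stages are
independently runnable (and testable) from the command line or from Python.
All randomness flows from a single root seed, split per stage with numpy's
``SeedSequence`` so results are fully determined by (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pfio
from .bell_evans import (
    BEFitResult,
    BellEvansParams,
    combine_fits,
    fit_be,
    fold_rate,
    predicted_fold_rate_moving_ts,
)
from .elastic import ElasticParams, released_extension
from .fdc import (
    FoldedBaseline,
    PullingTrace,
    classify_states,
    first_transition_force,
    fit_folded_baseline,
    median_filter,
)
from .rates import (
    RateCurve,
    RuptureForceSample,
    apply_fold_cutoff,
    rates_from_survival,
    rupture_density,
    survival_from_density,
)
from .simulate import SimulationConfig, generate_fdc_trace
from .thermal import ThermalContext
from .tsmap import TSProfile, ts_profile

__all__ = [
    "AnalysisConfig",
    "EmptyResultError",
    "run_simulate",
    "detect_events",
    "rates_from_rupture_table",
    "run_analysis",
    "RunResult",
]

log = logging.getLogger("pullfold")


class EmptyResultError(RuntimeError):
    """The pipeline produced no usable events."""


@dataclass
class AnalysisConfig:
    """Everything the analysis pipeline needs, serializable to YAML."""

    input_dir: str | None = None
    output_dir: str = "pullfold_out"
    temperature: float = 298.0
    elastic: ElasticParams = field(default_factory=ElasticParams.barnase)
    # detection
    median_window: int = 11
    debounce: int = 5
    fold_cutoff: float = 2.0  # pN
    baseline_fraction: float = 0.2
    fit_intercept: bool = False
    # binning / thresholds
    bin_width: float = 0.5  # pN
    min_survival: float = 0.05
    min_count: int = 5
    n_bootstrap: int = 200
    # TS mapping
    x_dagger: float | None = None  # nm; None -> use the fitted value
    ts_f_min: float = 2.0
    ts_f_max: float = 25.0
    ts_f_step: float = 0.1
    seed: int = 0
    simulation: SimulationConfig | None = None

    @property
    def ctx(self) -> ThermalContext:
        return ThermalContext(self.temperature)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            sim["be"] = dataclasses.asdict(self.simulation.be)
            sim["elastic"] = dataclasses.asdict(self.simulation.elastic)
            sim["ctx"] = {"temperature": self.simulation.ctx.temperature}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        d["elastic"] = ElasticParams(**d["elastic"])
        sim = d.get("simulation")
        if sim is not None:
            sim = dict(sim)
            sim["be"] = BellEvansParams(**sim["be"])
            sim["elastic"] = ElasticParams(**sim["elastic"])
            sim["ctx"] = ThermalContext(**sim["ctx"])
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        """Short stable hash of the scientific configuration (including the
        seed); filesystem locations are excluded so the same analysis run in
        two directories carries the same digest."""
        d = self.to_dict()
        d.pop("input_dir", None)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_simulate(cfg: AnalysisConfig) -> list[Path]:
    """Generate n_cycles unfold + fold traces with truth sidecars.

    One TSV file per trace, named ``cycle{i:04d}_{direction}.tsv`` with a
    matching ``.truth`` sidecar; a ``manifest.json`` records the seed and
    the config digest. Validation happens before any file is written.
    """
    if cfg.simulation is None:
        raise ValueError("run_simulate requires cfg.simulation")
    sim = cfg.simulation
    out = Path(cfg.output_dir) / "traces"
    out.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()
    children = np.random.SeedSequence(sim.seed).spawn(2 * sim.n_cycles)
    paths: list[Path] = []
    for i in range(sim.n_cycles):
        for j, direction in enumerate(("unfold", "fold")):
            rng = np.random.default_rng(children[2 * i + j])
            trace, truth = generate_fdc_trace(sim, direction, rng=rng, cycle_id=i)
            p = out / f"cycle{i:04d}_{direction}.tsv"
            pfio.write_trace(p, trace, digest=digest)
            pfio.write_truth(p.with_suffix(".truth"), [truth])
            paths.append(p)
    pfio.write_json(
        out / "manifest.json",
        {"seed": sim.seed, "config_digest": digest, "n_files": len(paths)},
    )
    log.info("simulated %d traces into %s", len(paths), out)
    return paths


def _expected_jump(cfg: AnalysisConfig, baseline: FoldedBaseline):
    """First-order force-jump model: k_eff times the released extension at
    the local force (forces clipped away from zero for the WLC inversion)."""

    def jump(f_local):
        f_safe = np.maximum(np.asarray(f_local, dtype=float), 0.25)
        return baseline.k_eff * released_extension(f_safe, cfg.elastic, cfg.ctx)

    return jump


def detect_events(traces: list[PullingTrace], cfg: AnalysisConfig) -> pd.DataFrame:
    """Run the detection chain on every trace; one row per trace.

    The folded baseline is fitted on each unfolding trace and shared with
    the folding trace of the same (molecule, cycle) — the tether stiffness
    is a property of the construct, and on a folding trace the low-lambda
    region is contaminated by the unfolded branch. Folding traces without a
    partner fall back to fitting their own low-lambda region.
    """
    baselines: dict[tuple[str, int], FoldedBaseline] = {}
    filtered: list[PullingTrace] = []
    for trace in traces:
        ft = median_filter(trace, cfg.median_window)
        filtered.append(ft)
        if trace.direction == "unfold":
            baselines[(trace.molecule_id, trace.cycle_id)] = fit_folded_baseline(
                ft, fit_intercept=cfg.fit_intercept, baseline_fraction=cfg.baseline_fraction
            )
    rows = []
    for trace in filtered:
        key = (trace.molecule_id, trace.cycle_id)
        baseline = baselines.get(key)
        if baseline is None:
            baseline = fit_folded_baseline(
                trace, fit_intercept=cfg.fit_intercept, baseline_fraction=cfg.baseline_fraction
            )
        labels = classify_states(trace, baseline, _expected_jump(cfg, baseline), cfg.debounce)
        event = first_transition_force(
            labels, trace, fold_cutoff=cfg.fold_cutoff, baseline=baseline
        )
        rows.append(
            {
                "molecule_id": trace.molecule_id,
                "cycle_id": trace.cycle_id,
                "direction": trace.direction,
                "force_pN": np.nan if event is None else event.force,
                "censored": False if event is None else event.censored,
                "detected": event is not None,
                "loading_rate_pN_s": trace.loading_rate,
            }
        )
    return pd.DataFrame(rows)


def _samples_from_table(table: pd.DataFrame, cfg: AnalysisConfig) -> dict[str, RuptureForceSample]:
    samples = {}
    for direction in ("unfold", "fold"):
        sub = table[(table["direction"] == direction) & table["detected"]]
        if sub.empty:
            continue
        uncensored = sub[~sub["censored"].astype(bool)]
        sample = RuptureForceSample(
            direction=direction,
            forces=uncensored["force_pN"].to_numpy(float),
            loading_rate=float(sub["loading_rate_pN_s"].median()),
            n_censored=int(sub["censored"].astype(bool).sum()),
        )
        samples[direction] = apply_fold_cutoff(sample, cfg.fold_cutoff)
    return samples


def rates_from_rupture_table(
    table: pd.DataFrame, cfg: AnalysisConfig
) -> dict[str, dict]:
    """Density, survival and rate curves per direction from a rupture table."""
    samples = _samples_from_table(table, cfg)
    if not samples:
        raise EmptyResultError("no detectable events in the rupture table")
    out = {}
    boot_seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    for i, (direction, sample) in enumerate(sorted(samples.items())):
        if sample.forces.size == 0:
            continue
        dist = rupture_density(sample, cfg.bin_width)
        surv = survival_from_density(dist, direction)
        curve = rates_from_survival(
            dist,
            surv,
            sample.loading_rate,
            min_survival=cfg.min_survival,
            min_count=cfg.min_count,
            n_bootstrap=cfg.n_bootstrap,
            seed=np.random.default_rng(boot_seeds[i]),
        )
        out[direction] = {"sample": sample, "density": dist, "survival": surv, "rates": curve}
    return out


@dataclass
class RunResult:
    """Bundle of everything run_analysis computed."""

    rupture_table: pd.DataFrame
    curves: dict[str, dict]
    fit: BEFitResult
    ts: TSProfile
    fold_prediction: RateCurve
    summary: dict


def run_analysis(cfg: AnalysisConfig, traces: list[PullingTrace] | None = None) -> RunResult:
    """Full analysis: detection, rate extraction, BE fit, TS mapping.

    When several molecule ids are present the BE branches are fitted per
    molecule and averaged with the standard statistical error across
    molecules; molecules with too few events fall back to the pooled fit.
    Writes all stage tables, a results JSON and a run log to
    ``cfg.output_dir``; every file carries the config digest.
    """
    if traces is None:
        if cfg.input_dir is None:
            raise ValueError("run_analysis needs traces or cfg.input_dir")
        in_dir = Path(cfg.input_dir)
        files = sorted(in_dir.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no trace files (*.tsv) found in {in_dir}")
        traces = [t for f in files for t in pfio.read_trace_table(f)]

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()

    table = detect_events(traces, cfg)
    n_detected = int(table["detected"].sum())
    n_censored = int(table["censored"].astype(bool).sum())
    if n_detected == 0:
        raise EmptyResultError("no detectable events in any trace")
    pfio.write_table(out / "ruptures.tsv", table, digest=digest)

    curves = rates_from_rupture_table(table, cfg)
    if "unfold" not in curves or "fold" not in curves:
        raise EmptyResultError("need events on both branches to fit the BE model")
    for direction, c in curves.items():
        dist, surv, curve = c["density"], c["survival"], c["rates"]
        pfio.write_table(
            out / f"density_{direction}.tsv",
            pd.DataFrame(
                {
                    "force_pN": dist.midpoints,
                    "density_per_pN": dist.density,
                    "count": dist.counts,
                }
            ),
            digest=digest,
        )
        pfio.write_table(
            out / f"survival_{direction}.tsv",
            pd.DataFrame({"force_pN": surv.force, "survival": surv.prob}),
            digest=digest,
        )
        pfio.write_table(
            out / f"rates_{direction}.tsv",
            pd.DataFrame(
                {
                    "force_pN": curve.force,
                    "rate_per_s": curve.rate,
                    "se_log_rate": curve.se_log_rate,
                    "n_events": curve.n_events,
                }
            ),
            digest=digest,
        )

    fit = _fit_with_molecule_averaging(table, curves, cfg)

    x_dagger = cfg.x_dagger if cfg.x_dagger is not None else fit.params.x_dagger
    f_grid = np.arange(cfg.ts_f_min, cfg.ts_f_max + 0.5 * cfg.ts_f_step, cfg.ts_f_step)
    ts = ts_profile(f_grid, x_dagger, cfg.elastic, cfg.ctx)
    pfio.write_table(out / "ts_profile.tsv", ts.to_frame(), digest=digest)

    fold_curve = curves["fold"]["rates"]
    anchor_f = float(np.median(fold_curve.force))
    anchor_f = min(max(anchor_f, ts.force[0]), ts.force[-1])
    anchor_rate = float(fold_rate(anchor_f, fit.params, cfg.ctx))
    prediction = predicted_fold_rate_moving_ts(ts.force, ts, anchor_f, anchor_rate, cfg.ctx)
    pfio.write_table(
        out / "fold_rate_prediction.tsv",
        pd.DataFrame({"force_pN": prediction.force, "rate_per_s": prediction.rate}),
        digest=digest,
    )

    fc = fit.coexistence_force
    x_m_th_fc = (
        float(released_extension(fc, cfg.elastic, cfg.ctx)) if fc > 0 else float("nan")
    )
    summary = {
        "config_digest": digest,
        "seed": cfg.seed,
        "n_traces": len(traces),
        "n_detected": n_detected,
        "n_censored": n_censored,
        "n_bins_unfold": int(curves["unfold"]["rates"].force.size),
        "n_bins_fold": int(curves["fold"]["rates"].force.size),
        "x_dagger_nm": fit.params.x_dagger,
        "x_star_nm": fit.params.x_star,
        "se": fit.se,
        "log_k0_unfold": fit.params.log_k0_unfold,
        "log_k0_fold": fit.params.log_k0_fold,
        "coexistence_force_pN": fc,
        "x_m_exp_nm": fit.x_m_exp,
        "x_m_th_at_fc_nm": x_m_th_fc,
        "ts_x_dagger_nm": x_dagger,
    }
    pfio.write_json(out / "results.json", summary)
    (out / "run.log").write_text(
        "\n".join(
            [
                f"config_digest={digest}",
                f"seed={cfg.seed}",
                f"traces={len(traces)} detected={n_detected} censored={n_censored}",
                f"bins_unfold={summary['n_bins_unfold']} bins_fold={summary['n_bins_fold']}",
                f"x_dagger={fit.params.x_dagger:.3f} nm  x_star={fit.params.x_star:.3f} nm",
                f"fc={fc:.3f} pN  x_m_exp={fit.x_m_exp:.3f} nm  x_m_th(fc)={x_m_th_fc:.3f} nm",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    return RunResult(
        rupture_table=table,
        curves=curves,
        fit=fit,
        ts=ts,
        fold_prediction=prediction,
        summary=summary,
    )


def _fit_with_molecule_averaging(table, curves, cfg: AnalysisConfig) -> BEFitResult:
    pooled = fit_be(curves["unfold"]["rates"], curves["fold"]["rates"], cfg.ctx)
    molecules = sorted(table["molecule_id"].unique())
    if len(molecules) < 2:
        return pooled
    fits = []
    for mol in molecules:
        sub = table[table["molecule_id"] == mol]
        try:
            c = rates_from_rupture_table(sub, cfg)
            fits.append(fit_be(c["unfold"]["rates"], c["fold"]["rates"], cfg.ctx))
        except (ValueError, KeyError, EmptyResultError) as err:
            warnings.warn(f"molecule {mol}: per-molecule fit skipped ({err})", UserWarning)
    return combine_fits(fits, cfg.ctx) if len(fits) >= 2 else pooled
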