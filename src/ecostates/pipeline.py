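"""End-to-end orchestration: standardize -> DFA selection -> per-trend HMM
-> non-stationarity screen, with reproducible, file-backed outputs.

A run is fully determined by (inputs, RunConfig): one master seed is
expanded into independent per-stage seeds, and all output files are
written with fixed numeric formatting so identical runs are byte-identical.
A non-convergent HMM stage is recorded and the run continues — short
series legitimately defeat state detection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dfa as dfa_mod
from . import hmm as hmm_mod
from . import nonstationarity as ns_mod
from .panel import IndicatorPanel, load_panel, standardize
from .simulate import RegimeSpec, SimulationConfig, make_dataset

__all__ = ["RunConfig", "RunResult", "run_model", "summarize"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one model run (one indicator group/region/window)."""

    # input: either a CSV panel or a synthetic scenario
    input_csv: str | None = None
    metadata_csv: str | None = None
    simulate: SimulationConfig | None = None
    # panel selection
    group: str | None = None
    region: str | None = None
    start_year: int | None = None
    end_year: int | None = None
    # DFA candidate grid and settings
    trend_candidates: tuple = (1, 2)
    r_candidates: tuple = dfa_mod.R_STRUCTURES
    dfa_max_iterations: int = 5000
    dfa_tolerance: float = 1e-6
    compute_intervals: bool = True
    # HMM settings
    state_candidates: tuple = (2, 3)
    hmm_restarts: int = 20
    # non-stationarity settings
    window: int = 11
    min_pairs: int = 8
    level: float = 0.90
    magnitude_threshold: float = 0.5
    # bookkeeping
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("specify exactly one of input_csv or simulate")
        if self.start_year is not None and self.end_year is not None:
            if self.start_year >= self.end_year:
                raise ValueError("start_year must precede end_year")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "regimes" in sim:
                sim["regimes"] = tuple(
                    RegimeSpec(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in r.items()})
                    for r in sim["regimes"]
                )
            for key in ("start_offsets",):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SimulationConfig(**sim)
        for key in ("trend_candidates", "r_candidates", "state_candidates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def analysis_dict(self) -> dict:
        """The analysis-defining configuration: everything except where the
        outputs land."""
        d = _as_jsonable(self)
        d.pop("output_dir", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunResult:
    """Everything one run produced, before/after serialization."""

    config: RunConfig
    panel: IndicatorPanel
    fit: dfa_mod.DfaFit
    loadings: list
    hmm_fits: dict          # trend id -> HmmFit
    hmm_failures: dict      # trend id -> reason string
    segments: dict          # trend id -> StateSegments
    window_results: list    # WindowCorrelation, all series x trends
    flags: list             # ChangeFlags
    output_dir: str | None = None
    log_lines: list = field(default_factory=list)


def _stage_seeds(seed: int, n: int = 4):
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_model(config: RunConfig) -> RunResult:
    """Execute the full analysis for one configuration.

    Raises before writing anything if the inputs or configuration are
    invalid; after that, downstream stage failures (e.g. a non-convergent
    HMM on a short trend) are recorded in the result and the run continues.
    """
    sim_seed, dfa_seed, hmm_seed, _ = _stage_seeds(config.seed)
    log = []

    if config.input_csv is not None:
        panel = load_panel(
            config.input_csv, metadata_path=config.metadata_csv,
            group=config.group, region=config.region,
        )
        log.append(f"loaded panel from {config.input_csv}: "
                   f"{panel.n_series} series x {len(panel.years)} years")
    else:
        sim = dataclasses.replace(config.simulate, seed=sim_seed)
        ds = make_dataset(sim)
        panel = ds.panel
        log.append(f"simulated panel: {panel.n_series} series x {len(panel.years)} years")
    if config.start_year is not None or config.end_year is not None:
        panel = panel.window(config.start_year, config.end_year)
        log.append(f"analysis window {panel.years[0]}-{panel.years[-1]}, "
                   f"{panel.n_series} series retained")
    if panel.n_series < 2:
        raise ValueError("need at least 2 series after filtering")

    std = standardize(panel)

    fit = dfa_mod.select_dfa(
        std,
        trend_candidates=config.trend_candidates,
        r_candidates=config.r_candidates,
        max_iterations=config.dfa_max_iterations,
        loglik_tolerance=config.dfa_tolerance,
        seed=dfa_seed,
    )
    fit = dfa_mod.rotate_and_align(fit)
    log.append(f"selected DFA: {fit.n_trends} trend(s), R={fit.config.r_structure}, "
               f"AICc={fit.aicc:.3f}")

    loadings = dfa_mod.loading_intervals(fit) if config.compute_intervals else []

    hmm_cfg = hmm_mod.HmmConfig(
        state_candidates=config.state_candidates,
        n_restarts=config.hmm_restarts,
        seed=hmm_seed,
    )
    hmm_fits, hmm_failures, segments = {}, {}, {}
    for k in range(fit.n_trends):
        tid = k + 1
        try:
            hfit = hmm_mod.select_hmm(fit.trends[k], hmm_cfg)
            hmm_fits[tid] = hfit
            segments[tid] = hmm_mod.to_segments(
                hfit.decoded_path, panel.years, hfit.persistence
            )
            log.append(f"trend {tid}: {hfit.K} states selected, "
                       f"persistence {np.round(hfit.persistence, 3).tolist()}")
        except (hmm_mod.HmmError, ValueError) as e:
            hmm_failures[tid] = str(e)
            log.append(f"trend {tid}: HMM stage did not converge ({e})")

    windows, flags = [], []
    for k in range(fit.n_trends):
        tid = k + 1
        for s in std.series:
            res = ns_mod.moving_window_corr(
                s.values, fit.trends[k], years=panel.years,
                window=config.window, min_pairs=config.min_pairs,
                level=config.level, series_name=s.name, trend_id=tid,
            )
            windows.extend(res)
            if res:
                flags.append(ns_mod.detect_changes(res, config.magnitude_threshold))

    result = RunResult(
        config=config, panel=panel, fit=fit, loadings=loadings,
        hmm_fits=hmm_fits, hmm_failures=hmm_failures, segments=segments,
        window_results=windows, flags=flags, output_dir=config.output_dir,
        log_lines=log,
    )
    if config.output_dir is not None:
        _write_outputs(result)
    return result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_outputs(result: RunResult):
    out = Path(result.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit = result.fit

    _write_csv(fit.trends_frame(), out / "trends.csv")
    if result.loadings:
        _write_csv(dfa_mod.loadings_frame(result.loadings), out / "loadings.csv")
    _write_csv(fit.candidates if fit.candidates is not None else pd.DataFrame(),
               out / "dfa_candidates.csv")

    state_rows, seg_frames, hmm_tables = [], [], {}
    for tid, hfit in sorted(result.hmm_fits.items()):
        for yr, s in zip(result.panel.years, hfit.decoded_path):
            state_rows.append(dict(year=int(yr), trend=tid, decoded_state=int(s)))
        sf = result.segments[tid].to_frame()
        sf.insert(0, "trend", tid)
        seg_frames.append(sf)
        hmm_tables[str(tid)] = json.loads(
            hfit.candidates.to_json(orient="records")
        ) if hfit.candidates is not None else None
    _write_csv(pd.DataFrame(state_rows, columns=["year", "trend", "decoded_state"]),
               out / "states.csv")
    _write_csv(
        pd.concat(seg_frames, ignore_index=True) if seg_frames
        else pd.DataFrame(columns=["trend", "start_year", "end_year", "state", "persistence"]),
        out / "segments.csv",
    )
    with open(out / "hmm_candidates.json", "w") as fh:
        json.dump({"fits": hmm_tables, "failures": result.hmm_failures}, fh,
                  indent=1, sort_keys=True)

    _write_csv(ns_mod.windows_frame(result.window_results), out / "nonstationarity.csv")
    _write_csv(ns_mod.flags_frame(result.flags), out / "flags.csv")

    provenance = dict(
        config=result.config.analysis_dict(),
        config_hash=result.config.config_hash(),
        seed=result.config.seed,
        package="ecostates 0.1.0",
    )
    with open(out / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")
    with open(out / "summary.txt", "w") as fh:
        fh.write(summarize(result))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize(result: RunResult) -> str:
    """Deterministic plain-text report: significant loadings by sign, state
    segments as year ranges with persistence, and non-stationarity flags."""
    fit = result.fit
    lines = []
    lines.append("Ecosystem indicator synthesis")
    lines.append("=============================")
    lines.append(f"Panel: {result.panel.n_series} series, "
                 f"{result.panel.years[0]}-{result.panel.years[-1]}")
    lines.append(f"Selected DFA model: {fit.n_trends} trend(s), "
                 f"R structure '{fit.config.r_structure}', AICc {fit.aicc:.2f}")
    lines.append("")
    for k in range(fit.n_trends):
        tid = k + 1
        lines.append(f"Trend {tid}")
        lines.append("-" * len(f"Trend {tid}"))
        sig = [e for e in result.loadings if e.trend == tid and e.significant]
        pos = sorted(e.series for e in sig if e.estimate > 0)
        neg = sorted(e.series for e in sig if e.estimate < 0)
        if result.loadings:
            if not sig:
                lines.append("  no significant loadings (95% CI)")
            else:
                if pos:
                    lines.append("  positive loadings: " + ", ".join(pos))
                if neg:
                    lines.append("  negative loadings: " + ", ".join(neg))
        if tid in result.hmm_fits:
            hfit = result.hmm_fits[tid]
            lines.append(f"  ecosystem states ({hfit.K}-state model):")
            for start, end, state in result.segments[tid].segments:
                pers = hfit.persistence[state - 1]
                lines.append(
                    f"    {start}-{end}: state {state} "
                    f"(probability of staying in state = {pers:.2f})"
                )
        elif tid in result.hmm_failures:
            lines.append(f"  state detection did not converge: {result.hmm_failures[tid]}")
        flagged = [f for f in result.flags if f.trend == tid
                   and (f.sign_change or f.magnitude_change)]
        if flagged:
            lines.append("  non-stationary indicator relationships:")
            for f in sorted(flagged, key=lambda f: f.series):
                kinds = []
                if f.sign_change:
                    kinds.append("sign change")
                if f.magnitude_change:
                    kinds.append(f"magnitude change (max |dr|={f.max_delta_r:.2f})")
                lines.append(f"    {f.series}: " + ", ".join(kinds))
        else:
            lines.append("  no non-stationary indicator relationships flagged")
        lines.append("")
    return "\n".join(lines)
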