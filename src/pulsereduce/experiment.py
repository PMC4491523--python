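"""Reduction-study orchestration: simulate, reduce, re-simulate, compare.

A study simulates a complete network once, applies a reduction schedule,
re-simulates every reduced model and reports the six waveform-error
metrics at each probe, producing a summary table of segment count versus
error.  A ``"full"`` schedule step compares against Frank's two-element
windkessel of the whole network (pressure only; the root flow is the
prescribed inflow in both models).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import write_network, write_waveforms_csv
from .metrics import ErrorReport, waveform_errors
from .network import ArterialNetwork, InflowWaveform, Windkessel2, count_parameters
from .reduction import ReductionSchedule, apply_schedule
from .solver import Probe, SolverSettings, WaveformSet, simulate
from .windkessel import wk2_response

__all__ = ["ExperimentConfig", "StudyResult", "run_reduction_study"]


@dataclass
class ExperimentConfig:
    """Declarative description of one reduction experiment."""

    network: str                      # path to a network document
    inflow: Optional[str] = None      # path to an inflow CSV (else embedded)
    schedule: str = "trim-generation"
    probes: List[Dict] = field(default_factory=list)
    out_dir: str = "study_out"
    seed: int = 0
    dx: float = 0.01
    cfl: float = 0.5
    max_cycles: int = 20
    periodicity_tol: float = 1e-3
    initial_pressure: Optional[float] = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    """Summary of a reduction study."""

    summary: pd.DataFrame
    waveforms: Dict[str, WaveformSet]
    reports: Dict[str, Dict[str, ErrorReport]]


def _frank_waveforms(network: ArterialNetwork, inflow: InflowWaveform,
                     reference: WaveformSet, wk: Windkessel2) -> WaveformSet:
    """Root-site waveforms of the whole-system two-element windkessel."""
    n_cycles = 12
    resp = wk2_response(inflow, wk.R, wk.C, p_out=wk.p_out,
                        t_end=n_cycles * inflow.period,
                        n_out=n_cycles * len(reference.time))
    keep = resp.time >= (n_cycles - 1) * inflow.period - 1e-12
    t = resp.time[keep] - (n_cycles - 1) * inflow.period
    p = np.interp(reference.time, t, resp.pressure[keep])
    q = np.asarray(inflow(reference.time), float)
    sites = {}
    for site in reference.sites:
        sites[site] = {"P": p, "Q": q, "A": np.full_like(p, np.nan)}
    return WaveformSet(time=reference.time.copy(), sites=sites)


def run_reduction_study(
    network: ArterialNetwork,
    inflow: InflowWaveform,
    schedule: ReductionSchedule,
    probes: Sequence[Probe],
    settings: Optional[SolverSettings] = None,
    out_dir: Optional[Path] = None,
    seed: int = 0,
    config_hash: str = "",
) -> StudyResult:
    """Run the complete model and every reduced model in the schedule.

    Returns the summary table (one row per model: label, segment count,
    parameter count and the six error metrics per probe) and, when
    ``out_dir`` is given, writes waveform CSVs, reduced-network documents
    and a JSON summary stamped with the seed and config hash.
    """
    settings = settings or SolverSettings()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    complete = simulate(network, inflow, settings, probes)
    waveforms: Dict[str, WaveformSet] = {"complete": complete}
    reports: Dict[str, Dict[str, ErrorReport]] = {}
    rows = [{
        "model": "complete",
        "segments": len(network.segments),
        "parameters": count_parameters(network),
        "converged": complete.converged,
    }]

    for label, reduced in apply_schedule(network, schedule):
        if isinstance(reduced, Windkessel2):
            waves = _frank_waveforms(network, inflow, complete, reduced)
            n_seg, n_par = 0, 4  # inflow, net R, total C, outflow pressure
            converged = True
        else:
            waves = simulate(reduced, inflow, settings, probes)
            n_seg = len(reduced.segments)
            n_par = count_parameters(reduced)
            converged = waves.converged
            if out_dir is not None:
                write_network(reduced, out_dir / f"network_{label.replace(':', '_')}.json")
        waveforms[label] = waves
        row = {"model": label, "segments": n_seg, "parameters": n_par,
               "converged": converged}
        reports[label] = {}
        for site in complete.sites:
            rep = waveform_errors(
                complete.sites[site]["P"], waves.sites[site]["P"],
                complete.sites[site]["Q"], waves.sites[site]["Q"])
            reports[label][site] = rep
            for key, val in rep.as_dict(percent=True).items():
                row[f"{site}:{key}"] = val
        rows.append(row)

    summary = pd.DataFrame(rows)
    if out_dir is not None:
        for label, waves in waveforms.items():
            write_waveforms_csv(waves, out_dir / f"waves_{label.replace(':', '_')}.csv")
        summary.to_csv(out_dir / "summary.csv", index=False)
        meta = {
            "seed": seed,
            "config_hash": config_hash,
            "models": [r["model"] for r in rows],
        }
        (out_dir / "study.json").write_text(json.dumps({
            "meta": meta,
            "summary": rows,
        }, indent=1, default=lambda o: bool(o) if isinstance(o, np.bool_) else o))
    return StudyResult(summary=summary, waveforms=waveforms, reports=reports)
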