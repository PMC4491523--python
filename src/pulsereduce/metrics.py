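"""Relative-error metrics comparing reduced-model to complete-model waveforms.

Six scalar metrics summarise the mismatch between pressure and flow
waveforms of a reduced (R) and a complete (C) model sampled on a common
time grid of N_t points:

    eps_P_avg  = mean_i |P_i^R - P_i^C| / |P_i^C|
    eps_Q_avg  = mean_i |Q_i^R - Q_i^C| / max_j Q_j^C
    eps_P_sys  = (max P^R - max P^C) / max P^C
    eps_Q_sys  = (max Q^R - max Q^C) / max Q^C
    eps_P_dias = (min P^R - min P^C) / min P^C
    eps_Q_dias = (min Q^R - min Q^C) / max_j Q_j^C

Averages are unsigned; systolic/diastolic errors keep their sign.  Flow
errors are normalised by the peak complete-model flow to avoid division
by near-zero diastolic flows (note this makes eps_Q_avg sensitive to a
common offset only through the peak normaliser).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

__all__ = ["ErrorReport", "error_report"]


@dataclass(frozen=True)
class ErrorReport:
    """The six relative-error metrics, stored as fractions (0.01 = 1%)."""

    eps_P_avg: float
    eps_Q_avg: float
    eps_P_sys: float
    eps_Q_sys: float
    eps_P_dias: float
    eps_Q_dias: float

    def as_dict(self, percent: bool = False) -> Dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {k: scale * v for k, v in self.__dict__.items()}

    def __str__(self) -> str:
        d = self.as_dict(percent=True)
        return ", ".join(f"{k}={v:+.3f}%" for k, v in d.items())


def error_report(complete, reduced, site: str) -> ErrorReport:
    """Compare two :class:`~pulsereduce.solver.WaveformSet` at one site."""
    if site not in complete.sites or site not in reduced.sites:
        raise KeyError(f"site '{site}' missing from one of the waveform sets")
    if complete.time.shape != reduced.time.shape or not np.allclose(
            complete.time - complete.time[0], reduced.time - reduced.time[0],
            rtol=0.0, atol=1e-9 * (complete.time[-1] - complete.time[0] + 1e-300)):
        raise ValueError("waveform sets are not sampled on the same time grid")
    pc = np.asarray(complete.sites[site]["P"], float)
    pr = np.asarray(reduced.sites[site]["P"], float)
    qc = np.asarray(complete.sites[site]["Q"], float)
    qr = np.asarray(reduced.sites[site]["Q"], float)
    return waveform_errors(pc, pr, qc, qr)


def waveform_errors(p_complete, p_reduced, q_complete, q_reduced) -> ErrorReport:
    """Compute the six metrics from raw arrays on a shared grid."""
    pc, pr = np.asarray(p_complete, float), np.asarray(p_reduced, float)
    qc, qr = np.asarray(q_complete, float), np.asarray(q_reduced, float)
    if pc.shape != pr.shape or qc.shape != qr.shape or pc.shape != qc.shape:
        raise ValueError("all waveforms must share one grid")
    q_max = qc.max()
    if q_max <= 0:
        raise ValueError("peak complete-model flow must be positive")
    if np.any(np.abs(pc) <= 0) or pc.min() <= 0:
        raise ValueError("complete-model pressure must be positive")
    return ErrorReport(
        eps_P_avg=float(np.mean(np.abs(pr - pc) / np.abs(pc))),
        eps_Q_avg=float(np.mean(np.abs(qr - qc)) / q_max),
        eps_P_sys=float((pr.max() - pc.max()) / pc.max()),
        eps_Q_sys=float((qr.max() - qc.max()) / qc.max()),
        eps_P_dias=float((pr.min() - pc.min()) / pc.min()),
        eps_Q_dias=float((qr.min() - qc.min()) / q_max),
    )
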