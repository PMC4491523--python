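"""Reading and writing network documents, inflows and waveform outputs.

Network documents are JSON (canonical) or YAML (accepted), with top-level
keys ``globals``, ``segments``, ``terminals`` and optionally ``inflow``.
Segment geometry may be given as inlet/outlet diastolic radius (m) or area
(m^2); wall stiffness as ``beta`` (Pa m) or diastolic PWV (m/s).  A
terminal ``R1`` may be the string ``"Z0"``, meaning the outlet
characteristic impedance of the attached segment.

An optional ``units`` block declares non-SI I/O units, e.g.
``{"pressure": "mmHg", "flow": "mL/s"}``; values are converted to SI on
read and from SI on write.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .network import (
    MMHG,
    ArterialNetwork,
    ArterialSegment,
    GlobalParams,
    InflowWaveform,
    NetworkError,
    Windkessel2,
    Windkessel3,
)

__all__ = [
    "read_network",
    "write_network",
    "read_inflow_csv",
    "write_inflow_csv",
    "write_waveforms_csv",
    "read_waveforms_csv",
    "write_fields_h5",
]

_PRESSURE_UNITS = {"Pa": 1.0, "mmHg": MMHG}
_FLOW_UNITS = {"m3/s": 1.0, "mL/s": 1e-6, "ml/s": 1e-6}


def _unit_factors(units: Optional[dict]) -> Tuple[float, float]:
    units = units or {}
    try:
        fp = _PRESSURE_UNITS[units.get("pressure", "Pa")]
        fq = _FLOW_UNITS[units.get("flow", "m3/s")]
    except KeyError as exc:
        raise NetworkError(f"unknown unit {exc} in units block") from exc
    return fp, fq


def _segment_from_doc(doc: dict, rho: float) -> ArterialSegment:
    name = doc.get("id")
    if not name:
        raise NetworkError("segment without an 'id'")
    length = float(doc["length"])
    if "radius_in" in doc:
        r_in, r_out = float(doc["radius_in"]), float(doc.get("radius_out", doc["radius_in"]))
    elif "area_in" in doc:
        r_in = math.sqrt(float(doc["area_in"]) / math.pi)
        r_out = math.sqrt(float(doc.get("area_out", doc["area_in"])) / math.pi)
    else:
        raise NetworkError(f"segment '{name}': needs radius_in or area_in")
    trunk = bool(doc.get("trunk", False))
    if "beta_in" in doc:
        return ArterialSegment(name, length, r_in, r_out,
                               float(doc["beta_in"]),
                               float(doc.get("beta_out", doc["beta_in"])),
                               trunk=trunk)
    if "pwv_in" in doc:
        return ArterialSegment.from_pwv(name, length, r_in, r_out,
                                        float(doc["pwv_in"]),
                                        float(doc.get("pwv_out", doc["pwv_in"])),
                                        rho=rho, trunk=trunk)
    raise NetworkError(f"segment '{name}': needs beta_in or pwv_in")


def network_from_dict(doc: dict) -> Tuple[ArterialNetwork, Optional[InflowWaveform]]:
    """Build a network (and optional inflow) from a parsed document."""
    fp, fq = _unit_factors(doc.get("units"))
    gdoc = doc.get("globals", {})
    g = GlobalParams(
        rho=float(gdoc.get("rho", 1050.0)),
        mu=float(gdoc.get("mu", 4.0e-3)),
        xi=int(gdoc.get("xi", 9)),
        diastolic_pressure=float(gdoc.get("diastolic_pressure", 0.0)) * fp,
    )
    segments: Dict[str, ArterialSegment] = {}
    parents: Dict[str, Optional[str]] = {}
    for sdoc in doc.get("segments", []):
        seg = _segment_from_doc(sdoc, g.rho)
        if seg.name in segments:
            raise NetworkError(f"duplicate segment id '{seg.name}'")
        segments[seg.name] = seg
        parents[seg.name] = sdoc.get("parent")
    terminals: Dict[str, Union[Windkessel2, Windkessel3]] = {}
    for tdoc in doc.get("terminals", []):
        sid = tdoc.get("segment")
        if sid not in segments:
            raise NetworkError(f"terminal references unknown segment '{sid}'")
        p_out = float(tdoc.get("p_out", 0.0)) * fp
        c = float(tdoc["C"]) * fq / fp
        if "R" in tdoc:  # two-element terminal
            terminals[sid] = Windkessel2(R=float(tdoc["R"]) * fp / fq, C=c, p_out=p_out)
            continue
        r1 = tdoc.get("R1", "Z0")
        if isinstance(r1, str):
            if r1 != "Z0":
                raise NetworkError(f"terminal '{sid}': R1 must be a number or 'Z0'")
            seg = segments[sid]
            r1_val = float(seg.char_impedance(seg.length, g.rho))
        else:
            r1_val = float(r1) * fp / fq
        terminals[sid] = Windkessel3(R1=r1_val, R2=float(tdoc["R2"]) * fp / fq,
                                     C=c, p_out=p_out)
    net = ArterialNetwork(segments=segments, parents=parents, terminals=terminals,
                          globals=g)
    inflow = None
    if "inflow" in doc:
        idoc = doc["inflow"]
        if "csv" in idoc:
            inflow = read_inflow_csv(idoc["csv"])
        else:
            inflow = InflowWaveform(
                period=float(idoc["period"]),
                times=np.asarray(idoc["time"], float),
                flows=np.asarray(idoc["flow"], float) * fq,
            )
    return net, inflow


def network_to_dict(network: ArterialNetwork,
                    inflow: Optional[InflowWaveform] = None) -> dict:
    """Serialize a network (SI units) to a plain document."""
    g = network.globals
    doc: dict = {
        "globals": {
            "rho": g.rho,
            "mu": g.mu,
            "xi": g.xi,
            "diastolic_pressure": g.diastolic_pressure,
        },
        "segments": [],
        "terminals": [],
    }
    for name in sorted(network.segments):
        seg = network.segments[name]
        sdoc = {
            "id": name,
            "parent": network.parents[name],
            "length": float(seg.length),
            "radius_in": float(seg.radius_in),
            "radius_out": float(seg.radius_out),
            "beta_in": float(seg.beta_in),
            "beta_out": float(seg.beta_out),
        }
        if seg.trunk:
            sdoc["trunk"] = True
        doc["segments"].append(sdoc)
    for name in sorted(network.terminals):
        wk = network.terminals[name]
        if isinstance(wk, Windkessel3):
            doc["terminals"].append({"segment": name, "R1": float(wk.R1),
                                     "R2": float(wk.R2), "C": float(wk.C),
                                     "p_out": float(wk.p_out)})
        else:
            doc["terminals"].append({"segment": name, "R": float(wk.R),
                                     "C": float(wk.C), "p_out": float(wk.p_out)})
    if inflow is not None:
        doc["inflow"] = {
            "period": inflow.period,
            "time": [float(t) for t in inflow.times],
            "flow": [float(q) for q in inflow.flows],
        }
    return doc


def read_network(path) -> Tuple[ArterialNetwork, Optional[InflowWaveform]]:
    """Read a network document (JSON or YAML, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return network_from_dict(doc)


def write_network(network: ArterialNetwork, path,
                  inflow: Optional[InflowWaveform] = None) -> None:
    """Write a network document (JSON or YAML, by extension)."""
    path = Path(path)
    doc = network_to_dict(network, inflow)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def read_inflow_csv(path) -> InflowWaveform:
    """Read an inflow waveform CSV with columns ``time_s, flow_m3s``."""
    df = pd.read_csv(path)
    if not {"time_s", "flow_m3s"} <= set(df.columns):
        raise NetworkError("inflow CSV must have columns time_s, flow_m3s")
    t = df["time_s"].to_numpy(float)
    q = df["flow_m3s"].to_numpy(float)
    return InflowWaveform(period=float(t[-1] - t[0]), times=t - t[0], flows=q)


def write_inflow_csv(inflow: InflowWaveform, path) -> None:
    pd.DataFrame({"time_s": inflow.times, "flow_m3s": inflow.flows}).to_csv(
        path, index=False)


def write_waveforms_csv(waveforms: "WaveformSet", path) -> None:
    """Write probe waveforms as tidy CSV (time, site, pressure, flow, area)."""
    rows = []
    for site, rec in waveforms.sites.items():
        rows.append(pd.DataFrame({
            "time": waveforms.time,
            "site": site,
            "pressure": rec["P"],
            "flow": rec["Q"],
            "area": rec["A"],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_waveforms_csv(path) -> "WaveformSet":
    from .solver import WaveformSet
    df = pd.read_csv(path)
    sites = {}
    time = None
    for site, grp in df.groupby("site", sort=False):
        time = grp["time"].to_numpy(float)
        sites[str(site)] = {
            "P": grp["pressure"].to_numpy(float),
            "Q": grp["flow"].to_numpy(float),
            "A": grp["area"].to_numpy(float),
        }
    if time is None:
        raise NetworkError("waveform CSV contains no rows")
    return WaveformSet(time=time, sites=sites)


def write_fields_h5(path, waveforms: "WaveformSet",
                    fields: Optional[dict] = None) -> None:
    """Write probe waveforms (and optional dense space-time fields) to HDF5.

    ``fields`` maps segment name to a dict with keys ``x`` (cell centres),
    ``t`` (snapshot times) and 2D arrays ``A``, ``U``, ``P``.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("probes")
        grp.create_dataset("time", data=waveforms.time)
        for site, rec in waveforms.sites.items():
            sg = grp.create_group(site)
            for key in ("P", "Q", "A"):
                sg.create_dataset(key, data=rec[key])
        if fields:
            fg = h5.create_group("fields")
            for seg, rec in fields.items():
                sg = fg.create_group(seg)
                for key, val in rec.items():
                    sg.create_dataset(key, data=np.asarray(val))
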