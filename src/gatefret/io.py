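"""CSV/JSON readers and writers for the pipeline's tabular artefacts.

All tables go through pandas.  Round-trips preserve values to better than
1e-12 (floats are written with repr precision).  Titration files carry the
fixed-partner concentration as a ``# E0_nM = <value>`` header comment.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from gatefret._util import InvalidInputError
from gatefret.ensemble_assays import KineticTrace, TitrationSeries
from gatefret.fret_histograms import FretHistogram
from gatefret.trace_analysis import IntensityTrace

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file could not be parsed; carries the offending path."""


def _read_csv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip", **kwargs)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file")
        return pd.DataFrame()
    except Exception as exc:  # surface pandas' line diagnostics
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(trace: IntensityTrace, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(trace.n_frames),
        "time_s": trace.time,
        "donor_counts": trace.donor,
        "acceptor_counts": trace.acceptor,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace_csv(path) -> IntensityTrace:
    df = _read_csv(path)
    if df.empty:
        return IntensityTrace(time=np.empty(0), donor=np.empty(0), acceptor=np.empty(0))
    missing = {"time_s", "donor_counts", "acceptor_counts"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy()
    period = float(t[1] - t[0]) if len(t) > 1 else 0.22
    return IntensityTrace(time=t, donor=df["donor_counts"].to_numpy(),
                          acceptor=df["acceptor_counts"].to_numpy(),
                          frame_period=period)


def write_efficiencies_csv(efficiencies, path) -> None:
    pd.DataFrame({"efficiency": np.asarray(efficiencies, dtype=float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_efficiencies_csv(path) -> np.ndarray:
    df = _read_csv(path)
    if df.empty:
        return np.empty(0)
    if "efficiency" not in df.columns:
        raise ParseError(f"{path}: expected an 'efficiency' column")
    return df["efficiency"].to_numpy()


def write_histogram_csv(hist: FretHistogram, path) -> None:
    cols = {
        "bin_lo": hist.bin_edges[:-1],
        "bin_hi": hist.bin_edges[1:],
        "frequency": hist.frequencies,
    }
    if hist.sem is not None:
        cols["sem"] = hist.sem
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_histogram_csv(path, condition: str = "", replicate: int = 0) -> FretHistogram:
    df = _read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty histogram file")
    if not np.allclose(df["bin_lo"].to_numpy()[1:], df["bin_hi"].to_numpy()[:-1]):
        raise ParseError(f"{path}: bins are not contiguous")
    edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].to_numpy()[-1]]])
    sem = df["sem"].to_numpy() if "sem" in df.columns else None
    return FretHistogram(bin_edges=edges, frequencies=df["frequency"].to_numpy(),
                         condition=condition, replicate=replicate, sem=sem)


def write_titration_csv(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# E0_nM = {series.E0!r}\n")
        pd.DataFrame({"concentration_nM": series.s, "fluorescence": series.F}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT)


def read_titration_csv(path) -> TitrationSeries:
    e0 = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "E0_nM" in first:
        e0 = float(first.split("=")[1])
    df = _read_csv(path, comment="#")
    if df.empty:
        raise ParseError(f"{path}: empty titration file")
    if e0 is None:
        raise ParseError(f"{path}: missing '# E0_nM = ...' header")
    return TitrationSeries(s=df["concentration_nM"].to_numpy(),
                           F=df["fluorescence"].to_numpy(), E0=e0)


def write_decay_csv(trace: KineticTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "fluorescence": trace.F}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_decay_csv(path) -> KineticTrace:
    df = _read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty decay file")
    return KineticTrace(time=df["time_s"].to_numpy(),
                        F=df["fluorescence"].to_numpy())


def write_results_json(results: dict, path) -> None:
    Path(path).write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")


def read_results_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
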