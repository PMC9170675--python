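"""Reading posterior draws from text files and writing FBST reports.

Draw files are plain comma-separated values, one draw per row, with an
optional header (auto-detected: a first row that does not parse as numbers
is treated as column names).  Results serialize to JSON with full float
precision so they round-trip losslessly.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FBSTResult, Hypothesis
from .density import PosteriorDraws
from .errors import InvalidInputError


def read_draws(path: str | Path, column: str | int | None = None) -> PosteriorDraws:
    """Read a posterior draw vector from a CSV (or single-column text) file.

    Parameters
    ----------
    path
        File with one draw per row; multiple comma-separated columns are
        allowed, in which case ``column`` selects one.
    column
        Column name (when the file has a header) or zero-based index.
        Defaults to the only column, or column 0 of a headerless file.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"draws file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    has_header = not _all_numeric(first.strip().split(","))
    frame = pd.read_csv(path, header=0 if has_header else None, dtype=str)
    if not has_header:
        frame.columns = (
            ["param"] if frame.shape[1] == 1 else [f"col{i}" for i in range(frame.shape[1])]
        )
    if column is None:
        if frame.shape[1] != 1:
            raise InvalidInputError(
                f"file has {frame.shape[1]} columns "
                f"({', '.join(map(str, frame.columns))}); specify one"
            )
        column = frame.columns[0]
    if isinstance(column, int):
        if not 0 <= column < frame.shape[1]:
            raise InvalidInputError(
                f"column index {column} out of range for {frame.shape[1]} columns"
            )
        name = str(frame.columns[column])
        series = frame.iloc[:, column]
    else:
        if column not in frame.columns:
            raise InvalidInputError(
                f"column {column!r} not found; available: "
                f"{', '.join(map(str, frame.columns))}"
            )
        name = str(column)
        series = frame[column]
    checked = pd.to_numeric(series, errors="coerce")
    bad = checked.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InvalidInputError(
            f"non-numeric value {series.iloc[row]!r} in column {name!r}, "
            f"data row {row + 1}"
        )
    # convert via the correctly-rounded parser so files written with
    # shortest-round-trip reprs reload bit-for-bit
    values = np.array(
        [float(t) for t in series.dropna()], dtype=float
    )
    if values.size < 2:
        raise InvalidInputError(f"need at least 2 draws, file has {values.size}")
    return PosteriorDraws(values, name=name)


def _all_numeric(tokens: list[str]) -> bool:
    if not tokens or all(t == "" for t in tokens):
        return False
    for t in tokens:
        if t == "":
            continue
        try:
            float(t)
        except ValueError:
            return False
    return True


def summarize(result: FBSTResult) -> str:
    """Fixed-layout text report of an FBST result (4 decimal places)."""
    h = result.hypothesis
    lines = [
        "Full Bayesian Significance Test",
        "-" * 47,
        f"Null hypothesis        H0: {result.parameter_name} = {h.theta0:g}",
        f"Reference function     {result.reference_label}",
        f"Method                 {result.method}",
        f"dim(Theta) k = {h.dim_theta}, dim(null set) h = {h.dim_null}",
        "",
        f"e-value against H0: {result.ev_against:.4f}",
        f"e-value in favor of H0: {result.ev_favor:.4f}",
        f"standardized e-value sev(H0): {result.sev:.4f}",
        f"standardized e-value bar sev_bar(H0): {result.sev_bar:.4f}",
    ]
    if result.ev0 is not None:
        lines.append(f"asymptotic Bayesian p-value ev0: {result.ev0:.4f}")
    if result.pv0 is not None:
        lines.append(f"asymptotic frequentist p-value pv0: {result.pv0:.4f}")
    lines.append(f"supremum surprise at null s*: {result.s_star:.4f}")
    return "\n".join(lines)


def result_to_dict(result: FBSTResult) -> dict:
    """JSON-serializable dictionary of every FBSTResult field."""
    h = result.hypothesis
    return {
        "version": __version__,
        "parameter": result.parameter_name,
        "hypothesis": {
            "theta0": h.theta0,
            "dim_theta": h.dim_theta,
            "dim_null": h.dim_null,
        },
        "reference": result.reference_label,
        "method": result.method,
        "ev_against": result.ev_against,
        "ev_favor": result.ev_favor,
        "s_star": result.s_star,
        "sev_bar": result.sev_bar,
        "sev": result.sev,
        "ev0": result.ev0,
        "pv0": result.pv0,
        "ev_against_montecarlo": result.ev_against_montecarlo,
        "n_draws": result.n_draws,
        "bandwidth": result.bandwidth,
    }


def write_result(result: FBSTResult, path: str | Path) -> None:
    """Write an FBST result to a JSON file (lossless float round-trip).

    Floats are serialized with Python's shortest-round-trip repr, so
    :func:`read_result` reproduces every field bit-for-bit.  A ``created``
    timestamp is the only field that varies between identical runs.
    """
    payload = result_to_dict(result)
    payload["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_result(path: str | Path) -> FBSTResult:
    """Read back a result written by :func:`write_result`."""
    payload = json.loads(Path(path).read_text())
    h = payload["hypothesis"]
    return FBSTResult(
        ev_against=payload["ev_against"],
        ev_favor=payload["ev_favor"],
        s_star=payload["s_star"],
        sev_bar=payload["sev_bar"],
        sev=payload["sev"],
        hypothesis=Hypothesis(h["theta0"], h["dim_theta"], h["dim_null"]),
        reference_label=payload["reference"],
        method=payload["method"],
        ev0=payload["ev0"],
        pv0=payload["pv0"],
        ev_against_montecarlo=payload["ev_against_montecarlo"],
        n_draws=payload["n_draws"],
        bandwidth=payload["bandwidth"],
        parameter_name=payload["parameter"],
    )
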