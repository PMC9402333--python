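"""Plain-text I/O: signal CSV files and evaluation reports.

Signal CSV dialects accepted:

* one column  — amplitude only (sampling rate must be supplied);
* two columns — ``time_s,amplitude`` with uniform time steps (sampling
  rate inferred from the steps unless overridden).

An optional single header line is detected by failed float conversion.
Values are written with 17 significant digits so read(write(s)) is exact.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np

from .signal import Signal


class SignalParseError(ValueError):
    """Malformed signal CSV; the message names the offending line."""


def read_signal_csv(path, fs: float | None = None) -> Signal:
    """Read a signal CSV; ``fs`` overrides/supplies the sampling rate."""
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            rows.append((lineno, [c.strip() for c in raw.split(",")]))
    if not rows:
        raise SignalParseError(f"{path}: empty file")
    # header detection: first non-empty line that does not parse as floats
    start = 0
    try:
        [float(c) for c in rows[0][1]]
    except ValueError:
        start = 1
    if not rows[start:]:
        raise SignalParseError(f"{path}: no data rows")
    ncol = len(rows[start][1])
    if ncol not in (1, 2):
        raise SignalParseError(
            f"{path}, line {rows[start][0]}: expected 1 or 2 columns, got {ncol}"
        )
    data = np.empty((len(rows) - start, ncol))
    for i, (lineno, cells) in enumerate(rows[start:]):
        if len(cells) != ncol:
            raise SignalParseError(
                f"{path}, line {lineno}: ragged row ({len(cells)} columns, "
                f"expected {ncol})"
            )
        for j, cell in enumerate(cells):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise SignalParseError(
                    f"{path}, line {lineno}: non-numeric value {cell!r}"
                ) from None
    if ncol == 1:
        if fs is None:
            raise SignalParseError(
                f"{path}: single-column file requires an explicit sampling rate"
            )
        return Signal(samples=data[:, 0], fs=fs, name=path.stem)
    time, amp = data[:, 0], data[:, 1]
    dt = np.diff(time)
    if dt.size == 0 or not np.all(dt > 0):
        raise SignalParseError(f"{path}: time column must be strictly increasing")
    dt0 = float(np.median(dt))
    if np.max(np.abs(dt - dt0)) > 1e-6 * dt0:
        raise SignalParseError(f"{path}: non-uniform time steps (uniform required)")
    return Signal(samples=amp, fs=fs if fs is not None else 1.0 / dt0, name=path.stem)


def write_signal_csv(signal: Signal, path) -> None:
    """Write ``time_s,amplitude`` CSV at full float64 precision."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("time_s,amplitude\n")
    for t, a in zip(signal.times, signal.samples):
        buf.write(f"{t:.17g},{a:.17g}\n")
    path.write_text(buf.getvalue())


def write_report(result, path, format: str = "json") -> None:
    """Serialise an EvaluationResult.

    ``json``: one document embedding master seed, config snapshot, rows and
    aggregates (keys sorted — byte-identical for identical results).
    ``csv``: per-trial rows at ``path`` plus aggregates next to it with an
    ``_aggregates`` stem suffix.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "master_seed": result.master_seed,
            "config": result.config,
            "n_dropped": result.n_dropped,
            "rows": result.rows.to_dict(orient="records"),
            "aggregates": result.aggregates.to_dict(orient="records"),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    elif format == "csv":
        result.rows.to_csv(path, index=False)
        agg_path = path.with_name(path.stem + "_aggregates" + path.suffix)
        result.aggregates.to_csv(agg_path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")
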