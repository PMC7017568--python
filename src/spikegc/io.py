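"""Plain-text readers/writers and deterministic test fixtures.

All formats are UTF-8 text with Unix newlines and '.' decimal separators:

* adjacency / weight / decision matrices: whitespace-delimited, one row per
  line, '#' comment lines allowed (column-acts-row convention);
* binned series: CSV, first column = bin start time (ms), remaining columns
  = channels;
* spike rasters: two-column CSV (neuron_id, spike_time_ms).
"""

from __future__ import annotations

import json

import numpy as np

from .simulate import (
    BinnedSeries,
    ConnectionMatrix,
    NeuronParams,
    SpikeRaster,
    assign_weights,
    bin_spikes,
    generate_random_network,
    simulate,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_series",
    "write_series",
    "read_raster",
    "write_raster",
    "write_provenance",
    "FIXTURES",
    "make_fixture",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _parse_table(path, delimiter=None):
    """Parse a numeric table, skipping '#' comments; errors carry line numbers."""
    rows = []
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split() if delimiter is None else s.split(delimiter)
            try:
                row = [float(p) for p in parts if p != ""]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return np.asarray(rows)


def write_matrix(path, matrix, comment: str | None = None):
    """Write a matrix as whitespace-delimited text with optional '#' header."""
    m = np.asarray(matrix)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# column-acts-row convention: entry [i, j] = influence of "
                 "node j (column) on node i (row)\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for row in m:
            if np.issubdtype(m.dtype, np.integer):
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(format(v, ".12g") for v in row) + "\n")


def read_matrix(path) -> np.ndarray:
    """Read a whitespace/comma-delimited numeric matrix, '#' comments ignored."""
    return _parse_table(path)


def write_series(series: BinnedSeries, path):
    """Write a binned series as CSV: time_ms, then one column per channel."""
    t0 = np.arange(series.n_bins) * series.bin_width
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = ",".join(f"ch{c}" for c in series.channel_ids)
        fh.write(f"# time_ms,{cols}\n")
        for b in range(series.n_bins):
            vals = ",".join(str(int(v)) for v in series.data[b])
            fh.write(f"{format(t0[b], '.10g')},{vals}\n")


def read_series(path) -> BinnedSeries:
    """Read a binned series CSV written by :func:`write_series`."""
    table = _parse_table(path)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus at least one channel")
    times = table[:, 0]
    data = table[:, 1:]
    if len(times) > 1:
        widths = np.diff(times)
        bin_width = float(widths[0])
        if not np.allclose(widths, bin_width):
            raise ParseError(f"{path}: bin start times are not evenly spaced")
    else:
        bin_width = 10.0
    if np.allclose(data, np.round(data)):
        data = data.astype(np.int64)
    return BinnedSeries(data=data, bin_width=bin_width)


def write_raster(raster: SpikeRaster, path):
    """Write spikes as two-column CSV (neuron_id, spike_time_ms)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# neuron_id,spike_time_ms\n")
        fh.write(f"# duration_ms={format(raster.duration, '.10g')} "
                 f"dt_ms={format(raster.dt, '.10g')} n={raster.n}\n")
        for i, times in enumerate(raster.spike_times):
            for t in times:
                fh.write(f"{i},{format(t, '.10g')}\n")


def read_raster(path, n: int | None = None, duration: float | None = None,
                dt: float = 1.0) -> SpikeRaster:
    """Read a two-column spike CSV; infers n and duration if not given."""
    table = _parse_table(path)
    if table.shape[1] != 2:
        raise ParseError(f"{path}: expected two columns (neuron_id, spike_time_ms)")
    ids = table[:, 0].astype(int)
    times = table[:, 1]
    n = int(ids.max()) + 1 if n is None else n
    duration = float(times.max()) if duration is None else duration
    spike_times = tuple(np.sort(times[ids == i]) for i in range(n))
    return SpikeRaster(spike_times=spike_times, duration=duration, dt=dt)


def write_provenance(path, **fields):
    """Write a JSON provenance record next to an output artifact."""
    from . import __version__

    record = {"tool": "spikegc", "version": __version__, **fields}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
    return record


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _fixture_null2(seed):
    return ConnectionMatrix(b=np.zeros((2, 2), dtype=np.int8), connection_ratio=0.0, seed=seed)


def _fixture_chain3(seed):
    # chain 0 -> 1 -> 2 (column acts row): tests direct-vs-mediated influence
    b = np.zeros((3, 3), dtype=np.int8)
    b[1, 0] = 1
    b[2, 1] = 1
    return ConnectionMatrix(b=b, connection_ratio=b.mean(), seed=seed)


def _fixture_6node(seed):
    # 6 nodes, exactly 5 directed edges drawn at random (seeded)
    return generate_random_network(6, connection_ratio=5 / 30, seed=seed, exact_count=True)


FIXTURES = {
    "null2": _fixture_null2,
    "chain3": _fixture_chain3,
    "fig1-like-6node": _fixture_6node,
}


def make_fixture(name: str, seed: int = 0, duration: float = 60_000.0,
                 bin_width: float = 10.0, weight: float | None = None,
                 params: NeuronParams | None = None):
    """Deterministic small ground-truth network + simulated binned series.

    Registry: ``null2`` (2 unconnected channels), ``chain3`` (0 -> 1 -> 2
    chain, for separating direct from mediated influence) and
    ``fig1-like-6node`` (6 nodes, exactly 5 random directed edges).
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    conn = FIXTURES[name](seed)
    kw = {} if weight is None else {"weight": weight}
    raster = simulate(
        conn, weights=assign_weights(conn, **kw), params=params,
        duration=duration, seed=seed + 1,
    )
    return conn, bin_spikes(raster, bin_width=bin_width)
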