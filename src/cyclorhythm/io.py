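"""On-disk formats: delimited-text recordings, JSON annotations, estimates.

Recordings are delimited text in an OpenBCI-log-style dialect: ``#``
metadata lines (sampling rate, start time, units), a header row with
channel labels, one row per sample, optionally led by a time column.
Annotations, feature vectors and configurations are JSON.  All numeric
serialization uses shortest round-trip ``repr``, so write/read cycles
preserve values bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import AnnotationError, FormatError
from .estimators import MomentEstimate, PhaseGrid
from .preprocess import MultichannelRecording
from .rhythm import CycleZoneAnnotation
from .spectral_features import FeatureVector, SensitivityReport

__all__ = [
    "RecordingFileDialect",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
    "read_estimate",
    "write_estimate",
    "write_feature_vector",
    "read_feature_vector",
    "write_sensitivity_report",
]


@dataclass(frozen=True)
class RecordingFileDialect:
    """Column layout of a recording file.

    ``time_column`` controls whether the first column holds sample times;
    the sampling rate always comes from the metadata header (or the
    ``fs`` override on read).
    """

    delimiter: str = ","
    time_column: bool = True
    units: str = "uV"
    comment_prefix: str = "#"


DEFAULT_DIALECT = RecordingFileDialect()


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def write_recording(
    path, rec: MultichannelRecording, dialect: RecordingFileDialect = DEFAULT_DIALECT
) -> None:
    p = Path(path)
    d = dialect.delimiter
    lines = [
        f"{dialect.comment_prefix} cyclorhythm recording",
        f"{dialect.comment_prefix} fs_hz = {_fmt(rec.sampling_rate)}",
        f"{dialect.comment_prefix} t0_s = {_fmt(rec.t0)}",
        f"{dialect.comment_prefix} units = {rec.units}",
    ]
    header = list(rec.channel_labels)
    if dialect.time_column:
        header = ["time_s"] + header
    lines.append(d.join(header))
    times = rec.times
    for l in range(rec.n_samples):
        row = [_fmt(v) for v in rec.samples[:, l]]
        if dialect.time_column:
            row = [_fmt(times[l])] + row
        lines.append(d.join(row))
    p.write_text("\n".join(lines) + "\n")


def read_recording(
    path,
    dialect: RecordingFileDialect = DEFAULT_DIALECT,
    fs: float | None = None,
) -> MultichannelRecording:
    """Parse a recording file; metadata may be overridden by ``fs``.

    Raises :class:`FormatError` with the offending 1-based row number for
    ragged rows or non-numeric cells, and when no sampling rate is
    available.
    """
    p = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    n_cols = None
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(dialect.comment_prefix):
            body = line[len(dialect.comment_prefix):].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        cells = line.split(dialect.delimiter)
        if header is None:
            header = [c.strip() for c in cells]
            n_cols = len(header)
            continue
        if len(cells) != n_cols:
            raise FormatError(
                f"{p}: row {lineno} has {len(cells)} cells, expected {n_cols}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"{p}: row {lineno}: {exc}") from None
    if header is None or not rows:
        raise FormatError(f"{p}: no data rows found")

    data = np.array(rows)
    if dialect.time_column:
        labels = header[1:]
        times = data[:, 0]
        values = data[:, 1:].T
    else:
        labels = header
        times = None
        values = data.T
    if fs is None:
        if "fs_hz" in meta:
            fs = float(meta["fs_hz"])
        elif times is not None and times.size >= 2:
            fs = 1.0 / float(times[1] - times[0])
        else:
            raise FormatError(
                f"{p}: sampling rate missing (no 'fs_hz =' header, no time "
                f"column, and no fs override)"
            )
    t0 = float(meta.get("t0_s", times[0] if times is not None else 0.0))
    return MultichannelRecording(
        samples=values,
        sampling_rate=float(fs),
        channel_labels=tuple(labels),
        t0=t0,
        units=meta.get("units", dialect.units),
    )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def write_annotation(path, annotation: CycleZoneAnnotation) -> None:
    obj = {
        "boundaries": [float(x) for x in annotation.boundaries],
        "zones_per_cycle": annotation.zones_per_cycle,
        "units": "s",
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_annotation(path) -> CycleZoneAnnotation:
    p = Path(path)
    try:
        obj = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{p}: invalid JSON: {exc}") from None
    if not isinstance(obj, dict) or "boundaries" not in obj:
        raise FormatError(f"{p}: expected an object with a 'boundaries' list")
    if obj.get("zones_per_cycle", 2) != 2:
        raise AnnotationError(
            f"{p}: zones_per_cycle must be 2, got {obj.get('zones_per_cycle')}"
        )
    try:
        return CycleZoneAnnotation(boundaries=np.asarray(obj["boundaries"], dtype=float))
    except AnnotationError as exc:
        raise AnnotationError(f"{p}: {exc}") from None


# ---------------------------------------------------------------------------
# Estimates
# ---------------------------------------------------------------------------


def write_estimate(path, est: MomentEstimate) -> None:
    """Estimate as CSV with metadata header lines, full precision."""
    lines = [
        f"# kind = {est.kind}",
        f"# order = {est.order}",
        f"# channels = {','.join(str(c) for c in est.channels)}",
        f"# exponents = {','.join(str(r) for r in est.exponents)}",
        f"# M = {est.n_cycles}",
        f"# M1 = {est.m1 if est.m1 is not None else ''}",
        f"# zone = {est.grid.zone}",
        "# boundaries = " + ",".join(_fmt(x) for x in est.grid.annotation.boundaries),
        "phase_s,value",
    ]
    for t, v in zip(est.grid.times, est.values):
        lines.append(f"{_fmt(t)},{_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_estimate(path) -> MomentEstimate:
    p = Path(path)
    meta: dict[str, str] = {}
    times, values = [], []
    seen_header = False
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not seen_header:
            seen_header = True
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise FormatError(f"{p}: row {lineno} has {len(cells)} cells, expected 2")
        try:
            times.append(float(cells[0]))
            values.append(float(cells[1]))
        except ValueError as exc:
            raise FormatError(f"{p}: row {lineno}: {exc}") from None
    required = ("kind", "order", "channels", "M", "zone", "boundaries")
    missing = [k for k in required if k not in meta]
    if missing:
        raise FormatError(f"{p}: missing metadata lines: {missing}")
    ann = CycleZoneAnnotation(
        boundaries=np.array([float(x) for x in meta["boundaries"].split(",")])
    )
    grid = PhaseGrid(times=np.array(times), zone=meta["zone"], annotation=ann)
    exponents = tuple(
        int(r) for r in meta.get("exponents", meta["order"]).split(",")
    )
    return MomentEstimate(
        kind=meta["kind"],
        order=int(meta["order"]),
        channels=tuple(int(c) for c in meta["channels"].split(",")),
        exponents=exponents,
        grid=grid,
        values=np.array(values),
        n_cycles=int(meta["M"]),
        m1=int(meta["M1"]) if meta.get("M1") else None,
    )


# ---------------------------------------------------------------------------
# Features and reports
# ---------------------------------------------------------------------------


def write_feature_vector(path, fv: FeatureVector) -> None:
    obj = {
        "K": fv.k,
        "threshold": fv.threshold,
        "coefficients": [float(c) for c in fv.coefficients],
        "energy_captured": fv.energy_captured,
        "source": fv.source,
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_feature_vector(path) -> FeatureVector:
    p = Path(path)
    try:
        obj = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{p}: invalid JSON: {exc}") from None
    try:
        return FeatureVector(
            k=int(obj["K"]),
            coefficients=np.asarray(obj["coefficients"], dtype=float),
            energy_captured=float(obj["energy_captured"]),
            threshold=float(obj["threshold"]),
            source=obj.get("source", {}),
        )
    except KeyError as exc:
        raise FormatError(f"{p}: missing field {exc}") from None


def write_sensitivity_report(path, report: SensitivityReport) -> None:
    """Both MAD blocks side by side, mirroring the published table layout."""
    time = report.time_domain.add_prefix("time_mad:")
    spec = report.spectral.add_prefix("spectral_mad:")
    combined = time.join(spec)
    combined.index.name = "characteristic"
    combined.to_csv(Path(path))
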