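"""Cycle-aligned statistical estimation of moment functions.

Given a recording, its cycle/zone annotation and the fitted rhythm
function, each probabilistic characteristic is estimated on a *phase
grid* — a set of time points inside the first cycle — by averaging the
signal over the ensemble of aligned times ``t + T(t, n)``, ``n = 0..M-1``.
Because the rhythm map preserves the normalized position within a zone,
row ``n`` of the aligned ensemble draws from the same phase of cycle
``n + 1``.

Implemented characteristics and their normalizations (kept exactly as
the method defines them, including the 1/M vs 1/(M-1) asymmetry between
the dispersion and the second central moment):

- mean                      ``(1/M) * sum_n x_n(t)``
- dispersion                ``(1/M) * sum_n (x_n(t) - mean(t))^2``
- initial moment, order k   ``(1/M) * sum_n x_n(t)^k``
- central moment, order k   ``(1/(M-1)) * sum_n (x_n(t) - mean(t))^k``
- mixed initial, order p    ``(1/(M-M1+1)) * sum_{n=0}^{M-M1} prod_j x_{i_j}^{r_j}(t_j + T(t_j,n))``
- mixed central, order p    ``(1/(M-M1)) * sum_{n=0}^{M-M1} prod_j (x_{i_j}(t_j+T(t_j,n)) - mean_{i_j}(t_j))^{r_j}``

``M1`` is the number of leading cycles over which the lag arguments
``t_2..t_k`` range.  Mean values at shifted arguments use the cyclic
extension of the mean estimate (its own invariance under the fitted
rhythm), i.e. ``mean(t + T(t,n)) := mean(t)``.

Signal values at fractional sample times are linearly interpolated;
times within a relative tolerance of an exact sample snap to it, so
regular-rhythm alignment with an integer number of samples per cycle is
exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, ParameterError, ValidationError
from .preprocess import MultichannelRecording
from .rhythm import CycleZoneAnnotation, RhythmFunction

__all__ = [
    "PhaseGrid",
    "AlignedSampleMatrix",
    "MomentEstimate",
    "SamePhaseLag",
    "FixedLag",
    "zone_indicator",
    "zone_component",
    "zone_components",
    "align",
    "estimate_mean",
    "estimate_dispersion",
    "estimate_initial_moment",
    "estimate_central_moment",
    "estimate_mixed_initial",
    "estimate_mixed_central",
]

_ZONE_NAMES = ("zone1", "zone2", "full_cycle")

# aligned times within this fraction of a sample period of an exact sample
# are read directly (no interpolation)
_SNAP_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Phase grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseGrid:
    """Time points inside the first cycle at which estimates are evaluated.

    ``zone`` names the reference region: the passivity zone (``zone1``),
    the activity zone (``zone2``) or the whole first cycle
    (``full_cycle``).  All times must lie inside that region.
    """

    times: np.ndarray
    zone: str
    annotation: CycleZoneAnnotation

    def __post_init__(self) -> None:
        if self.zone not in _ZONE_NAMES:
            raise ValidationError(
                f"zone must be one of {_ZONE_NAMES}, got {self.zone!r}"
            )
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("phase grid must be a non-empty 1-D time array")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("phase-grid times must be strictly increasing")
        lo, hi = self.region()
        if t[0] < lo or t[-1] >= hi:
            raise ValidationError(
                f"phase-grid times must lie in [{lo}, {hi}) of cycle 1"
            )
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    def region(self) -> tuple[float, float]:
        """Half-open support of the reference region within cycle 1."""
        if self.zone == "zone1":
            return self.annotation.zone_interval(1, 1)
        if self.zone == "zone2":
            return self.annotation.zone_interval(1, 2)
        return self.annotation.cycle_interval(1)

    @property
    def size(self) -> int:
        return self.times.size

    @classmethod
    def from_recording(
        cls,
        rec: MultichannelRecording,
        annotation: CycleZoneAnnotation,
        zone: str = "full_cycle",
        max_points: int | None = None,
    ) -> "PhaseGrid":
        """Grid of the recording's own sample times inside the region.

        ``max_points`` optionally thins the grid to at most that many
        (evenly strided) points.
        """
        lo, hi = cls._region_for(annotation, zone)
        t = rec.times
        i0, i1 = np.searchsorted(t, [lo, hi], side="left")
        times = t[i0:i1]
        if times.size == 0:
            raise ValidationError(
                f"no recording samples fall inside {zone} of cycle 1 "
                f"([{lo}, {hi}))"
            )
        if max_points is not None and times.size > max_points:
            stride = int(np.ceil(times.size / max_points))
            times = times[::stride]
        return cls(times=times, zone=zone, annotation=annotation)

    @staticmethod
    def _region_for(annotation: CycleZoneAnnotation, zone: str) -> tuple[float, float]:
        if zone == "zone1":
            return annotation.zone_interval(1, 1)
        if zone == "zone2":
            return annotation.zone_interval(1, 2)
        if zone == "full_cycle":
            return annotation.cycle_interval(1)
        raise ValidationError(f"zone must be one of {_ZONE_NAMES}, got {zone!r}")


# ---------------------------------------------------------------------------
# Zone decomposition
# ---------------------------------------------------------------------------


def zone_indicator(
    annotation: CycleZoneAnnotation, cycle: int, zone: int, times
) -> np.ndarray:
    """Indicator of ``W[cycle, zone]`` evaluated at ``times`` (0/1 floats)."""
    start, end = annotation.zone_interval(cycle, zone)
    t = np.asarray(times, dtype=float)
    return ((t >= start) & (t < end)).astype(float)


def zone_component(
    rec: MultichannelRecording,
    annotation: CycleZoneAnnotation,
    channel: int,
    cycle: int,
    zone: int,
) -> np.ndarray:
    """Masked signal: the channel on ``W[cycle, zone]`` and zero elsewhere."""
    if not 0 <= channel < rec.n_channels:
        raise ParameterError(
            f"channel must be in 0..{rec.n_channels - 1}, got {channel}"
        )
    ind = zone_indicator(annotation, cycle, zone, rec.times)
    return rec.samples[channel] * ind


def zone_components(
    rec: MultichannelRecording,
    annotation: CycleZoneAnnotation,
    channel: int,
) -> dict[tuple[int, int], np.ndarray]:
    """All zone components ``(cycle, zone) -> masked signal``.

    Their sum reconstructs the channel exactly on the annotated support.
    """
    out = {}
    for m in range(1, annotation.cycle_count + 1):
        for k in (1, 2):
            out[(m, k)] = zone_component(rec, annotation, channel, m, k)
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedSampleMatrix:
    """Ensemble of cycle-aligned signal values.

    Entry ``(n, j)`` holds the channel's value at ``t_j + T(t_j, shifts[n])``;
    ``interpolated[n, j]`` marks entries read between samples (as opposed
    to snapping to an exact sample time).
    """

    channel: int
    grid: PhaseGrid
    shifts: tuple[int, ...]
    values: np.ndarray
    interpolated: np.ndarray


def _read_channel(
    rec: MultichannelRecording, channel: int, t: np.ndarray, context: str
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of one channel with exact-sample snapping.

    The recording covers ``[t0, t0 + L/fs)``.  Times past the last sample
    but overrunning that coverage by less than one sample period read the
    final sample (boundary rounding at fs); larger overruns raise
    :class:`AlignmentError`.
    """
    fs = rec.sampling_rate
    t_first = rec.t0
    t_end = rec.t0 + rec.n_samples / fs  # end of coverage
    if np.any(t < t_first - _SNAP_RTOL / fs) or np.any(t >= t_end + 1.0 / fs):
        bad = t[(t < t_first - _SNAP_RTOL / fs) | (t >= t_end + 1.0 / fs)][0]
        raise AlignmentError(
            f"{context}: time {bad!r} outside recording coverage "
            f"[{t_first}, {t_end}) plus one sample period"
        )
    pos = (t - rec.t0) * fs
    nearest = np.rint(pos)
    snap = np.abs(pos - nearest) <= _SNAP_RTOL
    vals = np.interp(t, rec.times, rec.samples[channel])
    idx = np.clip(nearest[snap].astype(int), 0, rec.n_samples - 1)
    vals[snap] = rec.samples[channel, idx]
    interpolated = ~snap
    # overrun of the final sample by < 1/fs clamps (np.interp already did)
    interpolated[pos > rec.n_samples - 1] = False
    return vals, interpolated


def align(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    grid: PhaseGrid,
    channel: int,
    shifts=None,
) -> AlignedSampleMatrix:
    """Aligned ensemble matrix of one channel over cycle shifts.

    By default ``shifts = 0..M-1`` so row ``n`` draws from cycle ``n+1``
    at the grid's phases; row 0 is the recording itself on the grid.
    """
    if not 0 <= channel < rec.n_channels:
        raise ParameterError(
            f"channel must be in 0..{rec.n_channels - 1}, got {channel}"
        )
    M = rf.annotation.cycle_count
    if shifts is None:
        shifts = range(M)
    shifts = tuple(int(n) for n in shifts)
    values = np.empty((len(shifts), grid.size))
    interp = np.empty((len(shifts), grid.size), dtype=bool)
    for row, n in enumerate(shifts):
        aligned = rf.shift_times(grid.times, n)
        values[row], interp[row] = _read_channel(
            rec, channel, np.atleast_1d(aligned), context=f"shift n={n}"
        )
    return AlignedSampleMatrix(
        channel=channel, grid=grid, shifts=shifts, values=values, interpolated=interp
    )


# ---------------------------------------------------------------------------
# Moment estimates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MomentEstimate:
    """A probabilistic-characteristic estimate on a phase grid.

    ``order`` is the total moment order ``p = sum(exponents)``; values
    carry units of microvolts**p.  ``lags`` and ``m1`` are populated for
    mixed kinds only.
    """

    kind: str
    order: int
    channels: tuple[int, ...]
    exponents: tuple[int, ...]
    grid: PhaseGrid
    values: np.ndarray
    n_cycles: int
    m1: int | None = None
    lags: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.size,):
            raise ValidationError(
                f"values shape {v.shape} does not match grid size {self.grid.size}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("estimate values must be finite")
        if self.order != sum(self.exponents):
            raise ValidationError("order must equal the sum of the exponents")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def units(self) -> str:
        return "uV" if self.order == 1 else f"uV^{self.order}"


def _ensemble(rec, rf, grid, channel) -> np.ndarray:
    return align(rec, rf, grid, channel).values


def estimate_mean(
    rec: MultichannelRecording, rf: RhythmFunction, grid: PhaseGrid, channel: int
) -> MomentEstimate:
    """Mathematical-expectation estimate: per-phase mean over cycles."""
    x = _ensemble(rec, rf, grid, channel)
    return MomentEstimate(
        kind="mean", order=1, channels=(channel,), exponents=(1,),
        grid=grid, values=x.mean(axis=0), n_cycles=x.shape[0],
    )


def estimate_dispersion(
    rec: MultichannelRecording, rf: RhythmFunction, grid: PhaseGrid, channel: int
) -> MomentEstimate:
    """Dispersion estimate with 1/M normalization."""
    x = _ensemble(rec, rf, grid, channel)
    d = np.mean((x - x.mean(axis=0)) ** 2, axis=0)
    return MomentEstimate(
        kind="dispersion", order=2, channels=(channel,), exponents=(2,),
        grid=grid, values=d, n_cycles=x.shape[0],
    )


def estimate_initial_moment(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    grid: PhaseGrid,
    channel: int,
    order: int,
) -> MomentEstimate:
    """Initial moment function of the given order, 1/M normalization."""
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    x = _ensemble(rec, rf, grid, channel)
    return MomentEstimate(
        kind="initial", order=order, channels=(channel,), exponents=(order,),
        grid=grid, values=np.mean(x**order, axis=0), n_cycles=x.shape[0],
    )


def estimate_central_moment(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    grid: PhaseGrid,
    channel: int,
    order: int,
) -> MomentEstimate:
    """Central moment function of the given order, 1/(M-1) normalization."""
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    x = _ensemble(rec, rf, grid, channel)
    M = x.shape[0]
    if M < 2:
        raise ParameterError(f"central moments need M >= 2 cycles, got {M}")
    c = np.sum((x - x.mean(axis=0)) ** order, axis=0) / (M - 1)
    return MomentEstimate(
        kind="central", order=order, channels=(channel,), exponents=(order,),
        grid=grid, values=c, n_cycles=M,
    )


# ---------------------------------------------------------------------------
# Mixed moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamePhaseLag:
    """Lag argument tracking the grid point: ``t_j = t_1 + T(t_1, cycles)``.

    Expresses same-phase arguments a fixed number of cycles ahead
    (``cycles=0`` means the same instant on another channel); the natural
    probe for inter-cycle and cross-channel dependence.
    """

    cycles: int

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ParameterError("SamePhaseLag cycles must be >= 0")


@dataclass(frozen=True)
class FixedLag:
    """Lag argument at a fixed offset (seconds) from the start of a cycle.

    Offsets are specified relative to the cycle start and mapped through
    the rhythm function, keeping configurations rhythm-independent.
    """

    cycle: int
    offset: float

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise ParameterError("FixedLag cycle must be >= 1")
        if self.offset < 0:
            raise ParameterError("FixedLag offset must be >= 0")


def _check_mixed_args(channels, exponents, lags, m1, M):
    channels = tuple(int(c) for c in channels)
    exponents = tuple(int(r) for r in exponents)
    lags = tuple(lags)
    if len(channels) != len(exponents):
        raise ParameterError("channels and exponents must have equal length")
    if len(lags) != len(channels) - 1:
        raise ParameterError(
            f"{len(channels)}-argument mixed moment needs {len(channels) - 1} "
            f"lags, got {len(lags)}"
        )
    if any(r < 1 for r in exponents):
        raise ParameterError("all exponents must be >= 1")
    if not 1 <= m1 < M:
        raise ParameterError(f"M1 must satisfy 1 <= M1 < M, got M1={m1}, M={M}")
    for lag in lags:
        if isinstance(lag, SamePhaseLag):
            if lag.cycles + 1 > m1:
                raise ParameterError(
                    f"SamePhaseLag({lag.cycles}) lies in cycle {lag.cycles + 1}, "
                    f"outside the first M1={m1} cycles"
                )
        elif isinstance(lag, FixedLag):
            if lag.cycle > m1:
                raise ParameterError(
                    f"FixedLag cycle {lag.cycle} outside the first M1={m1} cycles"
                )
        else:
            raise ParameterError(f"unknown lag specification {lag!r}")
    return channels, exponents, lags


def _fixed_lag_time(ann: CycleZoneAnnotation, lag: FixedLag) -> float:
    start, end = ann.cycle_interval(lag.cycle)
    t = start + lag.offset
    if not start <= t < end:
        raise ParameterError(
            f"FixedLag offset {lag.offset}s falls outside cycle {lag.cycle} "
            f"([{start}, {end}))"
        )
    return t


def _mixed_factors(rec, rf, grid, channels, lags, n_shifts, center):
    """Per-argument factor arrays of shape (n_shifts, P), means optionally removed.

    The first argument ranges over the grid; each lag argument is either
    grid-tracking (SamePhaseLag) or a per-shift scalar broadcast over the
    grid (FixedLag).  When ``center`` is set, the cyclically extended mean
    estimate of the matching channel/phase is subtracted.
    """
    ann = rf.annotation
    M = ann.cycle_count
    factors = []

    def mean_on_grid(ch):
        return align(rec, rf, grid, ch).values.mean(axis=0)

    # argument 1: the grid itself
    base = align(rec, rf, grid, channels[0], shifts=range(n_shifts)).values
    if center:
        base = base - mean_on_grid(channels[0])
    factors.append(base)

    for ch, lag in zip(channels[1:], lags):
        if isinstance(lag, SamePhaseLag):
            mat = align(
                rec, rf, grid, ch,
                shifts=range(lag.cycles, lag.cycles + n_shifts),
            ).values
            if center:
                mat = mat - mean_on_grid(ch)  # same phases as the grid
            factors.append(mat)
        else:
            t_lag = _fixed_lag_time(ann, lag)
            # cycle-1 equivalent phase of the lag argument
            s = rf.shift_times(t_lag, 1 - lag.cycle)
            aligned = np.array([rf.shift_times(s, n) for n in range(M)])
            vals, _ = _read_channel(rec, ch, aligned, context=f"lag {lag}")
            col = vals[lag.cycle - 1 : lag.cycle - 1 + n_shifts]
            if center:
                col = col - vals.mean()  # mean estimate at the lag's phase
            factors.append(col[:, np.newaxis])
    return factors


def estimate_mixed_initial(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    grid: PhaseGrid,
    channels,
    exponents,
    lags=(),
    m1: int = 1,
) -> MomentEstimate:
    """Mixed initial moment function across channels and lagged arguments.

    Sums the product of powered factors over shifts ``n = 0..M-M1``,
    normalized by ``1/(M-M1+1)``.  With a single argument and ``M1 = 1``
    this reduces exactly to the plain initial moment.
    """
    M = rf.annotation.cycle_count
    channels, exponents, lags = _check_mixed_args(channels, exponents, lags, m1, M)
    n_shifts = M - m1 + 1
    factors = _mixed_factors(rec, rf, grid, channels, lags, n_shifts, center=False)
    prod = np.ones((n_shifts, grid.size))
    for f, r in zip(factors, exponents):
        prod = prod * f**r
    values = prod.sum(axis=0) / (M - m1 + 1)
    return MomentEstimate(
        kind="mixed_initial", order=sum(exponents), channels=channels,
        exponents=exponents, grid=grid, values=values, n_cycles=M, m1=m1, lags=lags,
    )


def estimate_mixed_central(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    grid: PhaseGrid,
    channels,
    exponents,
    lags=(),
    m1: int = 1,
) -> MomentEstimate:
    """Mixed central moment function across channels and lagged arguments.

    As :func:`estimate_mixed_initial` but with the cyclically extended
    mean estimate removed from every factor, normalized by ``1/(M-M1)``.
    """
    M = rf.annotation.cycle_count
    channels, exponents, lags = _check_mixed_args(channels, exponents, lags, m1, M)
    if M - m1 < 1:
        raise ParameterError(f"mixed central moments need M - M1 >= 1, got {M - m1}")
    n_shifts = M - m1 + 1
    factors = _mixed_factors(rec, rf, grid, channels, lags, n_shifts, center=True)
    prod = np.ones((n_shifts, grid.size))
    for f, r in zip(factors, exponents):
        prod = prod * f**r
    values = prod.sum(axis=0) / (M - m1)
    return MomentEstimate(
        kind="mixed_central", order=sum(exponents), channels=channels,
        exponents=exponents, grid=grid, values=values, n_cycles=M, m1=m1, lags=lags,
    )
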