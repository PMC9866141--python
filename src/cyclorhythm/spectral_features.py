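"""Spectra of moment estimates, Bessel-inequality reduction, sensitivity.

Each characteristic estimate on a uniform phase grid is carried to the
frequency domain with a one-sided DFT.  By Bessel's inequality the energy
of any truncated Fourier expansion is bounded by the signal energy, so
keeping the smallest prefix of coefficients whose cumulative energy
reaches a threshold (95% by default) bounds the discarded energy and cuts
the feature dimension — in practice from the hundreds of phase-grid values
down to a few tens of spectral values.

Sensitivity of a characteristic to the operator's mental-control action is
scored by the mean absolute distance (MAD) between its activity-zone and
passivity-zone estimates, in the time domain and between their spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError
from .estimators import (
    MomentEstimate,
    PhaseGrid,
    estimate_central_moment,
    estimate_dispersion,
    estimate_initial_moment,
    estimate_mean,
)
from .preprocess import MultichannelRecording
from .rhythm import CycleZoneAnnotation, RhythmFunction

__all__ = [
    "SpectrumEstimate",
    "FeatureVector",
    "SensitivityReport",
    "DEFAULT_CHARACTERISTICS",
    "spectrum_of_estimate",
    "select_leading",
    "mean_absolute_distance",
    "sensitivity_report",
]


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided DFT magnitudes of an estimate, with per-bin energies.

    ``bin_energies`` are the one-sided-weighted squared magnitudes scaled
    so that their total equals the time-domain energy of the source
    values (Parseval); ``cumulative_energy_fraction`` is their normalized
    prefix sum.
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    bin_energies: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        e = np.asarray(self.bin_energies, dtype=float)
        if not (f.shape == m.shape == e.shape) or f.ndim != 1 or f.size == 0:
            raise ValidationError("frequencies/magnitudes/energies must be equal-length 1-D")
        if np.any(e < 0):
            raise ValidationError("bin energies must be non-negative")
        if e.sum() == 0:
            raise ValidationError("spectrum has zero total energy")
        for a in (f, m, e):
            a.setflags(write=False)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitudes", m)
        object.__setattr__(self, "bin_energies", e)

    @property
    def cumulative_energy_fraction(self) -> np.ndarray:
        c = np.cumsum(self.bin_energies)
        return c / c[-1]

    @property
    def n_bins(self) -> int:
        return self.frequencies.size


def spectrum_of_estimate(est: MomentEstimate, remove_mean: bool = False) -> SpectrumEstimate:
    """One-sided DFT magnitude spectrum of an estimate on a uniform grid.

    Bin energies use one-sided weights (DC and, for even lengths, the
    Nyquist bin count once; every other bin twice) so that the total
    equals the time-domain energy ``sum(x**2)``.  No window or detrend is
    applied; ``remove_mean`` optionally subtracts the mean first.
    """
    t = est.grid.times
    dt = np.diff(t)
    if t.size < 2:
        raise ValidationError("spectrum needs at least two grid points")
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12 * max(abs(t[0]), abs(t[-1]), 1.0)):
        raise ValidationError(
            "phase grid is not uniform; resample the estimate before the DFT"
        )
    x = est.values - est.values.mean() if remove_mean else est.values
    P = x.size
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(P, d=float(dt[0]))
    mags = np.abs(X)
    weights = np.full(mags.size, 2.0)
    weights[0] = 1.0
    if P % 2 == 0:
        weights[-1] = 1.0
    energies = weights * mags**2 / P
    return SpectrumEstimate(
        frequencies=freqs,
        magnitudes=mags,
        bin_energies=energies,
        source={
            "kind": est.kind,
            "order": est.order,
            "channels": list(est.channels),
            "zone": est.grid.zone,
        },
    )


# ---------------------------------------------------------------------------
# Bessel-inequality reduction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    """Leading spectral magnitudes capturing at least the energy threshold.

    ``k`` is minimal: the ``k-1`` prefix falls below the threshold.
    """

    k: int
    coefficients: np.ndarray
    energy_captured: float
    threshold: float
    source: dict = field(default_factory=dict)


def select_leading(spec: SpectrumEstimate, threshold: float = 0.95) -> FeatureVector:
    """Smallest prefix of spectral coefficients meeting the energy threshold."""
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    frac = spec.cumulative_energy_fraction
    k = int(np.argmax(frac >= threshold)) + 1
    return FeatureVector(
        k=k,
        coefficients=spec.magnitudes[:k].copy(),
        energy_captured=float(frac[k - 1]),
        threshold=threshold,
        source=dict(spec.source),
    )


# ---------------------------------------------------------------------------
# Mean absolute distance
# ---------------------------------------------------------------------------


def _resample_pair(a: MomentEstimate, b: MomentEstimate, L: int):
    grid = np.linspace(0.0, 1.0, L)
    out = []
    for est in (a, b):
        t = est.grid.times
        phase = (t - t[0]) / (t[-1] - t[0]) if t.size > 1 else np.zeros(1)
        out.append(np.interp(grid, phase, est.values))
    return out


def mean_absolute_distance(a, b, L: int | None = None) -> float:
    """Mean absolute distance between two same-kind estimates or spectra.

    Time-domain estimates are linearly resampled onto a common ``L``-point
    normalized-phase grid (default: the shorter length); spectra are
    compared per bin over the first ``L`` bins.  A pseudometric: symmetric,
    non-negative, zero on identical inputs, triangle inequality.
    """
    if isinstance(a, MomentEstimate) and isinstance(b, MomentEstimate):
        if (a.kind, a.order) != (b.kind, b.order):
            raise ParameterError(
                f"cannot compare {a.kind}/order {a.order} with {b.kind}/order {b.order}"
            )
        L = min(a.values.size, b.values.size) if L is None else int(L)
        if L < 2:
            raise ParameterError(f"need L >= 2 resampling points, got {L}")
        va, vb = _resample_pair(a, b, L)
        return float(np.mean(np.abs(va - vb)))
    if isinstance(a, SpectrumEstimate) and isinstance(b, SpectrumEstimate):
        ka = a.source.get("kind"), a.source.get("order")
        kb = b.source.get("kind"), b.source.get("order")
        if ka != kb:
            raise ParameterError(f"cannot compare spectra of {ka} with {kb}")
        L = min(a.n_bins, b.n_bins) if L is None else int(L)
        if L < 2 or L > min(a.n_bins, b.n_bins):
            raise ParameterError(f"L must be in 2..{min(a.n_bins, b.n_bins)}, got {L}")
        return float(np.mean(np.abs(a.magnitudes[:L] - b.magnitudes[:L])))
    raise ParameterError(
        f"operands must both be MomentEstimate or both SpectrumEstimate, "
        f"got {type(a).__name__} and {type(b).__name__}"
    )


# ---------------------------------------------------------------------------
# Sensitivity report
# ---------------------------------------------------------------------------

#: (label, kind, order) rows in table order: higher-order moments first.
DEFAULT_CHARACTERISTICS: tuple[tuple[str, str, int], ...] = (
    ("Initial moments of fourth order", "initial", 4),
    ("Central moment functions of fourth order", "central", 4),
    ("Initial moments of third order", "initial", 3),
    ("Initial moments of second order", "initial", 2),
    ("Variance", "dispersion", 2),
    ("Mathematical expectation", "mean", 1),
)


@dataclass(frozen=True)
class SensitivityReport:
    """Activity-vs-passivity MAD per characteristic (rows) and channel (columns).

    ``time_domain`` scores the estimates themselves (units microvolts**p
    per row); ``spectral`` scores their one-sided magnitude spectra.
    """

    time_domain: pd.DataFrame
    spectral: pd.DataFrame

    def __post_init__(self) -> None:
        if self.time_domain.shape != self.spectral.shape:
            raise ValidationError("time and spectral blocks must have equal shape")


def _one_estimate(rec, rf, grid, channel, kind, order):
    if kind == "mean":
        return estimate_mean(rec, rf, grid, channel)
    if kind == "dispersion":
        return estimate_dispersion(rec, rf, grid, channel)
    if kind == "initial":
        return estimate_initial_moment(rec, rf, grid, channel, order)
    if kind == "central":
        return estimate_central_moment(rec, rf, grid, channel, order)
    raise ParameterError(f"unknown characteristic kind {kind!r}")


def sensitivity_report(
    rec: MultichannelRecording,
    rf: RhythmFunction,
    annotation: CycleZoneAnnotation,
    channels=None,
    characteristics=DEFAULT_CHARACTERISTICS,
) -> SensitivityReport:
    """Zone-sensitivity scores for every characteristic and channel.

    For each characteristic the passivity-zone (zone 1) and activity-zone
    (zone 2) estimates are computed on the recording's own sample times,
    and the time-domain and spectral MADs between them fill one cell per
    channel.
    """
    if channels is None:
        channels = range(rec.n_channels)
    channels = [int(c) for c in channels]
    grid1 = PhaseGrid.from_recording(rec, annotation, "zone1")
    grid2 = PhaseGrid.from_recording(rec, annotation, "zone2")
    labels = [rec.channel_labels[c] for c in channels]
    rows = [lab for lab, _, _ in characteristics]
    tmat = np.zeros((len(characteristics), len(channels)))
    smat = np.zeros_like(tmat)
    for i, (_, kind, order) in enumerate(characteristics):
        for jc, ch in enumerate(channels):
            e1 = _one_estimate(rec, rf, grid1, ch, kind, order)
            e2 = _one_estimate(rec, rf, grid2, ch, kind, order)
            tmat[i, jc] = mean_absolute_distance(e1, e2)
            smat[i, jc] = mean_absolute_distance(
                spectrum_of_estimate(e1), spectrum_of_estimate(e2)
            )
    return SensitivityReport(
        time_domain=pd.DataFrame(tmat, index=rows, columns=labels),
        spectral=pd.DataFrame(smat, index=rows, columns=labels),
    )
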