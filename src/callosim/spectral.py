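"""Spectral analysis of simulated cortical output.

Power spectra are estimated with the modified-periodogram (Welch)
method: tapered, per-segment demeaned periodograms averaged across
heavily overlapping segments (default 1 s Hamming windows advanced in
0.01 s hops).  Event-related (de)synchronisation is quantified as the
relative band-power change against a pre-task baseline,

    ERD/ERS(%) = 100 * (P(t) - P_B) / P_B,

negative values marking desynchronisation (power loss) and positive
values synchronisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model import PopulationRates

__all__ = [
    "BandDefinition",
    "BANDS",
    "PsdEstimate",
    "BandPowerSeries",
    "ErdErsCurve",
    "psd",
    "peak_frequency",
    "band_power_timecourse",
    "erd_ers",
    "working_point",
]


@dataclass(frozen=True)
class BandDefinition:
    """Closed frequency band [f_lo, f_hi] in Hz."""

    label: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band limits [{self.f_lo}, {self.f_hi}]")


#: Beta sub-bands of the three column presets plus the low band that
#: dominates a fully inhibited column.
BANDS = {
    "LB": BandDefinition("LB", 14.0, 19.0),
    "MB": BandDefinition("MB", 20.0, 24.0),
    "HB": BandDefinition("HB", 25.0, 30.0),
    "low": BandDefinition("low", 2.0, 7.0),
}


@dataclass
class PsdEstimate:
    """One-sided PSD per channel; ``power`` has shape (n_freq, n_chan)."""

    frequencies: np.ndarray
    power: np.ndarray
    fs: float
    window_s: float
    hop_s: float
    taper: str


@dataclass
class BandPowerSeries:
    """Sliding-window band-integrated power, timestamped at window
    centres; ``power`` has shape (n_windows, n_chan)."""

    times: np.ndarray
    power: np.ndarray
    band: BandDefinition
    fs: float
    window_s: float
    hop_s: float


@dataclass
class ErdErsCurve:
    """Relative band-power change versus baseline, in percent."""

    times: np.ndarray
    percent: np.ndarray
    baseline_power: np.ndarray
    band: BandDefinition
    baseline_window: tuple[float, float]


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    if x.ndim == 2:
        return x, False
    raise ValueError("signal must be 1-D or 2-D (time, channels)")


def psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    hop_s: float = 0.01,
    taper: str = "hamming",
) -> PsdEstimate:
    """Welch/modified-periodogram PSD of ``x`` (time along axis 0).

    Segments of ``window_s`` seconds are tapered, demeaned and advanced
    by ``hop_s`` seconds; their periodograms are averaged.  Density units
    are signal^2 / Hz.
    """
    x2, _ = _as_2d(x)
    nper = round(window_s * fs)
    hop = max(1, round(hop_s * fs))
    if x2.shape[0] < nper:
        raise ValueError(
            f"signal too short for the window: {x2.shape[0]} < {nper} samples"
        )
    f, p = sps.welch(
        x2,
        fs=fs,
        window=taper,
        nperseg=nper,
        noverlap=nper - hop,
        detrend="constant",
        axis=0,
        scaling="density",
    )
    return PsdEstimate(
        frequencies=f, power=p, fs=fs, window_s=window_s, hop_s=hop_s, taper=taper
    )


def peak_frequency(
    est: PsdEstimate,
    band: BandDefinition | None = None,
    include_dc: bool = False,
) -> float | np.ndarray:
    """Frequency of maximum power density, optionally within a band.

    The zero-frequency bin is excluded by default (segments are demeaned,
    so it carries only residual trend, not an oscillation).  Ties break
    toward the lower frequency.  Returns a scalar for single-channel
    estimates, else one peak per channel.
    """
    f = est.frequencies
    mask = np.ones_like(f, dtype=bool)
    if not include_dc:
        mask &= f > 0
    if band is not None:
        mask &= (f >= band.f_lo) & (f <= band.f_hi)
    if not mask.any():
        raise ValueError("empty frequency band for this estimate")
    sub = est.power[mask]
    peaks = f[mask][np.argmax(sub, axis=0)]
    return float(peaks[0]) if est.power.shape[1] == 1 else peaks


def band_power_timecourse(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_s: float = 1.0,
    hop_s: float = 0.01,
    taper: str = "hamming",
) -> BandPowerSeries:
    """Sliding modified-periodogram power in ``band``.

    Each window is demeaned, tapered and Fourier transformed; the
    density is integrated over the band bins.  Windows are centred, so
    the series spans [window_s/2, T - window_s/2].
    """
    x2, single = _as_2d(x)
    if band.f_lo >= fs / 2:
        raise ValueError(f"band {band.label} lies above the Nyquist frequency")
    nper = round(window_s * fs)
    hop = max(1, round(hop_s * fs))
    if x2.shape[0] < nper:
        raise ValueError("signal shorter than one analysis window")
    n_win = (x2.shape[0] - nper) // hop + 1
    idx = np.arange(nper)[None, :] + hop * np.arange(n_win)[:, None]
    segs = x2[idx]  # (n_win, nper, n_chan)
    segs = segs - segs.mean(axis=1, keepdims=True)
    w = sps.get_window(taper, nper)
    spec = np.fft.rfft(segs * w[None, :, None], axis=1)
    # One-sided density with taper power normalisation (matches welch).
    dens = (np.abs(spec) ** 2) / (fs * (w**2).sum())
    dens[:, 1:-1] *= 2.0
    f = np.fft.rfftfreq(nper, 1.0 / fs)
    sel = (f >= band.f_lo) & (f <= band.f_hi)
    if not sel.any():
        raise ValueError("band contains no frequency bins at this resolution")
    df = f[1] - f[0]
    p = dens[:, sel].sum(axis=1) * df  # (n_win, n_chan)
    times = (np.arange(n_win) * hop + nper / 2) / fs
    return BandPowerSeries(
        times=times,
        power=p if not single else p,
        band=band,
        fs=fs,
        window_s=window_s,
        hop_s=hop_s,
    )


def erd_ers(
    P: BandPowerSeries, baseline_window: tuple[float, float] = (0.0, 4.0)
) -> ErdErsCurve:
    """Relative band-power change (percent) against the baseline mean.

    ``baseline_window`` is an interval on the trial clock; windows whose
    centres fall inside it (margin of half a window on each side so the
    baseline windows use only baseline samples) define P_B.
    """
    lo, hi = baseline_window
    half = P.window_s / 2
    mask = (P.times >= lo + half - 1e-9) & (P.times <= hi - half + 1e-9)
    if not mask.any():
        raise ValueError("baseline window not covered by the power series")
    pb = P.power[mask].mean(axis=0)
    if np.any(pb <= 0):
        raise ValueError("baseline power is zero; ERD/ERS undefined")
    return ErdErsCurve(
        times=P.times,
        percent=100.0 * (P.power - pb) / pb,
        baseline_power=pb,
        band=P.band,
        baseline_window=baseline_window,
    )


def working_point(
    times: np.ndarray,
    rates: PopulationRates,
    window: tuple[float, float] | None = None,
) -> PopulationRates:
    """Time-mean spike density of each population over ``window`` (s)."""
    times = np.asarray(times)
    if window is None:
        mask = np.ones_like(times, dtype=bool)
    else:
        mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("empty averaging window")

    def avg(x):
        return np.asarray(x)[mask].mean(axis=0)

    return PopulationRates(
        zp=avg(rates.zp), ze=avg(rates.ze), zs=avg(rates.zs), zf=avg(rates.zf)
    )
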