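"""Experiment suite: coupling sweeps, working-region classification,
motor-imagery trials and ERD/ERS maps.

The sweep experiments characterise how the transcallosal gain K shapes
the joint dynamics of the two columns.  Three working regions appear as
K grows: (1) both columns drift off the upper saturation of the rate
sigmoid (concave decline of the mean pyramidal rate), (2) both operate
in the linear region with strongly amplified, synchronised rhythms
(convex decline), and (3) a winner-take-all regime in which noise breaks
the left/right symmetry and one column is silenced while the other
returns to its uncoupled working point.  Because the winning side is
decided by noise, winner and loser are identified by sorting the
per-trial mean pyramidal rates, never by hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CouplingSpec, SimulationSpec, integrate_batch
from .spectral import (
    BANDS,
    BandDefinition,
    ErdErsCurve,
    band_power_timecourse,
    erd_ers,
    psd,
)
from .stimuli import ModulatingInputSpec, StimulusSpec

__all__ = [
    "K_PRESETS",
    "SweepResult",
    "RegionBoundaries",
    "TrialProtocolResult",
    "ErdErsMap",
    "k_sweep",
    "classify_regions",
    "run_trial_protocol",
    "erd_ers_map",
]

#: Per-band coupling gains used for the high- and low-amplitude ERD/ERS
#: demonstrations (K_H, K_L).
K_PRESETS = {"LB": (10.0, 26.0), "MB": (6.0, 24.0), "HB": (4.0, 13.0)}


def _trial_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent trial seeds (< 2**31) from one master."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class SweepResult:
    """Per-K statistics of the two-column model under driving noise only.

    ``mean_zp`` has shape (n_K, n_trials, 2) with the last axis sorted
    per trial as (loser, winner); ``psd_power`` has shape
    (n_K, n_freq, 2), trial-averaged, same (loser, winner) order.
    """

    band: str
    K_grid: np.ndarray
    mean_zp: np.ndarray
    frequencies: np.ndarray
    psd_power: np.ndarray
    n_trials: int
    master_seed: int

    @property
    def loser_zp(self) -> np.ndarray:
        return self.mean_zp[:, :, 0].mean(axis=1)

    @property
    def winner_zp(self) -> np.ndarray:
        return self.mean_zp[:, :, 1].mean(axis=1)


@dataclass
class RegionBoundaries:
    """Boundaries between the three working regions on the K axis.

    ``k_12`` marks the concave-to-convex inflection of the mean
    pyramidal rate versus K; ``k_23`` the onset of winner-take-all.
    ``open_*`` flags mark boundaries not found inside the grid (the
    grid edge is then reported).
    """

    band: str
    k_12: float
    k_23: float
    open_12: bool = False
    open_23: bool = False


def k_sweep(
    band: str = "LB",
    K_grid: np.ndarray | None = None,
    sim: SimulationSpec | None = None,
    n_trials: int = 5,
    coupling: CouplingSpec | None = None,
    stimuli: StimulusSpec | None = None,
) -> SweepResult:
    """Sweep the transcallosal gain with driving noise only.

    For every K, ``n_trials`` independently seeded 16 s trials are
    integrated; per trial the columns' time-mean pyramidal rates are
    sorted into (loser, winner) and the output spectra are averaged in
    the same order.  The reduced default grid (step 2, 5 trials) keeps a
    sweep near a minute; pass ``np.arange(0, 101)`` and ``n_trials=20``
    for the full-resolution experiment.
    """
    if K_grid is None:
        K_grid = np.arange(0.0, 101.0, 2.0)
    K_grid = np.asarray(K_grid, dtype=float)
    if np.any(np.diff(K_grid) <= 0):
        raise ValueError("K grid must be strictly increasing")
    sim = sim or SimulationSpec()
    coupling = coupling or CouplingSpec()
    stimuli = stimuli or StimulusSpec()
    if stimuli.modulation is not None:
        raise ValueError("k_sweep runs without a modulating input")

    n_K = len(K_grid)
    seeds = _trial_seeds(sim.master_seed, n_K * n_trials)
    K_values = np.repeat(K_grid, n_trials)
    trials = integrate_batch(
        (band, band), coupling, stimuli, sim, seeds=seeds, K_values=K_values
    )

    mean_zp = np.empty((n_K, n_trials, 2))
    freqs = None
    psd_power = None
    for j, tr in enumerate(trials):
        i, t = divmod(j, n_trials)
        mz = tr.zp.mean(axis=0)
        order = np.argsort(mz)  # loser first
        mean_zp[i, t] = mz[order]
        est = psd(tr.v_out[:, order], fs=sim.fs_out)
        if psd_power is None:
            freqs = est.frequencies
            psd_power = np.zeros((n_K, len(freqs), 2))
        psd_power[i] += est.power / n_trials
    return SweepResult(
        band=band,
        K_grid=K_grid,
        mean_zp=mean_zp,
        frequencies=freqs,
        psd_power=psd_power,
        n_trials=n_trials,
        master_seed=sim.master_seed,
    )


def classify_regions(
    sweep: SweepResult,
    collapse_thresh: float = 0.5,
    asym_thresh: float = 2.0,
    smooth_width: int = 5,
) -> RegionBoundaries:
    """Locate the working-region boundaries on a sweep.

    k_23 is the smallest K at which the trial-averaged winner/loser
    mean rates differ by more than ``asym_thresh`` pps or the loser
    falls below ``collapse_thresh`` pps.  k_12 is the inflection
    (concave to convex) of the column-averaged mean rate versus K,
    found as the first negative-to-positive sign change of the second
    difference after moving-average smoothing of width
    ``smooth_width``.
    """
    K = sweep.K_grid
    loser, winner = sweep.loser_zp, sweep.winner_zp

    split = (winner - loser > asym_thresh) | (loser < collapse_thresh)
    if split.any():
        k_23 = float(K[int(np.argmax(split))])
        open_23 = False
    else:
        k_23, open_23 = float(K[-1]), True

    mean_curve = 0.5 * (winner + loser)
    sym = mean_curve[K <= k_23] if not open_23 else mean_curve
    Ksym = K[: len(sym)]
    if smooth_width > 1 and len(sym) >= smooth_width:
        kernel = np.ones(smooth_width) / smooth_width
        pad = smooth_width // 2
        padded = np.concatenate([sym[:1].repeat(pad), sym, sym[-1:].repeat(pad)])
        sym = np.convolve(padded, kernel, mode="valid")
    d2 = np.diff(sym, 2)
    sign_change = (d2[:-1] < 0) & (d2[1:] >= 0)
    if sign_change.any():
        idx = int(np.argmax(sign_change)) + 2  # centre of the stencil
        k_12 = float(Ksym[min(idx, len(Ksym) - 1)])
        open_12 = False
    else:
        k_12, open_12 = float(Ksym[0]), True
    return RegionBoundaries(
        band=sweep.band, k_12=k_12, k_23=k_23, open_12=open_12, open_23=open_23
    )


@dataclass
class TrialProtocolResult:
    """Trial-averaged ERD/ERS time courses of the two columns for one
    coupling gain, left column receiving the modulating input."""

    band: str
    K: float
    n_trials: int
    left: ErdErsCurve
    right: ErdErsCurve
    master_seed: int


def _protocol_power(
    band: str,
    K: float,
    n_trials: int,
    sim: SimulationSpec,
    band_def: BandDefinition,
    hop_s: float,
    coupling: CouplingSpec,
    stimuli: StimulusSpec,
):
    """Trial-averaged band-power series (times, power[n_win, 2])."""
    seeds = _trial_seeds(sim.master_seed, n_trials)
    trials = integrate_batch(
        (band, band),
        CouplingSpec(
            K=K,
            split_p=coupling.split_p,
            split_f=coupling.split_f,
            delay_s=coupling.delay_s,
        ),
        stimuli,
        sim,
        seeds=seeds,
    )
    acc = None
    series = None
    for tr in trials:
        series = band_power_timecourse(tr.v_out, sim.fs_out, band_def, hop_s=hop_s)
        acc = series.power if acc is None else acc + series.power
    series.power = acc / n_trials
    return series


def run_trial_protocol(
    band: str = "LB",
    K: float | None = None,
    n_trials: int = 20,
    sim: SimulationSpec | None = None,
    band_def: BandDefinition | None = None,
    hop_s: float = 0.01,
    coupling: CouplingSpec | None = None,
    stimuli: StimulusSpec | None = None,
) -> TrialProtocolResult:
    """Simulate the 16 s motor-imagery protocol and average ERD/ERS.

    The modulating input is added to the pyramidal drive of the left
    column (imagery of the right hand).  Band power is computed per
    column in the column's own beta sub-band, averaged across trials,
    and converted to percent change against the 4 s baseline; averaging
    power before the ratio keeps the baseline-normalisation bias of the
    small trial count out of the curves.
    """
    if K is None:
        K = K_PRESETS[band][0]
    sim = sim or SimulationSpec()
    band_def = band_def or BANDS[band]
    coupling = coupling or CouplingSpec()
    stimuli = stimuli or StimulusSpec(modulation=ModulatingInputSpec())
    if stimuli.modulation is None:
        raise ValueError("the trial protocol needs a modulating input")
    bp = _protocol_power(band, K, n_trials, sim, band_def, hop_s, coupling, stimuli)
    base = (0.0, stimuli.modulation.baseline_s)
    curve = erd_ers(bp, baseline_window=base)
    left = ErdErsCurve(
        times=curve.times,
        percent=curve.percent[:, 0],
        baseline_power=curve.baseline_power[0],
        band=band_def,
        baseline_window=base,
    )
    right = ErdErsCurve(
        times=curve.times,
        percent=curve.percent[:, 1],
        baseline_power=curve.baseline_power[1],
        band=band_def,
        baseline_window=base,
    )
    return TrialProtocolResult(
        band=band,
        K=float(K),
        n_trials=n_trials,
        left=left,
        right=right,
        master_seed=sim.master_seed,
    )


@dataclass
class ErdErsMap:
    """ERD/ERS (%) as a function of K and trial time, per column.

    ``percent`` has shape (n_K, n_windows, 2) with columns (left,
    right); the left column receives the modulating input.
    """

    band: str
    K_grid: np.ndarray
    times: np.ndarray
    percent: np.ndarray
    n_trials: int
    master_seed: int


def erd_ers_map(
    band: str = "LB",
    K_grid: np.ndarray | None = None,
    n_trials: int = 5,
    sim: SimulationSpec | None = None,
    band_def: BandDefinition | None = None,
    hop_s: float = 0.01,
    coupling: CouplingSpec | None = None,
    stimuli: StimulusSpec | None = None,
) -> ErdErsMap:
    """Map trial-averaged ERD/ERS over a grid of coupling gains.

    Intended for K inside working regions 1-2 (below the winner-take-all
    onset), where the task-modulated dynamics stay bilateral.
    """
    sim = sim or SimulationSpec()
    band_def = band_def or BANDS[band]
    coupling = coupling or CouplingSpec()
    stimuli = stimuli or StimulusSpec(modulation=ModulatingInputSpec())
    if stimuli.modulation is None:
        raise ValueError("the ERD/ERS map needs a modulating input")
    if K_grid is None:
        K_grid = np.arange(0.0, 29.0, 4.0)
    K_grid = np.asarray(K_grid, dtype=float)
    rows = []
    times = None
    for i, K in enumerate(K_grid):
        sub = SimulationSpec(
            duration_s=sim.duration_s,
            dt_s=sim.dt_s,
            fs_out=sim.fs_out,
            warmup_s=sim.warmup_s,
            master_seed=sim.master_seed + i,
            noise_scaling=sim.noise_scaling,
        )
        bp = _protocol_power(
            band, float(K), n_trials, sub, band_def, hop_s, coupling, stimuli
        )
        curve = erd_ers(bp, baseline_window=(0.0, stimuli.modulation.baseline_s))
        rows.append(curve.percent)
        times = curve.times
    return ErdErsMap(
        band=band,
        K_grid=K_grid,
        times=times,
        percent=np.stack(rows),
        n_trials=n_trials,
        master_seed=sim.master_seed,
    )
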