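"""External inputs: stochastic driving noise and the task-related
modulating input.

Each column is driven by two Gaussian white-noise inputs, one exciting
the pyramidal population (mean 40 pps) and one exciting the fast
inhibitory interneurons (mean 3 pps, hence a net inhibitory effect).
A motor-imagery-like task is emulated by a smoothed trapezoid added to
the pyramidal input of the column contralateral to the imagined hand
(the left column for right-hand imagery): 4 s baseline, 2 s raised-cosine
rise, 4 s plateau at 100 pps, 2 s fall, 4 s rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSpec",
    "ModulatingInputSpec",
    "StimulusSpec",
    "noise_sample",
    "modulating_value",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian driving-noise statistics for one target population.

    ``sd`` is interpreted as the intensity of continuous-time white
    noise: the integrator draws per-step samples with standard deviation
    ``sd / sqrt(dt)`` (Euler-Maruyama convention), so the statistics of
    the simulated trajectories do not depend on the step size.
    ``noise_sample`` itself returns plain N(mean, sd) draws.
    """

    mean: float = 40.0
    sd: float = 1.0
    target: str = "pyramidal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.target not in ("pyramidal", "fast"):
            raise ValueError(f"unknown noise target {self.target!r}")


@dataclass(frozen=True)
class ModulatingInputSpec:
    """Smoothed-trapezoid task input (all durations in seconds, amplitude
    in pps).  Defaults give the 16 s trial: 4 baseline + 2 rise + 4
    plateau + 2 fall + 4 rest, plateau at 100 pps."""

    baseline_s: float = 4.0
    rise_s: float = 2.0
    plateau_s: float = 4.0
    plateau_amp: float = 100.0
    fall_s: float = 2.0
    rest_s: float = 4.0
    target_column: str = "left"

    def __post_init__(self) -> None:
        for name in ("baseline_s", "rise_s", "plateau_s", "fall_s", "rest_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.plateau_amp < 0:
            raise ValueError("plateau amplitude must be non-negative")
        if self.target_column not in ("left", "right"):
            raise ValueError(f"target_column must be 'left' or 'right'")

    @property
    def total_s(self) -> float:
        return (
            self.baseline_s + self.rise_s + self.plateau_s + self.fall_s + self.rest_s
        )


@dataclass(frozen=True)
class StimulusSpec:
    """Complete stimulus description shared by both columns: pyramidal
    and fast-interneuron noise plus an optional modulating input."""

    noise_p: NoiseSpec = field(default_factory=lambda: NoiseSpec(mean=40.0, sd=1.0, target="pyramidal"))
    noise_f: NoiseSpec = field(default_factory=lambda: NoiseSpec(mean=3.0, sd=1.0, target="fast"))
    modulation: ModulatingInputSpec | None = None


def noise_sample(
    spec: NoiseSpec, n_steps: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n_steps`` i.i.d. Gaussian samples with the spec's mean/sd.

    Reproducible: with ``rng=None`` the stream is seeded from
    ``spec.seed``, so the same spec yields the same sequence.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.normal(spec.mean, spec.sd, size=n_steps)


def modulating_value(t, spec: ModulatingInputSpec = ModulatingInputSpec()):
    """Evaluate the smoothed trapezoid at trial time ``t`` (s).

    Zero during baseline and rest, ``plateau_amp`` on the plateau, and
    raised-cosine (half-Hann) ramps in between, making the waveform
    continuously differentiable at every segment join.  ``t`` may be a
    scalar or array; values outside [0, total] raise ``ValueError``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.total_s):
        raise ValueError(f"t outside the trial interval [0, {spec.total_s}]")
    t0 = spec.baseline_s
    t1 = t0 + spec.rise_s
    t2 = t1 + spec.plateau_s
    t3 = t2 + spec.fall_s
    out = np.zeros_like(t)
    if spec.rise_s > 0:
        m = (t >= t0) & (t < t1)
        out = np.where(
            m, spec.plateau_amp * 0.5 * (1 - np.cos(np.pi * (t - t0) / spec.rise_s)), out
        )
    m = (t >= t1) & (t < t2)
    out = np.where(m, spec.plateau_amp, out)
    if spec.fall_s > 0:
        m = (t >= t2) & (t < t3)
        out = np.where(
            m, spec.plateau_amp * 0.5 * (1 + np.cos(np.pi * (t - t2) / spec.fall_s)), out
        )
    return out if out.ndim else float(out)
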