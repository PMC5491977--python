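"""Stochastic integration of one or two delay-coupled cortical columns.

Two columns (left and right sensorimotor areas) interact through delayed
excitatory projections that originate from the pyramidal population of
one column and target the pyramidal population (fraction ``split_p``,
default 0.3) and the fast inhibitory interneurons (``split_f``, default
0.7) of the other, with conduction delay T = 13 ms:

    u_i(t) = n_i(t) + K_i * zp_other(t - T),        i in {p, f},
    K_p = split_p * K,   K_f = split_f * K.

Numerics
--------
The linear second-order synaptic kernels are advanced with their exact
zero-order-hold discretisation (matrix exponential of the critically
damped pair), with the nonlinear drives and the noise held constant over
each step of length ``dt`` (default 1e-4 s).  Driving noise follows the
Euler-Maruyama convention: a ``NoiseSpec`` with intensity ``sd`` is
realised as per-step deviates of standard deviation ``sd / sqrt(dt)``,
making trajectory statistics independent of the step size.  Output is
decimated to ``fs_out`` (default 100 Hz) by direct subsampling.

Column order is ``(left, right)``; the modulating input targets the
column named in its spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import root

from .model import (
    ColumnParams,
    ColumnState,
    MembranePotentials,
    PopulationRates,
    column_preset,
    membrane_potentials,
    population_rates,
    sigmoid,
)
from .stimuli import StimulusSpec, modulating_value

__all__ = [
    "CouplingSpec",
    "SimulationSpec",
    "TrialResult",
    "FixedPoint",
    "coupled_input",
    "integrate",
    "integrate_batch",
    "fixed_point",
]

COLUMN_NAMES = ("left", "right")

# Noise-stream order per run: (left, pyramidal), (left, fast),
# (right, pyramidal), (right, fast).
_N_STREAMS = 4
_NOISE_CHUNK = 10_000


@dataclass(frozen=True)
class CouplingSpec:
    """Transcallosal coupling: global gain K split 30/70 between
    pyramidal and fast-inhibitory targets, delay T in seconds."""

    K: float = 0.0
    split_p: float = 0.3
    split_f: float = 0.7
    delay_s: float = 0.013

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if abs(self.split_p + self.split_f - 1.0) > 1e-9:
            raise ValueError(
                f"split_p + split_f must equal 1, got {self.split_p + self.split_f}"
            )
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")

    @property
    def Kp(self) -> float:
        return self.split_p * self.K

    @property
    def Kf(self) -> float:
        return self.split_f * self.K


@dataclass(frozen=True)
class SimulationSpec:
    """Trial timing, integration step, output rate and master seed.

    ``warmup_s`` seconds are integrated before the trial proper and
    discarded, so the zero initial state has relaxed to the stochastic
    steady state before t = 0.
    """

    duration_s: float = 16.0
    dt_s: float = 1e-4
    fs_out: float = 100.0
    warmup_s: float = 2.0
    master_seed: int = 0
    noise_scaling: str = "intensity"  # or "per-step"

    def __post_init__(self) -> None:
        if self.dt_s > 1e-3:
            raise ValueError("dt must be <= 1e-3 s")
        decim = 1.0 / (self.fs_out * self.dt_s)
        if abs(decim - round(decim)) > 1e-9:
            raise ValueError("fs_out must divide 1/dt evenly")
        if self.duration_s <= 0 or self.warmup_s < 0:
            raise ValueError("durations must be positive")
        if self.noise_scaling not in ("intensity", "per-step"):
            raise ValueError("noise_scaling must be 'intensity' or 'per-step'")

    @property
    def decimation(self) -> int:
        return round(1.0 / (self.fs_out * self.dt_s))

    @property
    def n_steps(self) -> int:
        return round((self.duration_s + self.warmup_s) / self.dt_s)

    @property
    def warmup_steps(self) -> int:
        return round(self.warmup_s / self.dt_s)


@dataclass
class TrialResult:
    """Sampled output of one simulated trial.

    ``v_out`` and the rate series have shape (n_samples, n_columns) with
    column order (left, right); ``states``, when kept, has shape
    (n_samples, n_columns, 10) in ``STATE_FIELDS`` order.
    """

    time: np.ndarray
    v_out: np.ndarray
    zp: np.ndarray
    ze: np.ndarray
    zs: np.ndarray
    zf: np.ndarray
    columns: tuple[ColumnParams, ...]
    coupling: CouplingSpec
    stimulus: StimulusSpec
    sim: SimulationSpec
    seed: int
    stream_seeds: tuple[int, ...]
    states: np.ndarray | None = None
    inputs_f: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return self.v_out.shape[1]

    def mean_rates(self, window: tuple[float, float] | None = None) -> PopulationRates:
        """Time-mean spike densities per column over ``window`` (s)."""
        if window is None:
            mask = slice(None)
        else:
            mask = (self.time >= window[0]) & (self.time <= window[1])
        return PopulationRates(
            zp=self.zp[mask].mean(axis=0),
            ze=self.ze[mask].mean(axis=0),
            zs=self.zs[mask].mean(axis=0),
            zf=self.zf[mask].mean(axis=0),
        )


def coupled_input(n_i, K_i: float, zp_delayed):
    """External-plus-transcallosal input ``u_i = n_i + K_i zp(t - T)``.

    Before one delay has elapsed the delayed rate is the history
    pre-fill value (zero by default), so ``u_i = n_i`` there.
    """
    if np.any(np.asarray(K_i) < 0):
        raise ValueError("coupling gain must be non-negative")
    return np.asarray(n_i) + np.asarray(K_i) * np.asarray(zp_delayed)


def _as_columns(
    columns: ColumnParams | str | Sequence[ColumnParams | str],
) -> tuple[ColumnParams, ...]:
    if isinstance(columns, (ColumnParams, str)):
        columns = (columns,)
    out = tuple(column_preset(c) if isinstance(c, str) else c for c in columns)
    if len(out) not in (1, 2):
        raise ValueError("only one or two columns are supported")
    return out


def _kernel_coeffs(omega: float, G: float, dt: float):
    """Exact ZOH propagator of y'' = G w D - 2 w y' - w^2 y for constant D."""
    ed = np.exp(-omega * dt)
    return (
        ed * (1.0 + omega * dt),  # E11
        ed * dt,  # E12
        -(omega**2) * dt * ed,  # E21
        ed * (1.0 - omega * dt),  # E22
        G / omega,  # steady-state factor: y_ss = (G/w) D
    )


class _Kernel:
    __slots__ = ("E11", "E12", "E21", "E22", "S")

    def __init__(self, omega: float, G: float, dt: float):
        self.E11, self.E12, self.E21, self.E22, self.S = _kernel_coeffs(omega, G, dt)

    def step(self, y, x, drive):
        ys = self.S * drive
        dy = y - ys
        return ys + self.E11 * dy + self.E12 * x, self.E21 * dy + self.E22 * x


def integrate_batch(
    columns: ColumnParams | str | Sequence[ColumnParams | str],
    coupling: CouplingSpec,
    stimuli: StimulusSpec,
    sim: SimulationSpec,
    seeds: Sequence[int],
    K_values: Sequence[float] | None = None,
    keep_states: bool = False,
    keep_inputs: bool = False,
    initial_state: ColumnState | Sequence[ColumnState] | None = None,
) -> list[TrialResult]:
    """Integrate many independently seeded trials in one vectorised pass.

    All trials share the column parameters and specs; ``K_values`` may
    give one coupling gain per trial (for parameter sweeps), otherwise
    ``coupling.K`` applies to every trial.  Each trial's four noise
    streams are spawned from its own master seed, so results are
    bit-identical whether a trial is run alone or inside a batch.
    """
    cols = _as_columns(columns)
    ncols = len(cols)
    n = len(seeds)
    if n == 0:
        return []
    if K_values is None:
        K_arr = np.full(n, coupling.K, dtype=float)
    else:
        K_arr = np.asarray(K_values, dtype=float)
        if K_arr.shape != (n,):
            raise ValueError("K_values must have one entry per seed")
    if ncols == 1 and np.any(K_arr != 0.0):
        raise ValueError("a single column must be uncoupled (K = 0)")

    dt = sim.dt_s
    n_steps = sim.n_steps
    decim = sim.decimation
    warm = sim.warmup_steps
    n_out = round(sim.duration_s * sim.fs_out)
    D = max(1, round(coupling.delay_s / dt))

    Kp = (coupling.split_p * K_arr)[:, None]
    Kf = (coupling.split_f * K_arr)[:, None]

    # Per-band kernels (shared across the batch: one band per call).
    for c in cols[1:]:
        if (c.kernel_e, c.kernel_s, c.kernel_f, c.conn, c.sigmoid) != (
            cols[0].kernel_e,
            cols[0].kernel_s,
            cols[0].kernel_f,
            cols[0].conn,
            cols[0].sigmoid,
        ):
            raise ValueError("both columns must share one parameter set per batch")
    p0 = cols[0]
    ker_e = _Kernel(p0.kernel_e.omega, p0.kernel_e.G, dt)
    ker_s = _Kernel(p0.kernel_s.omega, p0.kernel_s.G, dt)
    ker_f = _Kernel(p0.kernel_f.omega, p0.kernel_f.G, dt)
    conn, sig_p = p0.conn, p0.sigmoid

    # Noise: four streams per trial, spawned from the trial's master seed.
    # A seed entry may also be an explicit 4-tuple of per-stream seeds in
    # (left-p, left-f, right-p, right-f) order, which makes the left/right
    # symmetry of the model directly testable by swapping column pairs.
    stream_seeds = []
    gens = []
    for s in seeds:
        if isinstance(s, (tuple, list, np.ndarray)):
            if len(s) != _N_STREAMS:
                raise ValueError(f"explicit stream seeds need {_N_STREAMS} entries")
            children = [np.random.SeedSequence(int(x)) for x in s]
        else:
            children = np.random.SeedSequence(int(s)).spawn(_N_STREAMS)
        gens.append([np.random.Generator(np.random.PCG64(c)) for c in children])
        stream_seeds.append(tuple(int(c.generate_state(1)[0]) for c in children))
    if sim.noise_scaling == "intensity":
        scale = 1.0 / np.sqrt(dt)
    else:
        scale = 1.0
    sd_p = stimuli.noise_p.sd * scale
    sd_f = stimuli.noise_f.sd * scale
    m_p, m_f = stimuli.noise_p.mean, stimuli.noise_f.mean

    # Modulating input, evaluated once per step on the trial clock.
    mod = stimuli.modulation
    if mod is not None:
        t_trial = (np.arange(n_steps) - warm) * dt
        mod_vals = np.zeros(n_steps)
        inside = (t_trial >= 0) & (t_trial <= mod.total_s)
        mod_vals[inside] = modulating_value(t_trial[inside], mod)
        mod_col = COLUMN_NAMES.index(mod.target_column)
        if mod_col >= ncols:
            raise ValueError("modulation targets a column that is not simulated")
    else:
        mod_vals = None
        mod_col = 0

    shape = (n, ncols)
    if initial_state is None:
        init = np.zeros((ncols, 10))
    elif isinstance(initial_state, ColumnState):
        init = np.broadcast_to(initial_state.as_array(), (ncols, 10))
    else:
        init = np.stack([st.as_array() for st in initial_state])
        if init.shape != (ncols, 10):
            raise ValueError("need one initial ColumnState per column")
    yp, xp, ye, xe, ys, xs, yf, xf, yl, xl = (
        np.broadcast_to(init[:, i], shape).copy() for i in range(10)
    )
    buf = np.zeros((D, n, ncols))

    out_v = np.empty((n_out, n, ncols))
    out_z = {k: np.empty((n_out, n, ncols)) for k in ("zp", "ze", "zs", "zf")}
    out_states = np.empty((n_out, n, ncols, 10)) if keep_states else None
    out_uf = np.empty((n_out, n, ncols)) if keep_inputs else None

    noise_p = np.empty((_NOISE_CHUNK, n, ncols))
    noise_f = np.empty((_NOISE_CHUNK, n, ncols))

    for step in range(n_steps):
        c = step % _NOISE_CHUNK
        if c == 0:
            m = min(_NOISE_CHUNK, n_steps - step)
            for i, g in enumerate(gens):
                for col in range(ncols):
                    noise_p[:m, i, col] = g[2 * col].normal(m_p, sd_p, m)
                    noise_f[:m, i, col] = g[2 * col + 1].normal(m_f, sd_f, m)
            if not (
                np.isfinite(yp).all()
                and np.isfinite(yf).all()
                and np.isfinite(yl).all()
            ):
                raise FloatingPointError(
                    f"numerical blow-up: non-finite state at step {step} "
                    f"(t = {step * dt - sim.warmup_s:.4f} s)"
                )

        vp = conn.Cpe * ye - conn.Cps * ys - conn.Cpf * yf
        ve = conn.Cep * yp
        vs = conn.Csp * yp
        vf = conn.Cfp * yp - conn.Cfs * ys + yl
        zp = sigmoid(vp, sig_p)
        ze = sigmoid(ve, sig_p)
        zs = sigmoid(vs, sig_p)
        zf = sigmoid(vf, sig_p)

        slot = step % D
        zp_del = buf[slot][:, ::-1] if ncols == 2 else 0.0
        u_p = noise_p[c] + Kp * zp_del
        u_f = noise_f[c] + Kf * zp_del
        if mod_vals is not None and mod_vals[step] != 0.0:
            u_p[:, mod_col] += mod_vals[step]
        buf[slot] = zp

        k = step - warm
        if k >= 0 and k % decim == 0 and (j := k // decim) < n_out:
            out_v[j] = vp
            out_z["zp"][j] = zp
            out_z["ze"][j] = ze
            out_z["zs"][j] = zs
            out_z["zf"][j] = zf
            if out_states is not None:
                out_states[j] = np.stack(
                    (yp, xp, ye, xe, ys, xs, yf, xf, yl, xl), axis=-1
                )
            if out_uf is not None:
                out_uf[j] = u_f

        yp, xp = ker_e.step(yp, xp, zp)
        ye, xe = ker_e.step(ye, xe, ze + u_p / conn.Cpe)
        ys, xs = ker_s.step(ys, xs, zs)
        yf, xf = ker_f.step(yf, xf, zf)
        yl, xl = ker_e.step(yl, xl, u_f)

    time = np.arange(n_out) / sim.fs_out
    results = []
    for i, s in enumerate(seeds):
        results.append(
            TrialResult(
                time=time,
                v_out=out_v[:, i].copy(),
                zp=out_z["zp"][:, i].copy(),
                ze=out_z["ze"][:, i].copy(),
                zs=out_z["zs"][:, i].copy(),
                zf=out_z["zf"][:, i].copy(),
                columns=cols,
                coupling=CouplingSpec(
                    K=float(K_arr[i]),
                    split_p=coupling.split_p,
                    split_f=coupling.split_f,
                    delay_s=coupling.delay_s,
                ),
                stimulus=stimuli,
                sim=sim,
                seed=int(s) if not isinstance(s, (tuple, list, np.ndarray)) else -1,
                stream_seeds=stream_seeds[i],
                states=out_states[:, i].copy() if out_states is not None else None,
                inputs_f=out_uf[:, i].copy() if out_uf is not None else None,
            )
        )
    return results


def integrate(
    columns: ColumnParams | str | Sequence[ColumnParams | str],
    coupling: CouplingSpec | None = None,
    stimuli: StimulusSpec | None = None,
    sim: SimulationSpec | None = None,
    keep_states: bool = False,
    keep_inputs: bool = False,
    initial_state: ColumnState | Sequence[ColumnState] | None = None,
) -> TrialResult:
    """Integrate a single trial; see ``integrate_batch`` for semantics."""
    coupling = coupling or CouplingSpec()
    stimuli = stimuli or StimulusSpec()
    sim = sim or SimulationSpec()
    return integrate_batch(
        columns,
        coupling,
        stimuli,
        sim,
        seeds=[sim.master_seed],
        keep_states=keep_states,
        keep_inputs=keep_inputs,
        initial_state=initial_state,
    )[0]


@dataclass
class FixedPoint:
    """One equilibrium of the noise-free system: per-column states
    (derivatives zero), rates and potentials."""

    states: tuple[ColumnState, ...]
    rates: tuple[PopulationRates, ...]
    potentials: tuple[MembranePotentials, ...]
    residual: float


def fixed_point(
    columns: ColumnParams | str | Sequence[ColumnParams | str],
    coupling: CouplingSpec | None = None,
    mean_inputs: tuple[float, float] = (40.0, 3.0),
    n_starts: int = 40,
    seed: int = 0,
    tol: float = 1e-10,
) -> list[FixedPoint]:
    """Equilibria of the deterministic (mean-input, noise-free) system.

    Noise standard deviations are treated as zero and the delay is
    ignored (equilibria do not depend on it).  The algebraic system in
    the five PSPs per column is solved from ``n_starts`` random initial
    guesses plus the origin; distinct solutions are returned sorted by
    the pyramidal rate of the first column.  Raises ``RuntimeError``
    when no start converges.
    """
    cols = _as_columns(columns)
    coupling = coupling or CouplingSpec()
    ncols = len(cols)
    if ncols == 1 and coupling.K != 0:
        raise ValueError("a single column must be uncoupled (K = 0)")
    m_p, m_f = mean_inputs
    p = cols[0]
    conn, sig_p = p.conn, p.sigmoid
    Se = p.kernel_e.G / p.kernel_e.omega
    Ss = p.kernel_s.G / p.kernel_s.omega
    Sf = p.kernel_f.G / p.kernel_f.omega

    def residuals(yv: np.ndarray) -> np.ndarray:
        Y = yv.reshape(ncols, 5)  # yp, ye, ys, yf, yl per column
        zp_all = [
            sigmoid(conn.Cpe * Y[c, 1] - conn.Cps * Y[c, 2] - conn.Cpf * Y[c, 3], sig_p)
            for c in range(ncols)
        ]
        out = np.empty_like(Y)
        for c in range(ncols):
            ypc, yec, ysc, yfc, ylc = Y[c]
            zo = zp_all[1 - c] if ncols == 2 else 0.0
            u_p = coupled_input(m_p, coupling.Kp, zo)
            u_f = coupled_input(m_f, coupling.Kf, zo)
            ve = conn.Cep * ypc
            vs = conn.Csp * ypc
            vf = conn.Cfp * ypc - conn.Cfs * ysc + ylc
            out[c, 0] = Se * zp_all[c] - ypc
            out[c, 1] = Se * (sigmoid(ve, sig_p) + u_p / conn.Cpe) - yec
            out[c, 2] = Ss * sigmoid(vs, sig_p) - ysc
            out[c, 3] = Sf * sigmoid(vf, sig_p) - yfc
            out[c, 4] = Se * u_f - ylc
        return out.ravel()

    rng = np.random.default_rng(seed)
    zmax = 2 * sig_p.e0
    scales = np.array([Se * zmax, Se * (zmax + m_p / conn.Cpe + coupling.Kp * zmax),
                       Ss * zmax, Sf * zmax, Se * (m_f + coupling.Kf * zmax)])
    found: list[FixedPoint] = []
    keys: list[tuple] = []
    for i in range(n_starts + 1):
        x0 = (
            np.zeros(5 * ncols)
            if i == 0
            else (rng.uniform(0, 1, (ncols, 5)) * scales).ravel()
        )
        sol = root(residuals, x0, method="hybr", tol=tol)
        if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-8:
            continue
        Y = sol.x.reshape(ncols, 5)
        states, rates, pots = [], [], []
        for c in range(ncols):
            st = ColumnState(
                yp=Y[c, 0], ye=Y[c, 1], ys=Y[c, 2], yf=Y[c, 3], yl=Y[c, 4]
            )
            pot = membrane_potentials(st, conn)
            states.append(st)
            pots.append(pot)
            rates.append(population_rates(pot, sig_p))
        key = tuple(np.round([r.zp for r in rates], 4))
        if key not in keys:
            keys.append(key)
            found.append(
                FixedPoint(
                    states=tuple(states),
                    rates=tuple(rates),
                    potentials=tuple(pots),
                    residual=float(np.max(np.abs(residuals(sol.x)))),
                )
            )
    if not found:
        raise RuntimeError(
            "fixed-point search did not converge from any start "
            f"(best residual unavailable, {n_starts + 1} starts)"
        )
    found.sort(key=lambda fp: float(np.atleast_1d(fp.rates[0].zp)[0]))
    return found
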