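"""Single cortical column: four coupled neural populations.

The column lumps pyramidal cells (p), excitatory interneurons (e), slow
GABAergic interneurons (s) and fast GABAergic interneurons (f) into one
unit each.  Every population converts its average membrane potential into
an average firing rate through a shared sigmoid, and every synapse class
(excitatory, slow inhibitory, fast inhibitory) filters presynaptic rate
through a critically damped second-order kernel

    h(t) = G * omega * t * exp(-omega * t),   t >= 0,

with average gain ``G`` (mV) and lumped rate constant ``omega`` (1/s).
State is carried by the postsynaptic potentials ``y`` and their
derivatives ``x``; an auxiliary excitatory pathway ``l`` feeds the
external input of the fast interneurons.  All functions below accept
scalars or NumPy arrays in the state fields, so the same code serves a
single evaluation and a vectorised batch of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "SigmoidParams",
    "SynapticKernelParams",
    "ConnectivityConstants",
    "ColumnParams",
    "ColumnState",
    "PopulationRates",
    "MembranePotentials",
    "STATE_FIELDS",
    "sigmoid",
    "membrane_potentials",
    "population_rates",
    "column_derivatives",
    "column_preset",
    "available_bands",
]

# Exponent clip keeping exp() finite in double precision.
_EXP_CLIP = 700.0

STATE_FIELDS = ("yp", "xp", "ye", "xe", "ys", "xs", "yf", "xf", "yl", "xl")


@dataclass(frozen=True)
class SigmoidParams:
    """Rate sigmoid: ``z(v) = 2 e0 / (1 + exp(r (s0 - v)))``.

    e0 : half-maximum firing rate (pps); the rate saturates at ``2 e0``.
    r  : slope at the centre (1/mV).
    s0 : centre potential (mV).
    """

    e0: float = 2.5
    r: float = 0.56
    s0: float = 6.0

    def __post_init__(self) -> None:
        if self.e0 <= 0:
            raise ValueError(f"e0 must be positive, got {self.e0}")
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class SynapticKernelParams:
    """Second-order synaptic kernel ``h(t) = G omega t exp(-omega t)``.

    G     : average synaptic gain (mV).
    omega : lumped rate constant (1/s), the reciprocal of the kernel
            time constant.
    """

    G: float
    omega: float

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError(f"kernel gain must be positive, got {self.G}")
        if self.omega <= 0:
            raise ValueError(f"kernel rate must be positive, got {self.omega}")


@dataclass(frozen=True)
class ConnectivityConstants:
    """Dimensionless intra-column coupling weights C_ij (j -> i).

    Defaults are the standard multiples of the global constant C = 135:
    Cep = C, Cpe = Cpf = 0.8 C, Csp = Cps = 0.25 C, Cfp = 0.3 C,
    Cfs = 0.1 C.
    """

    Cep: float = 135.0
    Cpe: float = 0.8 * 135.0
    Csp: float = 0.25 * 135.0
    Cps: float = 0.25 * 135.0
    Cfp: float = 0.3 * 135.0
    Cfs: float = 0.1 * 135.0
    Cpf: float = 0.8 * 135.0

    def __post_init__(self) -> None:
        for name in ("Cep", "Cpe", "Csp", "Cps", "Cfp", "Cfs", "Cpf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ColumnParams:
    """Full parameter set of one cortical column."""

    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    kernel_e: SynapticKernelParams = field(
        default_factory=lambda: SynapticKernelParams(G=3.9, omega=55.0)
    )
    kernel_s: SynapticKernelParams = field(
        default_factory=lambda: SynapticKernelParams(G=4.3, omega=25.0)
    )
    kernel_f: SynapticKernelParams = field(
        default_factory=lambda: SynapticKernelParams(G=25.0, omega=250.0)
    )
    conn: ConnectivityConstants = field(default_factory=ConnectivityConstants)
    band_label: str = "LB"


@dataclass
class ColumnState:
    """Dynamical state of one column.

    ``y*`` are postsynaptic potentials (mV) and ``x*`` their time
    derivatives (mV/s), for the pyramidal (p), excitatory (e), slow (s)
    and fast (f) synaptic pathways and the auxiliary input pathway (l).
    Fields may be scalars or equally shaped arrays.
    """

    yp: np.ndarray | float = 0.0
    xp: np.ndarray | float = 0.0
    ye: np.ndarray | float = 0.0
    xe: np.ndarray | float = 0.0
    ys: np.ndarray | float = 0.0
    xs: np.ndarray | float = 0.0
    yf: np.ndarray | float = 0.0
    xf: np.ndarray | float = 0.0
    yl: np.ndarray | float = 0.0
    xl: np.ndarray | float = 0.0

    @classmethod
    def zeros(cls, shape: tuple[int, ...] | int = ()) -> "ColumnState":
        return cls(*(np.zeros(shape) for _ in STATE_FIELDS))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ColumnState":
        """Build from an array whose last axis runs over STATE_FIELDS."""
        arr = np.asarray(arr)
        if arr.shape[-1] != len(STATE_FIELDS):
            raise ValueError(f"last axis must have length {len(STATE_FIELDS)}")
        return cls(*(arr[..., i] for i in range(len(STATE_FIELDS))))

    def as_array(self) -> np.ndarray:
        """Stack the fields along a trailing axis, in STATE_FIELDS order."""
        return np.stack(
            [np.asarray(getattr(self, f), dtype=float) for f in STATE_FIELDS], axis=-1
        )

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


@dataclass
class PopulationRates:
    """Average spike densities (pps), one per population."""

    zp: np.ndarray | float
    ze: np.ndarray | float
    zs: np.ndarray | float
    zf: np.ndarray | float


@dataclass
class MembranePotentials:
    """Average membrane potentials (mV); ``vp`` is the column output."""

    vp: np.ndarray | float
    ve: np.ndarray | float
    vs: np.ndarray | float
    vf: np.ndarray | float


def sigmoid(v, p: SigmoidParams = SigmoidParams()):
    """Potential-to-rate sigmoid, overflow-safe for any magnitude of ``v``.

    Returns ``2 e0 / (1 + exp(r (s0 - v)))``, strictly increasing in
    ``v`` and bounded in (0, 2 e0).
    """
    arg = np.clip(p.r * (p.s0 - np.asarray(v, dtype=float)), -_EXP_CLIP, _EXP_CLIP)
    out = 2.0 * p.e0 / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def membrane_potentials(
    state: ColumnState, conn: ConnectivityConstants = ConnectivityConstants()
) -> MembranePotentials:
    """Assemble the four membrane potentials from the synaptic PSPs.

    vp = Cpe ye - Cps ys - Cpf yf
    ve = Cep yp
    vs = Csp yp
    vf = Cfp yp - Cfs ys + yl
    """
    return MembranePotentials(
        vp=conn.Cpe * state.ye - conn.Cps * state.ys - conn.Cpf * state.yf,
        ve=conn.Cep * state.yp,
        vs=conn.Csp * state.yp,
        vf=conn.Cfp * state.yp - conn.Cfs * state.ys + state.yl,
    )


def population_rates(
    pot: MembranePotentials, p: SigmoidParams = SigmoidParams()
) -> PopulationRates:
    """Apply the shared sigmoid to every membrane potential."""
    return PopulationRates(
        zp=sigmoid(pot.vp, p),
        ze=sigmoid(pot.ve, p),
        zs=sigmoid(pot.vs, p),
        zf=sigmoid(pot.vf, p),
    )


def column_derivatives(
    state: ColumnState,
    u_p,
    u_f,
    params: ColumnParams,
) -> ColumnState:
    """Right-hand side of the column dynamics.

    Each synaptic pathway obeys ``y'' = G omega D - 2 omega y' - omega^2 y``
    with drives

    * pyramidal pathway:            D = zp
    * excitatory pathway:           D = ze + u_p / Cpe
    * slow inhibitory pathway:      D = zs
    * fast inhibitory pathway:      D = zf
    * auxiliary input pathway (l):  D = u_f  (through the excitatory kernel)

    ``u_p`` and ``u_f`` are the external inputs (pps) to the pyramidal
    and fast-inhibitory populations; they may fluctuate below zero.
    Raises ``FloatingPointError`` when the state is not finite, which the
    integrator reports as a numerical blow-up.
    """
    if not state.is_finite():
        raise FloatingPointError("non-finite column state (numerical blow-up)")
    rates = population_rates(membrane_potentials(state, params.conn), params.sigmoid)
    ke, ks, kf = params.kernel_e, params.kernel_s, params.kernel_f

    def second_order(y, x, kern: SynapticKernelParams, drive):
        return kern.G * kern.omega * drive - 2.0 * kern.omega * x - kern.omega**2 * y

    return ColumnState(
        yp=state.xp,
        xp=second_order(state.yp, state.xp, ke, rates.zp),
        ye=state.xe,
        xe=second_order(
            state.ye, state.xe, ke, rates.ze + np.asarray(u_p, dtype=float) / params.conn.Cpe
        ),
        ys=state.xs,
        xs=second_order(state.ys, state.xs, ks, rates.zs),
        yf=state.xf,
        xf=second_order(state.yf, state.xf, kf, rates.zf),
        yl=state.xl,
        xl=second_order(state.yl, state.xl, ke, np.asarray(u_f, dtype=float)),
    )


def _preset_text(band: str) -> str:
    try:
        return (
            resources.files("callosim").joinpath(f"presets/{band}.yaml").read_text()
        )
    except FileNotFoundError:
        raise KeyError(
            f"unknown band label {band!r}; expected one of {sorted(available_bands())}"
        ) from None


def available_bands() -> Iterable[str]:
    return ("LB", "MB", "HB")


def column_preset(band: str = "LB") -> ColumnParams:
    """Load one of the shipped per-band parameter presets (LB, MB, HB)."""
    doc = yaml.safe_load(_preset_text(band))
    sig = SigmoidParams(
        e0=doc["sigmoid"]["e0_pps"],
        r=doc["sigmoid"]["r_per_mv"],
        s0=doc["sigmoid"]["s0_mv"],
    )
    kern = {
        key: SynapticKernelParams(G=entry["gain_mv"], omega=entry["rate_per_s"])
        for key, entry in doc["kernels"].items()
    }
    C = doc["connectivity"]["C"]
    conn = ConnectivityConstants(
        **{
            name: C * doc["connectivity"][name]
            for name in ("Cep", "Cpe", "Csp", "Cps", "Cfp", "Cfs", "Cpf")
        }
    )
    return ColumnParams(
        sigmoid=sig,
        kernel_e=kern["excitatory"],
        kernel_s=kern["slow_inhibitory"],
        kernel_f=kern["fast_inhibitory"],
        conn=conn,
        band_label=doc["band"],
    )
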