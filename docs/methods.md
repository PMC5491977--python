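# Methods

## Model

Each cortical column follows the four-population Wendling-type neural
mass architecture.  State is carried by five second-order synaptic
pathways per column (pyramidal, excitatory, slow-inhibitory,
fast-inhibitory, plus an auxiliary excitatory pathway that feeds the
external input of the fast interneurons), i.e. ten ODE variables per
column.  The potentials are assembled as

    vp = Cpe ye − Cps ys − Cpf yf
    ve = Cep yp
    vs = Csp yp
    vf = Cfp yp − Cfs ys + yl

with the connectivity constants the standard multiples of C = 135
(Cep = C, Cpe = Cpf = 0.8 C, Csp = Cps = 0.25 C, Cfp = 0.3 C,
Cfs = 0.1 C).  All populations share one sigmoid (e0 = 2.5 pps,
r = 0.56 /mV, s0 = 6 mV), so rates live in (0, 5) pps.

The external pyramidal input enters the excitatory pathway as
`ze + u_p / Cpe`.  The division is deliberate: since `vp` multiplies
`ye` by `Cpe`, it makes the input's effective gain into `vp`
independent of `Cpe` and renders the formulation algebraically
identical to the classical Wendling form in which the input adds
directly to the excitatory feedback PSP.  We verified the equivalence
symbolically (mapping y1 = Cpe·ye) and numerically: the resulting
noise-free equilibrium places the pyramidal cells at zp ≈ 4.1–4.3
(near the linear/high-saturation transition), the excitatory
interneurons at the 5 pps ceiling and the fast interneurons at
zf ≈ 0.47–0.80, for all three band presets — the operating regime in
which the fast cells, sitting near low saturation, are the most
sensitive relay for extrinsic input.

The three presets (LB/MB/HB) differ only in synaptic gains and rate
constants (LB: Ge 3.9, Gs 4.3, Gf 25, ωe 55, ωs 25, ωf 250 s⁻¹; MB:
same gains with ωe 75, ωs 33, ωf 330; HB: Ge 4.3, Gs 4.6, Gf 29,
ωe 90, ωs 36, ωf 380).  The ω constants are used exactly as tabulated,
as lumped rate constants in s⁻¹, with no 2π conversion.  Linearising
the model at its fixed point yields output resonances at 12.7, 17.5 and
21.0 Hz for LB/MB/HB; the simulated Welch spectra peak at the same
frequencies (±1 bin).  These sit at, or somewhat below, the lower edges
of the nominal 14–19 / 20–24 / 25–30 Hz sub-bands; a uniform upward
rescaling of the ω constants would centre the peaks in the sub-bands
but pushes the fast-interneuron working point above 1 pps, breaking the
operating-regime structure described above, so the tabulated values are
kept.  Band-power analyses therefore resolve the upper flank of the
resonance when the nominal sub-band definitions are used, which is
sufficient for all relative (ERD/ERS) measures.

## Transcallosal coupling

Projections originate from the pyramidal cells of one column and reach
the other with delay T = 13 ms: `u_i = n_i + K_i zp(t−T)` for
i ∈ {p, f}, with K_p = 0.3 K and K_f = 0.7 K (the anatomical 30/70
split between pyramidal and fast-spiking targets).  The global gain K
is explored over 0–100.  The delay is realised as a circular buffer of
the pyramidal rate at integration-step resolution; its pre-fill is
zero, so the first T seconds of the warm-up run uncoupled.

## Stochastic inputs and their scaling

The driving inputs are Gaussian white noise: mean 40 pps (sd 1) to the
pyramidal pathway and mean 3 pps (sd 1) to the fast interneurons, four
independent streams (2 columns × 2 targets) spawned from one master
seed.  The stated standard deviation is interpreted as the *intensity*
of continuous-time white noise, i.e. the integrator draws per-step
deviates with standard deviation sd/√dt (the Euler–Maruyama
convention).  This choice keeps trajectory statistics independent of
the step size and produces pyramidal-rate fluctuations of ~0.2 pps,
large enough to drive the noise-dependent phenomena the model is built
to exhibit (most importantly the stochastic escape into the
winner-take-all regime, below).  Under the alternative convention —
holding unit-variance samples for one step with no rescaling — the
effective noise intensity shrinks with √dt and, at dt = 1e-4 s,
fluctuations become orders of magnitude too small to trigger any
symmetry breaking within a 16 s trial.  A `noise_scaling="per-step"`
switch preserves that alternative for comparison.

The motor-imagery input is a smoothed trapezoid on the left column's
pyramidal drive: 4 s baseline, 2 s rise, 4 s plateau at 100 pps, 2 s
fall, 4 s rest.  The ramps are raised-cosine (half-Hann), making the
waveform C¹ at every join; its integral is plateau_amp × (plateau + rise)
seconds·pps.

## Numerics

The synaptic kernels are linear, so they are advanced with their exact
zero-order-hold discretisation (the matrix exponential of the
critically damped pair), with the sigmoid drives and the noise held
constant over each step of dt = 1e-4 s.  This makes the kernel impulse
response exact to machine precision at any step size — the fast kernel
(ωf up to 380 s⁻¹) is the accuracy bottleneck under explicit Euler —
while the remaining discretisation error (piecewise-constant drives)
vanishes with dt; halving dt changes the noise-free mean pyramidal rate
by far less than 1e-3 pps.  Trials start from the zero state and a 2 s
warm-up is integrated and discarded so the analysis window sees the
stationary regime.  Output is decimated to 100 Hz by direct
subsampling.  Runs are bit-reproducible given the master seed, and a
trial integrates identically whether run alone or inside a vectorised
batch (per-trial RNG streams).

The noise-free equilibria are found by multi-start root finding on the
algebraic system obtained by zeroing all derivatives (delay-independent).
The solver reports all distinct solutions; at strong coupling it
exhibits the coexisting symmetric and asymmetric (winner-take-all)
equilibria.

## Spectral analysis

Spectra use the modified-periodogram (Welch) estimator: 1 s Hamming
windows, demeaned per segment, advanced in 0.01 s hops (99 % overlap).
The sliding band-power estimator integrates the same windowed
periodogram over a band; ERD/ERS is the percent change of band power
against the mean over the windows fully contained in the 4 s baseline.
For trial-averaged curves the band power is averaged across trials
*before* the ratio; per-trial ratios carry a positive small-sample bias
from the stochastic baseline estimate (≈ +20 % for a single trial)
that the power-domain average avoids.  Dominant frequencies exclude the
zero-frequency bin, which after per-segment demeaning contains only
residual trend.

## Working regions and the winner-take-all boundary

Sweeping K with driving noise only, the mean pyramidal rate declines
along three regions: a concave region near upper saturation, a convex
region of linear-regime operation with strongly amplified synchronised
rhythms, and a winner-take-all region where one column is silenced.
Asymmetric equilibria already exist from K ≈ 8–10 (the bifurcation is
strongly subcritical) while the symmetric state loses deterministic
stability only near K ≈ 44–56; in between, entering the winner-take-all
state within a 16 s trial is a noise-driven first-passage event.  The
observed onsets (HB ≈ 16, LB ≈ 33 ± 3 across master seeds) therefore
carry irreducible seed-to-seed spread of a few K units.

`classify_regions` operationalises the boundaries: the region-2/3
boundary is the smallest K at which the trial-averaged winner–loser
difference exceeds 2 pps or the loser falls below 0.5 pps; the
region-1/2 boundary is the concave-to-convex inflection of the
column-averaged rate (sign change of the second difference after
moving-average smoothing over 5 grid points).  Winner and loser are
always identified by sorting per-trial mean rates, because the winning
side is chosen by noise.  The thresholds are operational choices for
curves that are otherwise delimited by eye.

Reduced defaults (K step 2, 5 trials per K) keep a sweep around half a
minute on one CPU; the full 101-point, 20-trial protocol sits behind
`--full`.

## ERD/ERS phenomenology

With the imagery input on the left column, the left (contralateral)
column saturates and its beta power collapses — an ERD whose magnitude
grows with K (≈ −69 % at K = 10, ≈ −29 % at K = 26 for LB, plateau
average).  The right (ipsilateral) column shows the mirrored ERS —
its working point is pushed down into the high-gain linear region — and
the ERS grows with K to a maximum (≈ +19 % near K = 4 for LB) before
collapsing: beyond that, suppressing the left column's rhythm removes
the collective coupled-mode oscillation and both columns lose band
power.  At K = 0 the right column is untouched.  In this
implementation the ipsilateral ERS maximum sits at lower K (≈ 4) than
the K_H presets (10/6/4 for LB/MB/HB) chosen for the high-amplitude
demonstrations, so at K_H = 10 the LB ipsilateral response is already
negative; the K_H/K_L presets are kept as named constants, with the
map experiment (`erd_ers_map`) available to locate the ERS maximum for
any band.

## What the synthetic conditions do and do not show

All inputs are internally generated; no recorded EEG is consumed.  The
driving noise emulates the lumped effect of unmodelled afferents as a
stationary Gaussian process — real background activity is non-stationary
and spatially correlated, and real beta rhythms ride on 1/f broadband
activity, none of which is modelled.  Trial timing is fixed with no
inter-trial jitter or habituation.  Passing tests therefore demonstrate
the internal consistency of the model and estimators under the stated
idealised conditions, not the fidelity of any particular subject's
EEG.  Known limitations: no thalamic loop (the model targets cortically
generated beta, not mu/alpha), no plasticity, exactly seven intra-column
connections, and at most two columns.
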