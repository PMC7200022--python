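# Methods

## The spiking network

Each population α ∈ {E, I} contains N_α AdEx neurons with membrane equation

    C dV/dt = g_L(E_L − V) + g_L Δ_T exp((V − V_T)/Δ_T) − I_A + I_syn + I_ext,

spike cutoff at V_s = −40 mV, reset to V_r = −70 mV, refractory clamp for
T_ref = 1.5 ms.  Only excitatory neurons carry the adaptation current I_A
(subthreshold conductance a, spike-triggered increment b, reversal E_A,
time constant τ_A); inhibitory adaptation is far weaker in cortex and is
set to zero.  The external input per neuron is C·(μ_α^ext + σ^ext ξ_i(t))
with independent unit white noise ξ_i; σ^ext = 1.5 mV·ms^(−1/2) (the
square, in mV²/ms, is the diffusion coefficient entering the Fokker–Planck
picture).

Synapses are current based and saturating: the gating variable s_{i,αβ} of
the projection β→α onto neuron i decays with τ_{s,β} and jumps by
(c_αβ/|J_αβ|)(1 − s) per arriving spike, so s ∈ [0, 1], a single spike at
rest injects the PSC amplitude C·c_αβ, and a fully active projection
injects C·J_αβ.  J carries the sign of the projection (J_EI, J_II < 0);
the gating increment uses its magnitude.  Connectivity per projection is a
random binary matrix with fixed in-degree (K_E = 800 excitatory and
K_I = 200 inhibitory afferents per neuron, regardless of target
population), excluding self-connections, regenerated from the seed for
every simulation.  Spikes arrive after a delay set by the target
population (d_E = 4 ms, d_I = 2 ms).

Numerics: stochastic Heun with dt = 0.1 ms by default (configurable); the
same Gaussian increment σ^ext√dt·N(0,1) enters predictor and corrector.
Several spikes arriving within one step compose as
s ← 1 − (1 − s)(1 − c/|J|)^n, the exact result of n sequential single-spike
increments.  The threshold test runs after the corrector; the spike is
stamped at the end of the step.  Initial conditions: V uniform in
[V_r, V_T], s = I_A = 0.  A step of 0.1 ms resolves the exponential spike
initiation (validated below); coarser steps systematically distort the
escape dynamics.

Validation: (i) the deterministic single-neuron inter-spike interval
matches an adaptive-step scalar integration of the same ODE to 0.01%;
(ii) stationary rates of uncoupled noisy populations match the
Fokker–Planck solution to <1% (the test suite asserts 5% at five random
grid nodes with a 10⁴-neuron, 10 s Monte-Carlo estimate); (iii) at
identical external drives the network reproduces the mean-field state
classification at all five named operating points.

## Transfer functions (Fokker–Planck threshold integration)

For the EIF neuron (a = b = 0) with white-noise input of mean μ and
intensity σ, the stationary density/flux pair is integrated backward in V
from the absorbing cutoff V_s to a lower bound of −200 mV with step
0.01 mV, with unit outflux re-injected at V_r and the refractory mass
r·T_ref held at V_r.  This yields Φ(μ, σ) (rate) and V̄(μ, σ) (mean
potential).  An exponential-integrator step makes the scheme robust to the
stiff drift; when the unnormalized density overflows (deeply subthreshold
μ with tiny σ) the solution is rescaled, the rate reported as 0, and V̄
taken from the remaining bulk density.

The linear-response timescale τ(μ, σ) comes from the modulated problem:
for each frequency, two backward integrations (a homogeneous solution with
unit outflux, re-injected at V_r with the delay factor e^(−iωT_ref), and an
inhomogeneous solution sourced by the stationary density) determine the
complex rate response r₁(ω) from the zero-flux condition at the lower
bound.  |r₁(f)| at 20 log-spaced frequencies between 0.1 and 100 Hz is fit
by a Lorentzian |r₁(0)|/√(1 + (2πfτ)²); r₁(0) is taken as dΦ/dμ (central
difference), which the ω → 0 limit of the march reproduces to 1% — an
internal cross-check asserted in the tests.  The fit clamps below at
0.05 ms: in the mean-driven regime the response is nearly flat in this
band and the kernel is effectively instantaneous.  Nodes with vanishing
rate get τ = τ_m (leak-dominated dynamics; the fit is degenerate there and
flagged with a warning).

Default grid: μ ∈ [−2, 6] mV/ms in steps of 0.05 (the upper end leaves
headroom for the strongly driven adaptation regimes, where the recurrent
input transiently exceeds 4 mV/ms), σ ∈ [0.05, 5] mV·ms^(−1/2) on 30
log-spaced nodes.  Lookups are bilinear; out-of-range queries clamp to the
border and log a warning once.  Tables serialize to `.npz` with the neuron
parameter hash and round-trip bit-exactly.

## The mean-field cascade

State per projection αβ ∈ {EE, IE, EI, II}: mean synaptic activity s̄_αβ
and variance σ²_{s,αβ}, driven by the delayed effective input rate
r_αβ = (c_αβ/|J_αβ|)·K_β·r_β(t − d_α):

    ds̄/dt  = −s̄/τ_s + (1 − s̄)·r_αβ
    dσ²_s/dt = ρ_αβ(1 − s̄)² + (ρ_αβ − 2(r_αβ + 1/τ_s))·σ²_s ,   ρ_αβ = (c/|J|)·r_αβ

(the variance equation follows from Itô's rule applied to the
diffusion-approximated gating SDE).  The membrane-current variance is the
algebraic sum over source populations,

    σ_α² = Σ_β 2 J_αβ² σ²_{s,αβ} τ_{s,β} τ_m / ((1 + z_αβ) τ_m + τ_{s,β}) + σ_ext²,

with the dimensionless z_αβ = τ_{s,β}·r_αβ.  The mean current follows

    τ_α(μ_α^eff, σ_α) dμ_α/dt = J_αE s̄_αE + J_αI s̄_αI + μ_α^ext − μ_α,

with μ_E^eff = μ_E − Ī_A/C (the adaptation current shifts the abscissa of
all E-population lookups: Φ, V̄ and τ) and μ_I^eff = μ_I.  The mean
adaptation current evolves as
dĪ_A/dt = (a(V̄_E − E_A) − Ī_A)/τ_A + b·r_E.  Stimulation (in pA) is added
to μ_E^ext only: cortical pyramidal neurons, with their aligned apical
dendrites, dominate the susceptibility to extracellular fields.

Numerics: forward Euler, dt = 0.05 ms (0.01 ms for adaptation scans, where
the slow oscillation traverses near-degenerate regions).  The relaxation
factor dt/τ_α saturates at 1 so that the clamped fast-kernel nodes cannot
destabilize the scheme.  s̄ is clipped to [0, 1] and σ²_s to ≥ 0 (the
clips are inactive in normal operation).  Rates are kHz internally, Hz at
the interface.  Initialization: μ_α = μ_α^ext(0), synaptic state and Ī_A
zero, flat rate history from the initial lookup; analyses discard at least
the first second.  Halving dt changes the A2 oscillation frequency by
<2% (asserted).

## Field-to-current conversion

The ball-and-stick neuron (soma diameter 10 μm, specific capacitance
10 mF/m², soma and dendrite membrane resistivity 2.8 Ω·m², dendrite
1200 μm × 2 μm, axial resistivity 1.5 Ω·m) is solved in SI units; the
complex propagation constant is z = √((g_m + iωc_m)/g_a) and the somatic
polarization per unit field U_BS(f) has units of length (≈0.50 mm at DC,
i.e. 0.5 mV per V/m — the electrotonic length is ~1 mm, so the 1.2 mm
dendrite is *not* in the saturated long-cable regime).  The equivalent
current is I_ext = A|U_BS(f)/z_EIF(f)| with the linearized EIF impedance
z_EIF(f) = 1/(g_L(1 − e^((V_r−V_T)/Δ_T)) + 2πiCf) ≈ 100 MΩ at DC.  f = 0
is evaluated analytically, not by small-f extrapolation.  The conversion
is defined for the non-adapting neuron; adaptive parameters trigger a
warning and the EIF impedance is used.  Useful anchors: 5 pA per V/m at
DC, ~13 pA per V/m at 22 Hz.

## State classification and scans

A cell of the (C·μ_E^ext, C·μ_I^ext) plane is classified by a two-kick
probe: a −300 pA kick (500 ms plateau, 500 ms exponential decay — slow
compared with membrane and synaptic timescales, so the basin is entered
without ringing) settles the system into the low-activity basin; the
post-kick window is tested for oscillation (Welch, Hanning window;
oscillating iff the dominant frequency exceeds 0.1 Hz and its power
density exceeds 1 — the rate is in Hz, so the power density carries units
of Hz and the threshold is unity on that scale); a +300 pA kick then
probes for a coexisting up-state (bistable iff the relaxed means differ by
more than 10 Hz and neither window oscillates).  Non-oscillatory,
non-bistable cells are labelled up/down by a 10 Hz mean-rate split.
Oscillatory cells with dominant frequency below 6 Hz under adaptation are
labelled LC_aE (the excitation–adaptation loop runs at 0.5–5 Hz), faster
ones LC_EI (8–30 Hz).  When the oscillation power falls within a factor
two of threshold, the later half of the window is re-tested — this guards
against slow down→up transitions masquerading as oscillations near the
bistable border.

Two protocol variants: the standard one (7.5 s, 0.5 s Welch window) for
non-adapting scans, and a stretched one (12 s, 4 s analysis segment, 2 s
window) for adaptation scans, because a 0.5 s window cannot resolve
sub-hertz rhythms.  Default scan grids are 15×15 over
C·μ_E ∈ [0, 1] nA × C·μ_I ∈ [0, 0.5] nA, covering all named operating
points with margin; per-cell failures are recorded without aborting the
scan.

Entrainment sweeps run 6 s per stimulation frequency, discard 1 s, switch
the sinusoid on after the transient and use a 1 s Welch window; the 1:1
band is the set of stimulation frequencies whose output dominant frequency
matches them within 0.6 Hz (one spectral bin).  Phase locking uses the
peak-interval instantaneous phase (Gaussian smoothing of 5 ms, minimum
peak distance of half the dominant period — a period-relative rule rather
than a fixed width, which would be ill-posed across the 0.5–30 Hz range),
the Kuramoto order parameter R(t) of the stimulus/rate phase pair, and the
standard deviation of R(t) after 1.5 s as the locking index; indices below
0.05 are summarized as locked, but the continuous index is always
returned.

## Operating points

Five named drive pairs (A1–A3 without adaptation, B3–B4 with a = 15 nS,
b = 40 pA) mark the qualitatively distinct states: down (A1), the fast E–I
limit cycle (A2, ~22–23 Hz in the mean-field model), bistable up/down
coexistence (A3), the slow adaptation oscillation (B3, ~2.5 Hz) and a
high-drive down state (B4).  Mean-field and network variants of each point
are tabulated; at the mean-field drives both backends agree on all five
labels, which is the package's backend-consistency test (network at 10⁴
neurons, majority over three seeds).  The tabulated network-specific
drives place the spiking model's states at somewhat different positions
than the mean-field diagram predicts at those same inputs; the package's
network implementation, being validated against the Fokker–Planck and
single-neuron oracles above, follows the mean-field geometry closely, so
analyses comparing the two backends should use matched drives.

## What the synthetic data does and does not emulate

All inputs are generated by the simulators themselves; there is no
external data.  The network emulates a homogeneous, sparsely and randomly
connected cortical patch with equal neurons and stationary white-noise
background — it does not emulate heterogeneous cell parameters, log-normal
(heavy-tailed) synaptic weights, conductance-based synapses, structured
topology, or field effects on axons and on neurons misaligned with the
field.  Passing tests therefore certify the internal consistency of the
three descriptions and the stated dynamical phenomenology, not the
quantitative behavior of real cortex; in particular the strong-synapse
asynchronous-irregular regime is outside the model family's validity.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite in the tens of minutes on one core: networks of 10⁴ neurons
(2×5·10³) for spectra and state labels, 2×10⁴ for the finite-size ladder's
largest rung, 15×15 scan grids, 6–12 s simulations.  The bulk network
probes (state labels, Monte-Carlo rate checks, the finite-size ladder) run
at dt = 0.25 ms, where the single-neuron inter-spike interval is still
within 1.1% of the adaptive-step reference and population rates within
0.6% of the Fokker–Planck values; spectral worked examples keep the 0.1 ms
default.  These sizes are sufficient for every asserted property (the
finite-size trend is already monotone from 10³ neurons per population;
bifurcation diagrams agree with larger networks from a few thousand
neurons), but spectra from small networks carry visibly more finite-size
noise than the 10⁵-neuron regime.

## Known limitations

The exponential linear-response kernel underestimates transient ringing
after sharp input onsets (a damped-oscillator kernel would capture it);
the mean-field model is derived for weak, homogeneous coupling and large
N; the field conversion ignores dendrite–field misalignment and
suprathreshold field effects; and the Euler/Heun schemes require the
stated step sizes — the network integrator in particular should not be
run at millisecond steps, where exponential spike initiation is not
resolved.
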