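# adexfield

Cortical excitatory–inhibitory (E–I) populations of adaptive exponential
integrate-and-fire (AdEx) neurons under electrical stimulation: a spiking
network simulator, its low-dimensional mean-field reduction, and the
electric-field coupling that links both to experimentally realistic
stimulation amplitudes.

## Who this is for

Computational neuroscientists studying how weak electric fields — applied
transcranially or generated endogenously — interact with ongoing population
rhythms.  Simulating a cortical area as 10⁴–10⁵ spiking neurons is accurate
but slow; the package therefore couples three levels of description that
share a single biophysical parameter set:

1. **Spiking network** (`adexfield.network`): two delay-coupled populations
   of AdEx neurons with current-based saturating synapses, random
   fixed-in-degree connectivity and independent white-noise drive.
2. **Mean-field model** (`adexfield.meanfield`): a linear–nonlinear cascade.
   The mean membrane current μ_α of population α ∈ {E, I} relaxes with an
   input-dependent timescale τ_α(μ, σ) and is mapped to a rate through a
   precomputed static nonlinearity,

       r_α = Φ(μ_α − Ī_A/C, σ_α),

   where Φ, the mean membrane potential V̄(μ, σ) and τ(μ, σ) are obtained
   once by threshold integration of the stationary and linearly perturbed
   Fokker–Planck equation of the exponential integrate-and-fire (EIF)
   neuron (`adexfield.transfer`).  Synaptic means and variances per
   projection, delayed rates and the mean adaptation current Ī_A close the
   system.
3. **Field coupling** (`adexfield.field_coupling`): the equivalence
   I_ext = A·|U_BS(f)/z_EIF(f)| between a uniform extracellular field of
   amplitude A and an injected current, from the polarization transfer
   function U_BS of a ball-and-stick neuron and the EIF impedance z_EIF.

Analysis tools (`adexfield.analysis`) classify dynamical states (up/down
fixed points, bistability, the fast E–I limit cycle LC_EI, the slow
adaptation-driven limit cycle LC_aE), scan bifurcation diagrams with a
two-kick stimulus probe, and quantify frequency entrainment and Kuramoto
phase locking under sinusoidal drive.

## Worked example

```python
import adexfield as af

eif = af.NeuronParams().without_adaptation()
table = af.default_table(eif)

muE, muI = af.operating_point_drive("A2", "meanfield")
net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
trace = af.simulate_meanfield(eif, net, table, duration=6000.0, dt=0.05)

seg = trace.after(1000.0)
spec = af.welch_spectrum(seg.r_E, trace.dt, window_ms=1000.0)
print(f"dominant frequency: {spec.dominant_frequency:.1f} Hz")
print(f"field equivalent of a 20 pA drive at resonance: "
      f"{af.field_from_current(20.0, spec.dominant_frequency):.2f} V/m")
```

prints

```
dominant frequency: 23.0 Hz
field equivalent of a 20 pA drive at resonance: 1.50 V/m
```

— at operating point A2 the E–I loop sustains a low-gamma oscillation, and
a stimulus able to entrain it (see `examples/05_entrainment.py`: 1:1
entrainment holds up to 26 Hz at 20 pA) corresponds to an extracellular
field of only ~1.5 V/m, within the range of transcranial alternating
current stimulation.

The `examples/` directory walks through each capability: field/current
conversion, the mean-field oscillation, state switching with DC steps,
bifurcation scans, entrainment, phase locking, and the spiking-network
ground truth.  A thin CLI mirrors these workflows
(`adexfield simulate --point A2 ...`, `adexfield scan ...`,
`adexfield fieldconv ...`).

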