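"""Frequency entrainment of the endogenous oscillation by a weak sinusoid.

At operating point A2 the system oscillates at f0 ~ 22-23 Hz.  Driving the
excitatory population with a 20 pA sinusoid (about 1.5 V/m at resonance)
pulls the population frequency onto the stimulus frequency inside a finite
band around f0; outside the band the rhythm falls back to f0.
"""

import numpy as np

import adexfield as af

eif = af.NeuronParams().without_adaptation()
table = af.default_table(eif)
muE, muI = af.operating_point_drive("A2", "meanfield")
net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
backend = af.meanfield_backend(eif, net, table)

freqs = np.arange(16.0, 33.0, 1.0)
result = af.entrainment_sweep(backend, freqs, amplitude_pA=20.0)

print(" f_ext   dominant   1:1 entrained?")
for f, d in zip(result.f_ext_Hz, result.dominant_frequency):
    mark = "yes" if abs(f - d) <= 0.6 else ""
    print(f"{f:5.0f}   {d:7.1f}    {mark}")
print(f"\nupper edge of the entrainment band: {result.upper_edge():.0f} Hz")
print(f"equivalent field of the stimulus at f0: "
      f"{af.field_from_current(20.0, 22.0):.2f} V/m")
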