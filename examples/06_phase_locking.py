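"""Phase locking of the population rhythm to a weak periodic input.

The instantaneous phases of stimulus and excitatory rate are extracted
from their oscillation maxima, and their synchrony is summarized by the
Kuramoto order parameter R(t) of the two phases.  If the stimulus frequency
matches the endogenous one, R(t) stays constant (locked); a detuned
stimulus produces a slow beat in R(t).
"""

import adexfield as af

eif = af.NeuronParams().without_adaptation()
table = af.default_table(eif)
muE, muI = af.operating_point_drive("A2", "meanfield")
net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
backend = af.meanfield_backend(eif, net, table)

for f_ext in (23.0, 30.0):
    stim = af.sinusoid(40.0, f_ext, onset=0.0)
    trace = backend(stim, 20000.0)
    wave = stim.sample(20000.0, trace.dt)
    res = af.phase_locking_index(trace, wave.values_pA)
    print(f"f_ext = {f_ext:4.1f} Hz: locking index std(R) = "
          f"{res.locking_index:.4f}  -> "
          f"{'locked' if res.locked else 'not locked'}")

print()
print("A 40 pA drive at the endogenous frequency locks the rhythm (index")
print("near zero); 7 Hz of detuning leaves R(t) beating at the frequency")
print("difference, so the index is large.")
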