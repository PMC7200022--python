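"""Translate extracellular electric-field amplitudes into equivalent input
currents for a point neuron.

A uniform field polarizes the soma of a ball-and-stick neuron; dividing the
polarization transfer function by the EIF impedance gives the injected
current that would depolarize the point neuron identically.  The ratio is
frequency dependent: the dendritic cable low-passes the field while the
membrane low-passes the current, so oscillating fields are *more* effective
per V/m than static ones.
"""

import adexfield as af

bs = af.BallStickParams()
print(f"somatic polarization at DC: "
      f"{abs(af.bs_polarization_transfer(bs, 0.0)):.3f} mV per V/m")

for f in (0.0, 10.0, 22.0, 30.0, 100.0):
    ratio = af.current_from_field(1.0, f)
    print(f"f = {f:5.1f} Hz: 1 V/m  <->  {ratio:6.2f} pA")

print()
print(f"a 0.1 nA static input is worth {af.field_from_current(100.0, 0.0):.1f} V/m")
print(f"a 20 pA sinusoid at 22 Hz is worth {af.field_from_current(20.0, 22.0):.2f} V/m")
print()
print("Weak fields (~1 V/m, the range of transcranial stimulation) thus map")
print("to currents of only tens of pA per neuron - yet the network analyses")
print("in the other examples show such currents can entrain the population.")
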