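"""Map the dynamical landscape of the E-I system on a coarse grid.

Every cell of a (C*mu_E, C*mu_I) grid is classified with the two-kick
probe: a negative decaying kick (test for oscillations in the low-activity
basin), then a positive kick (test for a coexisting up-state).  With
adaptation enabled the bistable region is replaced by a slow oscillation.
"""

import numpy as np

import adexfield as af

eif = af.NeuronParams().without_adaptation()
table = af.default_table(eif)
net = af.NetworkParams()

mue = np.linspace(0.0, 1.0, 9)   # nA
mui = np.linspace(0.0, 0.5, 9)
factory = af.meanfield_scan_factory(eif, net, table, dt=0.05)
diagram = af.scan_bifurcation(factory, mue, mui, adaptation=False)

glyph = {"down": ".", "up": "#", "bistable": "B", "LC_EI": "o",
         "LC_aE": "S", "failed": "!"}
print("rows: C*mu_E = 0 -> 1 nA (top to bottom); "
      "cols: C*mu_I = 0 -> 0.5 nA")
for row in diagram.labels:
    print("  " + " ".join(glyph[l] for l in row))

lc = diagram.cells("LC_EI")
print(f"\nLC_EI cells: {lc.sum()}, frequencies "
      f"{np.nanmin(diagram.dominant_frequency[lc]):.0f}-"
      f"{np.nanmax(diagram.dominant_frequency[lc]):.0f} Hz")
print("'.' down, '#' up, 'B' bistable, 'o' fast E-I limit cycle")
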