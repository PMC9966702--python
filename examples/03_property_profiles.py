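"""Physicochemical contrasts between a predicted interface and the rest.

Builds a toy sequence whose N-terminal half is charge-rich, computes
sliding-window property profiles, and tests whether charge differs at a
"predicted" interface covering that half — the same analysis used to
characterize what drives a predicted dimerization interface.
"""

import numpy as np

import spdca
from spdca.core import HotspotRectangle
from spdca.physchem import BUILTIN_SCALES, contrast_table

# charge-rich stretch (D/E/K/R) followed by an apolar stretch
seq = "DEKRDEKRDEKRDEKRDEKR" + "AVLIAVLIAVLIAVLIAVLI"
interface = [HotspotRectangle(1, 20, 1, 1, 1.0, 0.5)]

profile = spdca.property_profile(seq, spdca.load_scale("charge"), window=9)
print("windowed charge profile (first 5 positions):",
      np.round(profile.values[:5], 3))

table = contrast_table(seq, interface, axis="A", window=9, seed=0)
print(f"\n{'scale':18s} {'inside':>8s} {'outside':>8s} {'diff':>8s} {'p':>9s}")
for _, row in table.iterrows():
    print(f"{row['scale']:18s} {row['mean_inside']:8.3f} {row['mean_outside']:8.3f} "
          f"{row['difference']:8.3f} {row['p_value']:9.2g}")
print("\n-> hydrophobicity is far lower and hydrophilicity/polarity/SASA far")
print("   higher inside the charged stretch (p ~ 1e-4); net charge does not")
print("   separate the halves (alternating +/- residues average to ~0, p ~ 0.6).")
print("   The permutation p-values flag which scales genuinely distinguish")
print("   interface from non-interface residues.")
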