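"""Derive distribution-based attributes from a small occupancy table.

For one species observed over grid cells grouped into regions, compute the
group-equalized phi preference per region, the specialization index, and
the logit commonness, then discretize a scale variable into the five-level
ordinal form every model attribute uses.
"""

import numpy as np

from redlistrf import bin_ordinal, commonness, phi_coefficient, specialization

# 10 grid cells in two regions; the species occupies 3 of 4 coastal cells
# and 1 of 6 inland cells
cells = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
regions = np.array(["coastal"] * 4 + ["inland"] * 6)

profile = phi_coefficient(cells, regions)
for group, phi in zip(profile.groups, profile.phi):
    print(f"phi({group}) = {phi:+.4f}")
print(f"specialization S = {specialization(profile):.4f}")
# phi > 0 marks preference for the region after equalizing region sizes;
# S aggregates preference strength across all regions.

print(f"commonness (4 of 10 group cells) = {commonness(4, 10):+.4f}")
# logit scale: 0 means present in half the group-occupied cells.

body_mass = np.array([1.2, 3.5, 10.0, 44.0, 120.0, 800.0, np.nan])
levels = bin_ordinal(body_mass, use_log=True)
print(f"log-binned body mass levels: {levels}")
# equal-width bins on the log scale; the missing value stays missing.
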