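"""Assign evolutionary ages to enzymes and bin them into nd eras.

The age of a multidomain enzyme is the nd value of its second oldest
structural domain (the accepting context of a domain cooption); the
alternative rule takes the oldest domain outright.  nd runs from 0
(most ancient) to 1 (most recent) and is cut into ten width-0.1 eras.
"""

import numpy as np

from metanet import SimulationConfig, simulate_structure, assign_enzyme_age, assign_all_ages, bin_to_era

# worked example: enoyl-CoA hydratase (EC 4.2.1.17) carries five dated
# fold-family domains spanning both innovation peaks
domains = [0.791971, 0.0912409, 0.080292, 0.0912409, 0.813869]
print("EC 4.2.1.17 second-oldest age:", assign_enzyme_age(domains, "second_oldest"))
print("EC 4.2.1.17 oldest age:       ", assign_enzyme_age(domains, "oldest"))

ds = simulate_structure(SimulationConfig(seed=42))
ages = assign_all_ages(ds, "second_oldest")
hist = np.bincount([bin_to_era(a) for a in ages.values()], minlength=11)[1:]
print("\nenzymes first appearing per era (1 = most ancient):")
for era, n in enumerate(hist, start=1):
    print(f"  era {era:2d}: {'#' * (n // 20)} {n}")
# the two maxima (era 1 and eras 6-8) are the biphasic pattern of
# domain innovation the generator is calibrated to reproduce.
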