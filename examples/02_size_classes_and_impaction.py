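"""Droplet size classes, inhalability and the overspray/deposit split.

Discretises a lognormal spray spectrum into equal-mass classes and shows
which classes impact the wall and which remain airborne as overspray.
"""

import numpy as np

from spraymix.fixtures import worked_example_h2o2
from spraymix.spray_source import (
    critical_diameter,
    discretise_distribution,
    impaction_parameter,
    inhalable_fraction,
    split_release,
)

sc = worked_example_h2o2()
rho = sc.product_density()
classes = discretise_distribution(sc.distribution)
d_crit = critical_diameter(sc.jet, rho, sc.env)
rate = sc.application[0][2]
dep, osp = split_release(np.full(5, rate / 5), classes, sc.jet, rho, sc.env)

print(f"spectrum: MMD {sc.distribution.d_m * 1e6:.0f} um, GSD {sc.distribution.gsd}, "
      f"{len(classes)} classes of 20% mass each")
print(f"critical diameter: {d_crit * 1e6:.1f} um\n")
print(f"{'class':>5} {'median um':>10} {'K':>8} {'inhalable':>10} {'fate':>10}")
for c, dpc in zip(classes, dep):
    K = impaction_parameter(c.d_median, sc.jet, rho, sc.env)
    fate = "deposit" if dpc > 0 else "overspray"
    print(f"{c.index:5d} {c.d_median * 1e6:10.1f} {K:8.3f} "
          f"{inhalable_fraction(c.d_median):10.3f} {fate:>10}")
print(f"\noverspray fraction: {osp.sum() / rate:.0%} of the released mass stays")
print("airborne; the rest lands on the wall and evaporates from there.")
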