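"""Localize a basal free-wall contraction deficit on an AHA-17 bullseye.

A hypokinetic phantom (deficit d = 0.5 in the basal free-wall sectors)
is analyzed and the peak-systolic surface-area strain is averaged per
AHA segment.  The affected segments (5, basal inferolateral; 6, basal
anterolateral) show visibly reduced |Ea|.
"""

import numpy as np

from cmrstrain import analyze_mesh, build_dynamic_mesh, generate_phantom
from cmrstrain.phantom import BASAL_FREE_WALL_HYPOKINESIA, PhantomConfig
from cmrstrain.regions import bullseye_table

config = PhantomConfig(hypokinesia=dict(BASAL_FREE_WALL_HYPOKINESIA))
mesh = build_dynamic_mesh(generate_phantom(config))
results = analyze_mesh(mesh, kinds=("ea",))

field = results["ea"]["field"]
spec = results["ea"]["region_spec"]
mean_curve = field.values.reshape(len(field.time_fractions), -1).mean(axis=1)
peak_t = int(np.argmax(np.abs(mean_curve)))
values = field.values[peak_t]
values = np.concatenate([values, values[-1:]], axis=0)  # pad basal edge row

table = bullseye_table(values, spec)
print(table.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))
print("\nSegments 5 and 6 (basal free wall) have the smallest |Ea|:")
print("the deficit localizes where it was prescribed.")
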