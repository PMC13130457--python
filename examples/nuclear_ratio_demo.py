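"""Nuclear/cytoplasmic intensity ratio with per-muscle aggregation.

Simulates four muscles: one control (ratio 1) and three with increasing
nuclear accumulation of the signal, as seen transiently after
denervation.  Each muscle is quantified per nucleus, averaged per muscle
(the biological replicate) and normalized to the control group.
"""

import pandas as pd

from fiberquant import (
    aggregate_by_muscle,
    make_nuclei_image,
    normalize_to_control,
    run_nc_pipeline,
)

muscles = []
for i, (ratio, group) in enumerate(
    [(1.0, "innervated"), (1.5, "den2d"), (2.0, "den2d"), (1.0, "innervated")]
):
    stack, _ = make_nuclei_image(15, ratio, noise_sd=5.0, seed=30 + i)
    records = run_nc_pipeline(stack, muscle_id=f"M{i}", group=group)
    muscles.append(aggregate_by_muscle(records))

summaries = normalize_to_control(pd.concat(muscles, ignore_index=True), "innervated")
print(summaries.to_string(index=False))
print(
    "normalized_ratio is each muscle's mean nucleus/cytoplasm ratio divided "
    "by the control-group mean; the injected den2d muscles read ~1.5x and ~2x."
)
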