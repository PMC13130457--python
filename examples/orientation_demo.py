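"""Mitochondrial orientation relative to the fiber axis.

Generates a synthetic central frame in which 88.5% of the rods truly lie
at 60-90 degrees to the fiber (the innervated-muscle pattern), runs the
full orientation pipeline and prints the recovered bin proportions next
to the injected truth.  After denervation this 60-90 share collapses, so
the 60-90 proportion is the readout that separates the conditions.
"""

import numpy as np

from fiberquant import (
    INNERVATED_BIN_FRACTIONS,
    VolumeImage,
    make_fiber_frame,
    run_orientation_pipeline,
)

frame, truth = make_fiber_frame(
    400, INNERVATED_BIN_FRACTIONS, fiber_angle_deg=20.0, seed=11
)
stack = VolumeImage(
    frame.pixels[np.newaxis, np.newaxis], (1.0, *frame.spacing), ("tomm20",)
)
summary, objects = run_orientation_pipeline(stack)

print(f"segmented objects: {summary.n_total} (reliable={summary.reliable})")
for name, est, true in zip(
    ("0-30", "30-60", "60-90"), summary.proportions, truth.params["bin_fractions"]
):
    print(f"  {name:>6} deg: recovered {est:6.1%}   injected {true:6.1%}")
print(
    "The 60-90 degree share is the transversal-network signature; it should "
    "sit within a few points of the injected 88.5%."
)
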