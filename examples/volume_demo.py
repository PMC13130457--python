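"""3D mitochondrial volumes and distribution comparison.

Builds two synthetic stacks of ellipsoidal mitochondria whose volume
distributions differ by a 2-fold median shift (mimicking innervated vs
denervated fragmentation), measures per-object volumes through the 3D
segmentation, and compares the distributions with a two-sample KS test.
"""

from fiberquant import (
    compare_distributions,
    make_mito_volume,
    object_volumes,
    segment_mito_3d,
    volume_distribution_summary,
)

groups = {}
for name, median in (("innervated-like", 0.6), ("denervated-like", 0.3)):
    stack, truth = make_mito_volume(
        30, ("lognormal", {"median_um3": median, "sigma": 0.4}), seed=21
    )
    labels = segment_mito_3d(stack, "tomm20")
    table = object_volumes(labels, stack.spacing)
    summary = volume_distribution_summary(table["volume_um3"])
    groups[name] = table["volume_um3"].to_numpy()
    print(
        f"{name}: n={summary.n_objects} objects, "
        f"median {summary.median_um3:.3f} um^3 "
        f"(injected median {median:.1f} um^3)"
    )

d, p = compare_distributions(groups["innervated-like"], groups["denervated-like"])
print(f"KS test: D={d:.3f}, p={p:.2e}")
print("A small p confirms the injected shift toward smaller mitochondria.")
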