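"""Endplate morphometry and dual-label AChR turnover.

Simulates a fragmented endplate where 40% of voxels are dominated by the
"new" bungarotoxin label (high receptor turnover, as after denervation)
and quantifies volume, fragment count and the dominance fractions.
"""

from fiberquant import make_endplate, run_endplate_pipeline

stack, truth = make_endplate(new_fraction=0.4, n_fragments=6, seed=41)
record, _ = run_endplate_pipeline(stack, endplate_id="demo")

print(f"endplate volume:   {record.volume_um3:.1f} um^3")
print(f"fragments:         {record.fragment_count} (injected {len(truth.objects)})")
print(
    f"dominance:         new {record.new_fraction:.3f} / old {record.old_fraction:.3f}"
    f" / tie {record.tie_fraction:.3f} (injected new fraction 0.400)"
)
print(
    "The new-dominant fraction is the turnover readout: ~0 in stable "
    "innervated endplates, rising sharply when receptors are replaced."
)
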