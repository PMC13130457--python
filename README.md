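# fiberquant

Quantification of denervation-induced remodeling in skeletal muscle
fibers from fluorescence microscopy, plus a three-contrast classifier of
differential-expression results.

Cutting the motor nerve triggers a coordinated synaptic, contractile and
metabolic reprogramming of muscle fibers.  Measuring it requires a set of
bespoke image quantifications that are usually buried in ad-hoc scripts:
how the mitochondrial network is oriented relative to the fiber axis, how
mitochondrial volumes shift as the network fragments, how much a
transcriptional regulator accumulates in myonuclei relative to the
cytoplasm, how the neuromuscular endplate changes in volume and
fragmentation, and how fast acetylcholine receptors (AChRs) turn over in
a dual-label pulse–chase.  `fiberquant` implements these as a tested,
reusable library, together with a gene classifier that partitions
knockdown-responsive genes into activity-dependent and -independent
classes.  Every pipeline has a seeded synthetic generator with exact
ground truth, so the whole analysis is testable without raw microscopy or
sequencing data.

## The measurements

**Mitochondrial orientation** (`mito_orientation` via
`run_orientation_pipeline`): the central z-frame of a TOMM20 stack is
bilateral-filtered; the fiber is segmented (morphological closing + Otsu)
and its axis taken from the mask's second central moments; mitochondria
are enhanced with a multiscale Frangi vesselness filter and segmented by
Otsu within the fiber mask; each object's principal-axis angle θ is
folded against the fiber angle φ into a relative angle
r = min(|θ−φ|, 180°−|θ−φ|) ∈ [0°, 90°], and summarized over the bins
[0°,30°), [30°,60°), [60°,90°].  In innervated fast muscle the network is
transversal (60–90° share ≈ 88.5%); weeks after denervation it turns
longitudinal (≈ 18.7%).

**Mitochondrial volumes and shape** (`morphology`): 3D segmentation
(Gaussian smoothing, Otsu, 26-connected components), per-object volume
`voxel_count · dz·dy·dx`, median and empirical CDF, two-sample
Kolmogorov–Smirnov comparison between conditions; 2D electron-microscopy
style metrics with circularity 4πA/P².

**Nuclear/cytoplasmic ratio** (`nuclear_ratio`): per-nucleus mean signal
intensity divided by one global cytoplasmic mean per image; nuclei from
DAPI, cytoplasm = fiber minus dilated nuclei.  Ratios are averaged per
muscle (the biological replicate) and normalized to the control-group
mean.

**Endplate morphometry and AChR turnover** (`endplate`): endplate mask
from the summed old+new bungarotoxin channels; volume, 26-connected
fragment count, and per-voxel *pixel dominance*: each channel normalized
to its own 99th-percentile intensity within the mask, a voxel assigned to
the channel whose normalized intensity wins by more than a tie band.

**DEG classes** (`deg`): genes observed in three contrasts — DEN
(denervated vs innervated control), SH_IN and SH_DE (knockdown vs
control in innervated / denervated muscle) — are flagged DE when
|fold change| ≥ 1.5 (|log2FC| ≥ log2 1.5, inclusive) and p < 0.05
(strict), then partitioned into activity-independent (AIN^In, AIN^De,
AIN^InDe) and activity-dependent classes (AD^In±, AD^De±, AD^InDe and its
sign-inverse) by flag pattern and fold-change sign agreement.

## Worked example

```bash
python examples/orientation_demo.py
```

```
segmented objects: 398 (reliable=True)
    0-30 deg: recovered   5.0%   injected   5.0%
   30-60 deg: recovered   8.0%   injected   6.5%
   60-90 deg: recovered  86.9%   injected  88.5%
```

A synthetic frame with 400 rods carrying the innervated-muscle angle
mixture is generated, pushed through the full pipeline, and the
recovered bin proportions are printed next to the injected truth: the
transversal 60–90° share is recovered within ~1.6 points.  The other
examples (`volume_demo.py`, `nuclear_ratio_demo.py`, `endplate_demo.py`,
`deg_demo.py`) follow the same pattern — build a small input with known
truth, run the pipeline, print recovered vs injected.

A thin CLI mirrors the library (`fiberquant simulate ...`,
`fiberquant mito-orient ...`, `fiberquant deg-classify ...`); run
`fiberquant --help` for the subcommands.

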