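# replidyn

Toolkit for studying DNA replication dynamics during cell-fate change:
how slow replication forks, altered origin usage and replication-timing
(RT) remodeling accompany the reprogramming of mouse embryonic stem cells
(ESCs) into totipotent-like 2-cell-like cells (2CLCs).

It is aimed at groups running dual-pulse DNA fiber assays, FACS time
courses of rare-state emergence, and three-fraction Repli-seq, and at
anyone who wants to validate such pipelines on synthetic data with known
ground truth.

## What it computes

**DNA fiber assay quantification.** Stretched fibers labeled with two
sequential analog pulses (IdU then CldU, 30 min each) are located in
confocal images by multiscale Hessian ridge filtering, reconnected with a
spatially variant oriented morphological closing, thinned to subpixel
B-spline centerlines, and partitioned into label branches by a CART-style
regression tree on the log channel ratio. A fixed grammar over the branch
sequence yields the replication pattern (ongoing fork, stalled fork,
first/second-pulse origin, termination, multi-origin). Fork speed uses the
established stretching conversion

    v [kb/min] = track length [um] x 2 [kb/um] / pulse [min],

so a 20.1 um CldU track from a 30-min pulse is 1.34 kb/min. Origin
positions are midpoints of adjacent label boundaries; inter-origin
distances (IODs) are consecutive origin differences.

**Cell-cycle compartment model.** Cells traverse G1 -> S -> G2/M with
fixed phase durations and convert to the 2CLC state with a phase-specific
hazard f_p (per hour). For a synchronization design with initial
cycle-age density rho(a),

    fraction(t) = Int rho(a) [1 - exp(-Int_0^t f_phase(a+s) ds)] da,

integrated exactly piecewise. `fit_feasible_region` maps all rate triples
(f_G1, f_S, f_G2M) whose joint SSE against observed time courses stays
within a chi-square-style band of the minimum, and projects the set onto
the (f_G1/f_S, f_G2M/f_S) ratio plane; axis intercepts below 1 mean the
transition must occur predominantly in S phase.

**Repli-seq RT analysis.** Early/mid/late S-phase read counts are binned
(100 kb), RPM-normalized, log2(E/L) is loess-smoothed (tricube,
local-linear, 500-kb span), and the pipeline calls: differential-RT
regions between conditions at a twofold cutoff (1.5-fold for transitional
S-phase comparisons), early/late domains by circular binary segmentation,
per-gene stage classification (argmax fraction density over the gene
body), and repeat-class enrichment in shifted regions with permutation
p-values.

**Synthetic data.** `replidyn.simulate` renders fiber images (142-nm
pixels, Gaussian PSF, Poisson-Gaussian noise) from analytically known fork
events, samples binomial FACS time courses from the compartment model, and
generates three-fraction Repli-seq counts with planted RT-shift blocks and
repeat annotations — every downstream stage is testable without any
external download.

## Worked example

Measure fork speed in a simulated 2CLC-like cohort (slow forks, median
0.56 kb/min):

```python
import numpy as np
from replidyn import PulseProtocol
from replidyn.pipeline import analyze_image
from replidyn.fiber_stats import measurements_frame
from replidyn.simulate import render_fiber_image
from replidyn.simulate.populations import ongoing_fork_spec, lognormal_speeds

protocol = PulseProtocol()  # IdU 30 min, then CldU 30 min
rng = np.random.default_rng(0)
speeds = lognormal_speeds(50, median_kb_min=0.56, rng=rng)
patterns = []
for i, v in enumerate(speeds):
    image, truth = render_fiber_image([ongoing_fork_spec(v, protocol, rng)],
                                      protocol, seed=i)
    patterns.extend(analyze_image(image, protocol))

table = measurements_frame(patterns, protocol.second_pulse_min)
print(f"fibers analyzed:    {len(patterns)}")
print(f"median fork speed:  {table['speed_kb_min'].median():.2f} kb/min")
```

prints

```
fibers analyzed:    50
median fork speed:  0.57 kb/min
```

i.e. the image pipeline recovers the planted 0.56 kb/min median within
2%. The same loop with `median_kb_min=1.34` emulates an ESC cohort.

The CLI wraps the same library calls, e.g.:

```bash
replidyn simulate repliseq --seed 1 --out rs/
replidyn rt diff rs/counts_a.tsv rs/counts_b.tsv --out diff.bed
# -> 2 regions (3.80% of genome) -> diff.bed
```

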