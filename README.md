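# guvstack

Automated analysis of confocal fluorescence z-stacks of giant unilamellar
vesicles (GUVs): circle segmentation, 3-D vesicle assembly, membrane and
droplet intensity quantification, lipid phase-separation state
determination, and CNN-based vesicle selection and state classification
trained on a built-in virtual confocal image simulator.

GUV experiments — protein–membrane binding assays, lipid domain phase
studies, protein droplet reconstitution — require measuring tens to
hundreds of vesicles per condition.  Each vesicle appears in a z-stack as
a short run of bright circular contours of radius
`rho(z) = sqrt(R^2 - (z - z0)^2)`.  `guvstack` automates what a trained
experimenter does by hand: find the circles, link them into 3-D vesicles,
discard ill-formed ones (multilamellar, overlapping, out-of-focus), and
compute per-vesicle quantities with background correction
`I_net = I_raw - I_background`.

Three pipeline programs differ in how much decision-making is learned:

| program | vesicle selection | phase-state decision |
|---|---|---|
| 1 | edge-contrast computation | contour-discontinuity statistic |
| 2 | 4-class CNN (C1 valid / C2 multilamellar / C3 overlapping / C4 hazy) | contour-discontinuity statistic |
| 3 | 4-class CNN | 2-class CNN on background-zeroed patches |

The phase-state statistic divides each detected contour into N angular
segments, reads the domain *high*/*low* levels at the 20th-percentile
ranks of the sorted segment means, and counts directional intensity swings
spanning ±p% around their midpoint with a hysteresis traversal — each
swing is one domain boundary, so ≥ 2 means a phase-separated section; a
vesicle is called separated when at least 40% of its sections are.  The
two small CNNs (16/32/64 and 8/16/32 conv filters, 3×3 kernels, two 2×2
max-pools, softmax output on 50×50 zerocenter inputs) train with SGDM at
learning rate 0.01 for 4 epochs, validating every 30 iterations — the
2-class state network entirely on simulator-generated, automatically
annotated virtual confocal images.

The simulator is a first-class component: vesicles are analytic spheres,
domains are secondary sphere/shell intersections, sections are rendered
with Gaussian PSF blur and additive noise, and exact per-section ground
truth (center, ring radius, phase label) comes with every render.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Simulate a three-vesicle stack (two vesicles carry a lipid domain, one is
homogeneous) and run the program-1 phase analysis:

```python
import numpy as np
from guvstack.simulate import SceneParams, sample_scene, render_zstack
from guvstack.config import AnalysisConfig
from guvstack.pipeline import run_program1

params = SceneParams(
    n_vesicles=(3, 3),
    radius_um=(22.0, 30.0),          # at 1 µm/px: 22-30 px rings
    field_of_view_um=256.0,
    frame_px=256,
    z_spacing_um=3.0,
    domain_probability=0.5,
)
scene = sample_scene(params, np.random.default_rng(12))
stack, truth = render_zstack(scene)
print("truly separated:", sorted(set(truth[truth.phase_label == "separated"].vesicle_id)))

cfg = AnalysisConfig(radius_range_px=(18, 40), channel_b=0, contour_p_percent=35.0)
result = run_program1([stack], cfg, mode="phase")
print(result.report[["vesicle_id", "n_sections", "mean_r_px",
                     "fraction_separated", "state"]].round(2).to_string(index=False))
```

Output:

```
truly separated: [0, 1]
 vesicle_id  n_sections  mean_r_px  fraction_separated     state
          0          13      21.17                0.62 separated
          1          14      23.79                0.93 separated
          2          11      20.78                0.18   uniform
```

Vesicles 0 and 1 — the two that carry a domain sphere in the ground truth —
are found in 13 and 14 z-sections and show discontinuous contours in 62%
and 93% of them, well above the 40% decision fraction; vesicle 2's
homogeneous contour stays inside the hysteresis dead band in most sections
(18% < 40%), so it is called uniform.  `contour_p_percent=35` suits this
strongly partitioned simulated reporter (dim domains ≤ 45% of the bright
level); dimmer-contrast reporters need a smaller p.

The same stack analyses are available from the shell:

```sh
guvstack simulate --out demo --seed 12 --n-vesicles 3
guvstack train --model-out models/state --kind state --n-per-class 2000
guvstack program1 demo/stack.tif --out run1 --mode phase --n-channels 1
```

Every run writes `report.csv`, an `entities.csv` audit table, color-coded
PNG overlays (uniform blue / separated yellow; CNN classes cyan, green,
blue, magenta; edge-touching red) and a `run_manifest.yaml` embedding the
fully resolved configuration.

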