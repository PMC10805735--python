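# nucleoshell

Quantification of how a fluorescent signal distributes radially around
core–shell nuclear condensates (nucleoli), for cell biologists analyzing
multi-channel fluorescence microscopy of nuclear bodies — e.g. asking
whether a DNA-state probe accumulates in the nucleolar core and whether a
drug treatment flattens that accumulation.

## What it computes

The nucleolus has a core–shell architecture: the fibrillar center and
dense fibrillar component form the core, the granular component (marked by
nucleophosmin, NPM) forms the shell.  For each nucleolus, segmented as the
filled territory of the shell marker, the package measures intensity along
rays from the centroid and assigns each sample the boundary-normalized
distance

    d = r / r_b(θ)

where r_b(θ) is the distance from the centroid to the outline along the
ray — so d = 1 is the boundary for every nucleolus, d ∈ [0, 0.5] the deep
interior ("inside") and d ∈ [1.5, 2.0] the surrounding nucleoplasm
("outside").  Per-nucleolus profiles are binned over d ∈ [0, 2],
moving-average smoothed, and aggregated (mean ± s.d. across nucleoli,
pooled over cells).  Inside/outside window means, one pair per nucleolus,
are compared between conditions with the two-sided Mann–Whitney U test
(two groups) or the two-sided Steel–Dwass all-pairs test (three or more,
studentized-range reference, family-wise error controlled).  Paired and
one-sample t tests plus helpers for gel-based crosslink-protection
fractions and ChIP-qPCR percent input (100·f·2^ΔCt, control-normalized)
round out the analysis layer.

Because suitable public raw images are not available, the package ships a
first-class synthetic generator: nuclei containing core–shell nucleoli
with parameterized radial intensity laws, Gaussian PSF, Poisson + read
noise, and exact ground truth (masks, centroids, analytic boundaries).
Condition presets emulate a core-enriched control (inside/outside ratio
ρ = 3), polymerase-inhibition-like core flattening (ρ = 1), G4-ligand-like
flattening with reduced shell marker, and strand-break-like global
reduction.  Every stage of the pipeline is validated against this ground
truth; see `docs/methods.md` for the model, defaults and limitations.

## Worked example

Simulate a two-condition experiment (4 fields each), segment, profile and
compare:

```python
from nucleoshell.pipeline import RunConfig, run_pipeline

config = RunConfig(
    conditions=("control", "RNAPI_inhibited_like"),
    n_fields_per_condition=4,
    seed=7,
)
manifest = run_pipeline(config, "demo/")
```

The manifest reports per-stage counts — here 14 control and 15 treated
nucleoli profiled from 4 nuclei each — and `demo/stats.csv` holds the
comparison:

```
 window           test group_a              group_b  statistic  p_value  n_a  n_b
 inside mann_whitney_u control RNAPI_inhibited_like        210 0.000005   14   15
outside mann_whitney_u control RNAPI_inhibited_like         80 0.284949   14   15
```

Read: the core signal differs decisively between control and the
polymerase-inhibited-like condition (inside window, U = 210,
p ≈ 5 × 10⁻⁶ — the treated cores lost their enrichment), while the
nucleoplasm is indistinguishable (outside window, p ≈ 0.28), the signature
of a specific core depletion rather than a global intensity change.
`demo/` also contains per-nucleolus profile tables, per-condition summary
curves (mean ± s.d. per d-bin), window means, the resolved configuration,
and a manifest listing every exclusion with its reason.

The same steps are available as a CLI for shell use:

```
nucleoshell simulate --out sim/ --seed 7 --condition control --n-fields 4
nucleoshell segment  --in sim/control-f000.tif --out seg/
nucleoshell profile  --in sim/control-f000.tif --masks seg/ --out prof/
nucleoshell compare  --windows a.csv --windows b.csv --out stats.json
nucleoshell run      --config run.yaml --out out/
```

plus `assay-crosslink`, `assay-chip` and `lineprofile`.

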