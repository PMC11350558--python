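# immunogate

Analysis pipeline for **low-volume murine peripheral-blood immunophenotyping**:
declarative 14-marker flow-cytometry panels with hierarchical gating trees,
absolute cell-count normalization, and the longitudinal statistics needed to
plan and analyze repeated-measures immune studies in mice.

Serial blood sampling in mice is capped at roughly 10% of total blood volume,
so longitudinal immune monitoring must work from ~50 µL of blood per panel.
This package implements the full analysis side of that workflow for three
built-in panels (myeloid, lymphoid, intracellular/cytotoxic — 14 markers
each; the two peripheral panels jointly resolve **42 reported immune
subsets**), plus a synthetic event generator with known ground truth so every
stage is testable end to end.

## What it computes

- **Gating.** Each gate is a conjunction of per-channel threshold conditions
  applied to asinh-transformed intensities, `x ↦ asinh(x / c)` with cofactor
  `c = 150`. Thresholds are placed automatically per channel: equal-posterior
  boundaries of a 2- or 3-component Gaussian mixture (kernel-density valley
  and quantile modes available), executed top-down so a node's member set is
  the intersection of its parent's set with its conditions.
- **Absolute counts.** Gated events become concentrations in whole blood:

  `cells/µL = (gate count / acquired volume) × (blood + diluent) / blood`

  (50 µL blood in 550 µL suspension → dilution factor 11), with
  `log10(x + 1)` as the analysis scale.
- **Variance decomposition.** For each subset measured on A animals × T
  timepoints, a two-factor repeated-measures decomposition
  `SS_total = SS_animal + SS_time + SS_residual` yields
  η² shares: inter-individual (animal factor) and intra-individual
  (repetition factor). Method-of-moments variance components
  (σ²_inter, σ²_intra) are available for parameter recovery.
- **Study planning.** Minimum detectable change `MDC = d × SD` (default
  Cohen's d = 0.5) and the per-group sample size from exact noncentral-t
  power inversion: for d = 0.5, 80% power, two-sided α = 0.05 it prints
  **64 per group** (63 by the normal approximation).
- **Group validation statistics.** Baseline-normalized percent change,
  pooled-variance Student's t-tests, additive block × group ANOVA (block
  dropped when non-significant), a two-sided variance-ratio F-test, and the
  clinical endpoint rule (any welfare item at 4, or cumulative score > 16).

## Worked example

Simulate one myeloid-panel blood sample, gate it, and recover absolute
counts (`python examples/02_gate_synthetic_sample.py`):

```
sample A1_T1: 50000 events, dilution factor 11
subset                        events cells/µL est cells/µL true
CD45_Leukocytes                48448       5329.3        5329.3
CD45_Myeloid                   16770       1844.7        1844.7
Granulocytes                   12290       1351.9        1351.9
Neutrophils                     8536        939.0         939.0
...
Classical_Monocytes             1084        119.2         121.0
mature_cDC1                       52          5.7           5.7
```

Estimated concentrations match the generator's ground truth to within a few
percent even for subsets a hundred-fold rarer than leukocytes. The other
examples cover the panel registry (`01`), longitudinal η²/MDC tables (`03`),
the blocked treated-vs-control comparison (`04`), and power planning (`05`).

The same stages are scriptable from the shell:

```sh
immunogate simulate --panel myeloid --animals 5 --timepoints 5 --out-dir study/
immunogate gate --panel myeloid --input study/A1_T1.csv --sidecar study/samples.csv --out gated.csv
immunogate power --d 0.5 --power 0.8
```

## Layout

- `src/immunogate/panel_model.py` — panels, gating trees, config I/O
  (versioned YAML; built-ins under `src/immunogate/panels/`)
- `src/immunogate/gating.py` — transform, threshold estimation, gating engine
- `src/immunogate/quantify.py` — absolute counts and log scale
- `src/immunogate/variance.py` — η², variance components, MDC, sample size
- `src/immunogate/groups.py` — challenge-study statistics and endpoint rule
- `src/immunogate/synthetic.py` — ground-truth event/abundance generator
- `src/immunogate/fcs.py`, `io.py`, `cli.py` — formats, pipeline, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
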