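# Methods

This note records the models behind `immunogate`, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Panels and gating trees

A panel is a registry of 14 marker/detector assignments plus FSC/SSC. The
gating hierarchy is a tree whose root is the intact-cell scatter rectangle;
every other node carries a conjunction of per-channel threshold conditions
(`positive`/`negative` for one cut; `low`/`intermediate`/`high` for two
ordered cuts). This is a deliberate operationalization of manual 2-D gating:
free-hand polygons drawn in acquisition software are not reproducible from a
written description, whereas threshold conjunctions (rectangle gates in
transformed space) are deterministic, serializable, and reviewable by an
immunologist in the shipped YAML configs — the configs, not the code, are
the source of truth for gate logic.

The three built-in trees use standard murine marker logic (e.g. neutrophils
CD11b⁺Ly6G⁺Siglec-F⁻, classical monocytes Ly6C-high CCR2⁺, pDC
CD11c⁺B220⁺, naive T cells CD44⁻CD62L⁺, Th subsets by CXCR3/CCR4/CCR6,
Tregs CD25⁺ with TNF-RII or FOXP3). The myeloid tree reports 16 subset
variables, the lymphoid tree 26 (42 jointly, with unique names enforced
across the pair), the intracellular tree the 9 cytotoxic/regulatory
populations of the endpoint panel. Three acquired exhaustion markers
(TIM-3, PD1, CTLA4) stay registry-only because no unambiguous gate
definition was available; this is flagged in the config comments rather
than guessed. One detector (APC) carries a CD80/CD86 co-stim cocktail; the
registry lists the two reagents with distinguishing channel labels so the
one-detector-per-row invariant stays checkable.

## Transform and threshold placement

Fluorescence channels are transformed with `asinh(x / c)`, cofactor
`c = 150` (per-call override available); scatter stays linear. The
transform is invertible and maps 0 to 0.

Automatic thresholds are estimated per channel on the transformed pooled
events of a sample:

- **Mixture boundaries (default).** A Gaussian mixture with 2 components
  (3 for channels gated at three levels) is fitted with EM initialized at
  the most prominent histogram-density peaks — k-means initialization is
  unreliable when mode weights are very unequal (it splits the heavy mode),
  while peak-seeded EM lands in the separated optimum whenever one exists.
  Cuts are the equal-posterior boundaries between adjacent components.
  A separation guard rejects fits whose adjacent means are closer than 3
  pooled SDs (a split single Gaussian lands near 2.65, genuinely distinct
  expression levels far above it) and falls back to the quantile cut.
- **Kernel-density valley.** The minimum between the two most prominent KDE
  modes (prominence ≥ 2% of the density maximum). Selectable; it is not the
  default because for subsets occupying a fraction of a percent of events
  the minor mode's density is comparable to the sampling wiggle of the
  major mode.
- **Quantile fallback.** When a channel is effectively unimodal (marker
  absent, or guard fired) the cut is the 0.995 quantile of pooled events;
  the fallback is recorded in the threshold's `method_tag` and surfaced in
  logs. An unstained/control sample can instead supply the cut as its 0.99
  quantile.

Events exactly on a cut go to the positive/higher side (fixed convention).
Gating is executed top-down; membership masks are retained so containment
(child ⊆ parent) and partition properties are assertable on any run.
Fractions are reported per parent and per the hierarchy's denominator node
(the CD45⁺ gate in the peripheral panels, viable cells in the endpoint
panel).

## Absolute counts

The printed normalization in the source protocol reduces to a suspension
concentration times a dilution correction. With 50 µL blood stored in
500 µL diluent (the panel's defaults), the factor is 11:

    cells/µL blood = (gate count / acquired µL) × (blood + diluent) / blood

The dilution factor is exposed separately for audit. Whether "acquired
volume" denotes suspension or blood-equivalent volume is configurable via
the sample metadata, with suspension as default. The analysis scale is
`log10(x + 1)`; the +1 offset keeps zero counts representable, is recorded
in output metadata, and is configurable (a zero offset demands strictly
positive input).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
cytometry physics. Populations are defined by an expression signature
(channel → level among negative/low/intermediate/high) and a base
concentration in cells/µL of whole blood. Abundance noise is log-normal on
the log10 scale:

    log10 c_{a,t,p} = log10 c_p + u_{a,p} + v_{a,t,p},
    u ~ N(0, σ²_inter),  v ~ N(0, σ²_intra)

with `u` drawn once per animal (shared across its timepoints) and `v` fresh
per occasion. Defaults: 5 animals × 5 timepoints, σ_inter = 0.2,
σ_intra = 0.1, volumes 50 µL blood + 500 µL diluent with 100 µL of
suspension acquired. Event counts are multinomial over the occasion's
concentrations; by default the total is the cell yield implied by the
concentrations and volumes, which keeps realized and model concentrations
consistent. Fixing `events_per_sample` instead makes counts purely
compositional — fine for gating studies, wrong for absolute-count effect
studies (the challenge-design example uses volume-derived yields for
exactly this reason).

Intensities are log-normal per expression level, log10 locations
2.0 / 2.7 / 3.7 / 4.4 and scale 0.15. These place adjacent levels ≥ ~5–6 SD
apart after the asinh transform — the "well-separated" regime in which the
recovery guarantees (every subset count within 1% of total events;
concentrations within 5% relative for subsets ≥ 50 cells/µL) are stated.
Real marker distributions overlap far more; passing those checks
demonstrates the correctness of the gating/quantification machinery, not
expected accuracy on real blood. Likewise absent from the generator:
spillover by default (an optional mixing matrix exists as a stress option),
autofluorescence, acquisition drift, doublets, and staining variability.
A debris population (~2% of events) lies outside the scatter rectangle and
exercises the intact-cell gate. Default concentrations are
order-of-magnitude plausible for healthy adult mouse blood (a few thousand
leukocytes/µL, dendritic subsets rare) and deliberately not calibrated to
any measured dataset.

All randomness derives from one seed through per-(animal, occasion) spawned
streams, so identical configurations are byte-identical and single samples
are reproducible in isolation.

## Variance decomposition and its mapping

For one variable on a balanced A × T grid (log10 scale), the two-factor
decomposition without replication is computed from row and column means;
additivity `SS_animal + SS_time + SS_residual = SS_total` holds to floating
point, and η² shares sum to 1 within 1e-9. Unbalanced input is handled by
documented listwise dropping of incomplete timepoints. Constant variables
raise an explicit error rather than returning silent zeros.

Two mapping conventions exist, and the package exposes both:

- **Default (reporting convention):** η²_intra is the timepoint factor's
  share, η²_inter the animal factor's, and the residual is reported but
  unassigned — the layout used by the reference table, whose rows do not
  sum to 100%.
- **`intra_includes_residual`:** occasion noise that is not synchronized
  across animals lands almost entirely in the residual, not the time
  factor (E[SS_time] = (T−1)σ²_intra out of a total intra contribution of
  (AT−1)σ²_intra). When the quantity of interest is *total*
  within-animal variability — as in any comparison against the generator's
  σ²_intra — the residual belongs to the intra component, and the
  structural-ordering analyses use this mapping.

For recovering the generating (σ²_inter, σ²_intra) themselves, the package
provides method-of-moments components from the ANOVA mean squares.
A caution documented here because it is easy to trip over: *per-replicate*
shares built from either η² or the component estimates are biased at small
A (with A = 5 animals a generating share of 0.80 yields per-replicate means
around 0.74, a consequence of taking a ratio of few-degrees-of-freedom
estimates). Averaging the unbiased component estimates across replicate
studies first and forming shares from the pooled means removes the bias;
the acceptance script does exactly that over 500 studies.

## Detectable change and sample size

MDC = d × SD of the repeated measurements, default d = 0.5 (medium
effect), reported absolutely and as a percentage of the variable's own mean
by default; a leukocyte-mean denominator is available because the reference
table's caption wording suggests it, but the table's own arithmetic is only
consistent with the own-mean reading for the non-leukocyte rows. MDC and
the power computation are deliberately separate quantities: d × SD does not
involve power, so "80% power" enters only through `required_n`, which
inverts the exact two-sided two-sample noncentral-t power function
(normal-approximation result reported alongside). The two-sample design is
an assumption; the source protocol does not state the design behind its
power statement.

## Group statistics

The challenge-study comparison takes per-animal percent change from
baseline (zero baselines are flagged and excluded, never silently dropped;
raw follow-up values are an alternative mode recorded in the output), then
pooled-variance Student's t-tests per variable — pooled, not Welch, to
match the stated method, with Welch available. The additive block × group
ANOVA is computed from scratch (sums of squares against the residual, which
absorbs the interaction) and cross-checked against statsmodels in the
tests; when no variable shows a significant block effect the block is
dropped from downstream tests, and that decision is logged. No
multiple-testing correction is applied by default (matching the source
analysis); Benjamini–Hochberg is available opt-in. The variance-ratio
F-test puts the larger variance in the numerator and doubles the upper
tail. The endpoint rule is strict: any single welfare item at 4, or a
cumulative score strictly greater than 16; the result names the rule that
fired and is monotone in every item.

## Numerical and engineering choices

- Threshold estimation requires ≥ 50 events per channel (configurable).
- KDE valley input is strided down to ≤ 20k points; density is evaluated on
  a 512-point grid.
- GMM fits are deterministic given (data, seed): histogram-peak
  initialization, single EM run.
- η² residual shares are clipped into [0, 1] against subtraction noise
  before normalization.
- Degenerate t-tests (zero pooled variance) return p = 1 for equal means
  and p = 0 otherwise, documented rather than NaN.
- FCS support is intentionally minimal: single data set, list mode,
  float32 (plus common integer widths on read), $PnS/$PnN naming, strict
  $TOT-vs-decodable-event check. Written files round-trip bit-exactly.
- Problem sizes in the shipped checks — 10⁵-event recovery samples, 500
  replicate 5×5 studies, 10⁴ null simulations, 200 structural-ordering
  replicates — are the package's chosen defaults and complete in well
  under a minute each on one CPU.

## Known limitations

- Rectangle gates cannot express diagonal or curved boundaries; real
  panels with strongly correlated spillover may need the control-based
  thresholds or fixed cuts.
- No compensation/unmixing estimation, no doublet (FSC-H/FSC-A) gate, no
  batch alignment across samples.
- The variance machinery assumes a balanced complete design beyond the
  documented listwise handling; no REML/mixed-model path is provided.
- Synthetic validation bounds transfer to real data only to the extent the
  separability assumption holds; on real blood, threshold quality — not the
  engine — is the accuracy bottleneck.
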