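# Methods

This note documents the models and numerical choices behind each stage, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Calcium response analysis

**Model.** Each neuron contributes two 30 Hz time series: cell-body
fluorescence and surrounding background. The analysis assumes ROI pixel
averaging happened upstream and that the stimulus protocol (onset times,
5-s stimulus, 15-s inter-stimulus interval, 5 repetitions by default) is
known exactly. ΔF/F uses a single baseline F₀ per cell, the mean
background-subtracted signal over the 2–4 s windows before every onset; this
assumes no slow drift across the ~2-minute recording.

**Noise floor.** The "non-spike level" is not uniquely defined by the
protocol, so it is implemented as a robust SD — 1.4826 × median absolute
deviation of all ΔF/F samples outside stimulus windows — recomputed once
after masking samples more than twice the first estimate away from the
median. Robust estimation keeps spontaneous transients between stimuli from
inflating the floor; the re-masking pass shrinks a clean-Gaussian estimate by
about 5%, which is within the tolerance of every downstream rule. A constant
trace yields a zero floor with a warning, and any strictly positive
excursion then counts as an event.

**Decision rules (fixed, inclusive/strict exactly as stated).** A repetition
is positive when the window peak reaches 2 × noise (inclusive). ≥ 4/5
positives → LS, ≤ 1/5 → NS, otherwise excluded. The detection window is
exactly the stimulus window with no latency allowance; the response-magnitude
pre-window is [onset − 4 s, onset − 2 s]. Event counting for treatment
comparisons uses hysteresis: an event opens at 2 × noise and closes only
below 1 × noise, so a double peak that never dips below the floor counts
once.

## Synthetic calcium cohorts

Transients rise instantaneously at a uniform-random latency within the first
second of a designed-positive stimulus window and decay exponentially
(τ = 1 s default); peak amplitude is `transient_amplitude_snr × noise_sd`
(5 × 0.02 ΔF/F by default), with a 0.1 ΔF/F amplitude floor when
`noise_sd = 0` so noiseless designs still carry visible transients.

The additive noise is Gaussian with its excursions truncated at
1.8 × noise_sd. The truncation emulates the sub-Gaussian tails of
shot noise after the temporal filtering of indicator dynamics and imaging
optics, and it is what makes a designed response count a well-defined ground
truth: with heavy-tailed per-frame noise, the maximum of ~150 frames in a
5-s window would exceed the 2 × SD event threshold almost surely, and no
threshold detector could recover the design. Truncation leaves the
MAD-based noise estimate unbiased and the marginal SD within 2% of
`noise_sd`. Consequences worth knowing: recovery tests on this generator
validate the decision rules and their boundary behavior, not robustness to
heavy-tailed or drifting noise, which real recordings do have.

The canonical 83-trace fixture designs 41 cells with ≥ 4 positives, 22 with
≤ 1 and 20 with 2–3, at amplitude SNR 20, so the classifier's retention of
63 cells is a design property, not a statistical outcome.

## Synthetic expression cohorts

Counts are negative-binomial (dispersion 0.2) around per-gene log-normal
base means scaled to an expected library of 5 × 10⁵ fragments, with
log-normal per-cell size factors (σ = 0.3). Gene lengths are uniform on
[500, 10,000] bp; ~95% of genes are protein-coding. The generator emits
counts plus lengths so the FPKM stage is exercised rather than bypassed.

*Planted differential genes* (100 by default, alternating up/down at
log₂FC = 3 in LS cells) are drawn from genes with base expression of at
least 40 FPKM — below that, a fold change cannot exceed the 2.5 decision
bound on the pseudocounted (FPKM + 1) scale — and with a per-gene count cap
chosen so the up-regulated half adds at most 10% of extra library mass.
Without the cap, planted mass inflates LS library sizes and compositionally
shrinks every measured FPKM fold change; both constraints are statements
about what "a planted DE gene" means for an FPKM-based statistic, not
tuning knobs.

*Planted modules* (5 × 30 genes) share a per-module latent factor with
loadings uniform on [0.8, 1.2]; the trait module's factor is a noisy copy
(SD 0.5) of the standardized LS indicator. *Cell types*: each cell is
excitatory (80%) or inhibitory, expressing only its own neuron marker pair;
glial markers are zero in all cells except designed doublets, which
co-express the full astrocyte, oligodendrocyte, or both-neuron marker sets
(every designed marker forced ≥ 1 fragment). *Designed metric failures*
receive cDNA in [300, 900] pg/μL, mitochondrial fraction in [0.30, 0.50],
or have all but 800 genes silenced. A block of 27 real channel/receptor
symbols (Grin1, Gabra1, Atp1a1, …) is carried in every cohort so the panel
stage resolves against synthetic matrices.

The canonical 63-cell fixture plants 2 cDNA, 2 mito and 1 low-gene failure
and 4 astro/oligo + 1 ex–in doublets, all on NS-labeled cells, so the staged
QC yields 58 → 53 cells with a 41 LS / 12 NS final split by design. The
fixture follows the stage-resolved failure tallies (2 + 2 + 1).

What the generator does **not** emulate: gene–gene correlation outside
planted modules, batch effects, dropout beyond NB sampling, ambient RNA,
length-coupled coverage bias, and any coupling between calcium phenotype and
expression other than the planted DE genes and trait module.

## Expression QC

Stage order is fixed: FPKM → gene filter → metric filters (cDNA, then mito,
then detected genes; a cell is removed at its first failing stage) → doublet
removal. Metric thresholds are strict as worded (< 1,000 pg/μL, > 25%,
< 1,000 genes); gene detection is inclusive (≥ 1 FPKM). The "detected at
≥ 1 FPKM across all samples" gene rule is read as detected in *at least one*
sample (`mode="any"`), since the in-every-sample reading empties plate-based
matrices; `mode="all"` is available. The detected-gene metric counts
protein-coding genes, i.e. it is evaluated after the biotype restriction.
Absent doublet-marker genes are treated as uniformly zero with a warning.
Cohort correlations are Pearson on log₂(FPKM + 1); the log transform is a
package choice to stabilize heavy-tailed FPKM values.

## Differential expression

The statistic is deliberately simple and fully specified: fold change on
pseudocounted FPKM means, Welch's t on log₂(FPKM + 1), BH across all tested
genes. Pseudocount 1 bounds both quantities at zero expression. Degenerate
genes (zero variance in both groups, equal means) get p = 1. Genes are
called at p_adj < 0.05 and |log₂FC| > 2.5 and ranked by descending log₂FC
with ties broken by ascending p then gene id. A negative-binomial Wald fit
(pydeseq2) applied to a planted cohort under the same decision rule recovers
the same gene set in the test suite; exact p-value replication of count
models is a non-goal.

## Co-expression modules

Unsigned soft adjacency |r|^β on log₂(FPKM + 1) with β = 6 (a standard
default; the choice is exposed, and no scale-free fit is attempted), optional
topological-overlap transform, UPGMA on 1 − a. Dynamic tree cutting is
replaced by a scanned fixed-height cut: candidate cuts at midpoints between
successive merge heights, capped at 99% of the top height so an unstructured
tree yields no module; the cut maximizing the number of clusters of size
≥ 10 wins, with ties resolved toward fewer grey (unassigned) genes and then
the lower cut. Modules whose eigengenes correlate above 0.75 are merged
iteratively, strongest pair first. Eigengenes are first principal components
of gene-standardized log expression, unit variance, signed to correlate
non-negatively with the module mean profile; a singular module falls back to
its standardized mean. Module–trait analysis appends the 0/1 LS indicator as
module "white" and reports Pearson r with exact t-transform p-values
(n − 2 df). Planted-partition recovery (ARI ≥ 0.8, trait module top-ranked)
validates the simplified cut on cohorts of the default size; behavior on
real dendrograms with nested structure will differ from published dynamic
cutting.

Colors are assigned by decreasing module size from a fixed palette; "grey"
is reserved for unassigned genes and "white" for the trait.

## Panel statistics

Default panels are symbol-prefix tables (Atp1a*/Atp1b*, Scn*, Kcn*, Cacn*,
Gria*, Grid*, Grik*, Grin*, Gabr*, Chrn*, Htr*, Grm*, Gabbr*, Chrm*, Drd*,
Cnr*) resolved against the matrix; explicit (panel, gene) TSVs override
them. The tested statistic is the per-cell sum of member-gene FPKM (per-gene
mode available); groups are compared with Welch's t (Satterthwaite df), with
significance stars at p < 0.05 / 0.01 / 0.001. Identical constant groups
return p = 1 by convention. Paired before/after event-count comparisons use
the paired t-test; an all-zero difference vector gives p = 1, a constant
non-zero one is reported as a sign-determined effect with a warning. Raw
two-sided p-values are reported; no cross-panel correction is applied by
default since panels overlap.

## Pipeline

`run-all` executes simulate → calcium → QC → DE → modules → panels with
labels joined on cell id (calcium labels take precedence over metadata
labels). In simulation mode the two canonical fixtures share an id space by
construction: the first 63 recorded cells are the sequencing cohort.
All stage thresholds are echoed into `run_report.json`; identical seeds give
byte-identical reports. DE and module stages are skipped with a note when a
group has fewer than 2 cells or fewer DEGs than the minimum module size.

## Problem sizes and determinism

Default test-suite problem sizes: 83-trace and 63-cell fixtures,
2,000-gene cohorts (10,000 genes for null-calibration checks), 10,000
replicates for type-I-error checks. Every stochastic test and the acceptance
script run from fixed or caller-supplied seeds; the fixture cohort counts
are design properties independent of the seed.

## Known limitations

- The response classifier has no latency allowance and no drift correction;
  slow baseline drift would bias F₀ and the noise floor.
- FPKM-based testing inherits compositional effects; no size-factor model is
  fitted.
- The simplified module cut assumes modules separate at a common height;
  nested module structure is out of reach by design.
- Panel membership by prefix can over-resolve (e.g. Kcnh vs Kcnj families);
  curated lists should be supplied for real analyses.
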