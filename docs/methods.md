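# Methods

`drugpath` implements a ten-step workflow that turns per-well summaries of
a high-content small-molecule screen into pathway-interactome predictions,
plus a companion analysis of cell-size-control strategy.  This note records
the statistical model, the choices made where the design was genuinely open,
and what the synthetic data can and cannot show.

## Screen model and normalization

The unit of observation is a well: one cell line, one technical replicate,
one condition (an inhibitor or an `untreated`/`vehicle` control), summarized
into ten homeostatic parameters — relative survival, apoptotic fraction, the
three cell-cycle phase fractions, and five FSC-A size readouts (all cells,
per phase, apoptotic).  Fractions are stored in [0, 1].

Raw values are first divided by the same-plate, same-cell-line control mean
(vehicle/DMSO by default; untreated is equivalent by flag, since the two
control kinds are interchangeable in this design).  Normalized values are
then standardized per process, `z = (x − μ)/σ`, with μ and σ (sample, n−1
estimator) taken over **all conditions × all replicates of one cell line**.
This scoping is the narrowest reading of "all values of a cellular process"
that keeps lines with different dynamic ranges comparable; per-group and
global scoping are selectable (`zscore(..., scope=...)`).  Δz-scores subtract
the control condition's z from every inhibitor z, sample-wise.

Two consequences of screen-internal standardization are worth knowing:

* σ is estimated from the full condition population, so strong real effects
  inflate it and attenuate every z.  The effect is ~5% in an 81-inhibitor
  screen with a single strong hit and grows with hit density.
* dividing by a noisy control mean (n wells) inflates the normalized-scale
  spread by √(1 + 1/n).  The generator injects planted effects with this
  factor included, so "effect size in z-units" means z-units of the realized
  population.

## Quality control

Replicate concordance (Pearson r of z between replicate pairs over all
conditions, per cell line and process), intra-plate statistics (median and
SEM of z per sample), and inter-plate alignment (per-plate z medians and the
largest pairwise gap).  Default pass thresholds — r ≥ 0.8 and max |Δmedian|
≤ 0.5 — are configuration values, not measured constants: the reference
analysis reports only qualitative concordance.  Note that replicate
concordance measures *shared biological signal*; a screen of inert compounds
has r ≈ 0 regardless of assay quality.

## Hit calling

Per inhibitor × process × unordered group pair, a two-sample t-test compares
group z-scores.  The cited upstream analysis used paired t-tests, but group
members (cell lines × replicates) are unpaired and unequal in general, so
the default here is Welch's test with a pooled-variance option exposed;
neither is claimed to be the original's exact variant.  p-values are
Benjamini–Hochberg adjusted within one (process, comparison) family across
inhibitors (configurable to a global family).  A hit requires adjusted
p < 0.01 **and** a group mean z beyond the noise cutoff (default |z| ≥ 2;
the reference shows but does not quantify its noise band) in an eligible
direction.  For the apoptosis readout only increases are eligible — a
decrease below the already-low apoptotic baseline is not a scorable
response.  ESC and IPSC samples can be consolidated into one "ESC/IPSC"
group before testing, which is the default in the pipeline because the two
populations cluster together in every process.

Hit calling on this design controls false positives conservatively: on
simulated null screens the hit fraction at α = 0.01 is far below 1% because
the BH step and the noise cutoff compound.

## Clustering

Sample similarity is the Pearson-correlation matrix over condition profiles
(optionally restricted to significant hits).  The dendrogram uses complete
linkage on Euclidean distances **between rows of the Spearman-correlation
matrix** — i.e. two samples are close when they correlate with all samples
similarly; being rank-based it is invariant to monotone per-sample
transforms.  PCA operates on the transposed z-matrix (samples =
observations) with condition-mean centering; component signs are fixed by
making each component's largest-magnitude loading positive.

## Target expansion and ranking

Every effective inhibitor fans out to its validated targets with maximal
effective concentration ≤ 5 µM (inclusive boundary).  The gene-level rank
metric defaults to the difference of group mean Δz (first group minus
second), so the head of the list reads "stronger response in ESC/IPSC".
Because the sign mixes response direction with group, an inhibitor that
*lowers* a readout in one group lands at the same end as one that *raises*
it in the other — a property inherited from the method, and the reason the
recovery simulations plant same-direction effects.  When several inhibitors
share a target, contributions collapse by the signed value of the largest
|Δz| (ties: positive sign, then inhibitor name); `mean` and `sum` are
first-class alternatives because the original collapse rule is not
documented anywhere.  Output ordering is metric-descending with a
lexicographic gene tiebreak.

## Pre-ranked GSEA

Authored from scratch.  The running sum over the ranked universe increments
at members by |metric|^p normalized over in-set weights (p = 1 default;
p = 0 exposed for oracle tests) and decrements at non-members by 1/(N−Nh);
ES is the extremum of largest magnitude (first occurrence on ties).  The
leading edge takes members at or before the extremum (ES > 0) or strictly
after it (ES < 0).  The null permutes set membership over the universe
preserving set size — the standard null for pre-ranked mode, where no
sample-level phenotype exists to permute — with 1000 permutations by
default.  NES divides ES by the mean magnitude of same-sign null ES;
nominal p is the same-sign tail fraction (0 with an underflow flag when the
observed ES beats every null); FDR q is the canonical NES-ratio estimate
against the pooled normalized null, clipped to [0, 1].  Sets are restricted
to the ranked universe and size-filtered (3–500 after intersection).
Retention threshold: FDR < 0.25.

## Enrichment map

Nodes are FDR-passing sets; node group attribution follows the NES sign
(positive → first group).  Edges connect sets whose overlap coefficient
|A∩B|/min(|A|,|B|) — computed on the universe-intersected member lists that
GSEA actually scored — reaches 0.05.  An *interactome* is a connected
component; *universal* if it mixes group attributions, otherwise
group-specific.  The headline fraction counts nodes in universal components
over all nodes.  Exports: GraphML (attributes preserved) and SIF.

## Size control

FSC-A readouts are mapped to sphere geometry; the default convention treats
FSC-A as proportional to cross-sectional area (r ∝ √readout), with diameter
and volume conventions selectable since the true transform of the cytometer
is not identifiable from summary data.  Classification by slope sign is
convention-robust on noise-free constructions.  For a sphere SA/V·r = 3
identically — used as an internal consistency check on every record.

Added volume ΔV = V(G2) − V(G1) is regressed (OLS) on birth volume V(G1)
across condition means; slope +1 ⇒ timer (fixed fold-growth), 0 ⇒ adder
(fixed added volume), −1 ⇒ sizer (fixed division volume).  The qualifier
bands |slope − nearest| ≤ 0.1 ("perfect") and ≤ 0.25 ("near") are package
conventions.  Supporting analyses: OLS slope + Pearson r of G2 on G1 sizes
(a "normal doubling" flag near slope +1), per-group added-size variance with
a two-sided F ratio (a sizer's added-size variance carries the full birth
spread on top of noise, an adder's does not), and treated-vs-control shifts
in mean G1 SA/V with Welch tests (shrinking radius by f multiplies SA/V by
1/f exactly).

Note that on a screen with no planted size structure, per-phase size
readouts are independent noise, and regressing ΔV on V(G1) then yields a
slope near −1 by construction (regression-to-the-mean); a real sizer signal
is distinguishable from this artifact only through the G1–G2 correlation,
which the pipeline reports alongside.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study design: 3 groups × 3 cell lines × 3
technical replicates, 81 inhibitors plus vehicle/untreated controls at one
concentration, ten parameters per well, 96-well plates holding one cell line
with fixed control positions (2 wells per control kind by default,
configurable).  Baselines are Gaussian on the normalized scale with
process-typical means (survival 1.0; apoptotic fraction 0.05; G1/S/G2M
fractions 0.40/0.30/0.20; sizes in arbitrary FSC-A units around 45–55k);
z-scoring removes location and scale, so these choices affect realism, not
downstream statistics.  Multiplicative per-cell-line and per-plate factors
(lognormal, sd 0.05) add plate-structured noise that normalization must
remove.  Planted effects are group-restricted mean shifts in realized
z-units.  Fractions are clipped to [0, 1] and the cell-cycle trio rescaled
to sum ≤ 1 when extreme draws violate measurement constraints.

Not emulated: optical/edge artifacts, single-cell event distributions,
dose–response structure, correlated process readouts (e.g. survival vs
apoptosis), and non-Gaussian tails.  Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure under the stated design — not performance on any real screen.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` with explicit seeds;
with `noise_sd = 0` every generator is a deterministic function of its
configuration.  Linkage ties resolve to the lowest-index pair (scipy
convention); ranked-list and aggregation ties break lexicographically; PCA
signs are fixed as above; JSON artifacts are written with sorted keys and no
timestamps, so identical config + seed reproduces byte-identical artifact
trees (verified by checksum in the pipeline manifest).  Degenerate inputs
are reported as missing rather than coerced: constant vectors give NaN
correlations, zero-variance-in-both-groups t-tests give NaN p, sets without
same-sign null ES carry a flag instead of a q-value.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
null-screen error control uses 200 screens of 20 inhibitors; planted-effect
recovery uses 50–60 screens of 81 inhibitors; the end-to-end recovery
scenario uses an 81-inhibitor screen with ten planted effects, a 150-gene
universe and 1000 permutations; size-model identities use populations of
200.  These sizes were chosen so the whole battery completes in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

* The original screen data this workflow was designed around are not
  publicly deposited, so its published percentages (universal-interactome
  fractions per process) are not reproducible here; the pipeline computes
  the same quantities on synthetic screens instead.
* The exact pairing scheme of the upstream t-tests, the Δz collapse rule,
  the GSEA weighting, and the FSC-A→geometry transform are not documented
  upstream; each is implemented with a declared default and exposed
  alternatives rather than a claim of exact reproduction.
* Gene symbols are taken as given (upper-cased, whitespace-stripped); no
  alias or identifier resolution is attempted.
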