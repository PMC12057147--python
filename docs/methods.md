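# Methods

## The scoring model

LC8 (DYNLL1) binds client motifs as an added β-strand that pairs with the
β3 strand of one protomer, in either of the two symmetric grooves of the
dimer. The pipeline therefore treats the confidence a structure predictor
assigns to exactly that interface as the signal, and everything else
(global fold confidence, the client's flanks) as background. Five scores
are computed per predicted structure:

- **confidence** — the multimer ranking score, 0.2·pTM + 0.8·ipTM. The
  identity is validated at parse time (tolerance 1e−6).
- **interface pLDDT** — mean per-residue pLDDT over the bound client
  region plus the β3 residues in contact with it. The bound region is the
  set of client residues whose Cα lies within the contact cutoff of any
  β3 Cα of either protomer.
- **LtoP / PtoL** — mean predicted aligned error of the contacting β3
  residues aligned on the bound client residues, and the transpose block.
  PAE is directional; the β3 side is usually the calmer one because LC8
  is folded while the client is disordered, but both directions carry
  independent information and are kept separate.
- **dimer PAE** — mean PAE (both directions) over inter-protomer Cα
  pairs within the contact cutoff, excluding each protomer's last three
  (floppy tail) residues. This monitors whether the LC8 scaffold itself
  was predicted soundly; a bad dimer invalidates the groove scores.

Unbound predictions (empty bound region) are scored, not discarded: the
client-wide span and the full β3 set substitute for the missing
interface, and the result is flagged `unbound`. Nonbinders must keep
their poor scores, otherwise classifier training would see only
successes. For 2-client structures each groove is scored and the groove
values averaged, giving one value per score per structure.

Run-level scores come from the structure maximising interface pLDDT (not
rank 1: the ranking confidence is the weakest discriminator of the five).
Matched 1-client and 2-client runs of the same window are joined on
window identity into a 10-parameter vector.

### Geometry parameters

| parameter | default | meaning |
|---|---|---|
| `beta3_span` | residues 60–67 (1-based LC8 numbering) | β3 strand; brackets the G63 landmark |
| `g63_residue` | 63 | groove landmark defining motif position 0 |
| `contact_cutoff` | 8.0 Å | Cα–Cα distance defining contacts |
| `cterm_exclude` | 3 residues | tail dropped from each protomer for the dimer PAE |

The β3 span and cutoffs are configuration, recorded with outputs; only
Cα atoms are used, which keeps synthetic fixtures exact and real input
requirements minimal. The packaged LC8 sequence is human DYNLL1 (89
residues, G at position 63); the ortholog used per run is caller-chosen
and recorded in run metadata.

## Classification

A window is a binder iff **all ten** conditions hold simultaneously —
confidence and pLDDT above their cuts, the three PAEs below, for both
client counts, with strict inequalities. Conjunction is the only
combination rule consistent with the exclusive/inclusive behaviour of the
shipped sets, one tuned for low false positives (site discovery) and one
for low false negatives (exhaustive mapping). Note the inclusive set is
not uniformly looser: its 2-client PtoL cut is stricter.

### Threshold training

Retraining uses a genetic algorithm over the ten cut values:

| hyperparameter | default |
|---|---|
| population | 200 |
| generations | 300 |
| mutation | Gaussian, sd = 5 % of each parameter's observed range, per-gene rate 0.4 |
| crossover | uniform, rate 0.7 |
| selection | tournament of 3, elitism 5 % |

Individuals are selected by Youden's J (TPR − FPR) — the frontier target
(AUROC) is a property of the whole search, not of one individual — while
*every* evaluated set contributes one (FPR, TPR) point to an archive. The
reported ROC is the Pareto frontier of that archive plus the corners, and
its area is the conservative lower staircase, so the AUROC is a lower
bound of what the composite thresholds can attain. The archive is
pre-seeded with the exhaustive single-parameter ROC of every parameter
(each cut embedded in an otherwise fully permissive set), which
guarantees structurally that the composite frontier AUROC is at least the
best single-parameter AUROC. Two best-set extraction rules are exposed:
maximal J (default) and maximal accuracy (used for learning curves).

Because exhaustive sweeps place candidate cuts exactly on observed
values, the selected set would otherwise hug training-data edges and
misclassify held-out samples just beyond the training extremes. The
returned set therefore gets a *margin-midpoint refinement*: each cut is
moved to the midpoint between the nearest passing and nearest failing
observed value, which provably changes no training prediction and is the
max-margin choice among equivalent cuts.

Runs are exactly reproducible given the seed. Learning curves use
stratified random splits, train on a fraction, and report the held-out
accuracy of the accuracy-maximal frontier set (mean ± sd over
iterations).

## Affinity estimation and filtering

Two shipped linear inversions convert a score into a rough Kd (µM):
TQT-anchored motifs use the best-structure 1-client dimer PAE,
Kd = (x − 0.89)/0.0035; other anchors use the across-structure mean of
the 1-client PtoL PAE, Kd = (x − 4.45)/0.135. Linear inversion inevitably
produces negative values for very good scores; predictions below 1 µM
are floored at 1 µM (the floor also covers the sub-µM range, where the
calibration has no resolution). Candidate sites with predicted Kd above
40 µM are discarded rather than extrapolated — the calibration data
contain essentially no weaker affinities — and sites whose anchor falls
inside a user-supplied structured interval (BED-like, 0-based half-open)
are discarded because LC8 binds only disordered regions.

Fits are ordinary least squares on the linear Kd scale, matching the
form of the shipped inversions (a log-scale fit would be the
conventional alternative; the inversion formulas are linear, so the
calibration is kept linear). Multiple-testing correction offers
Bonferroni and Benjamini–Hochberg (via statsmodels). Adjusted mutual
information uses the max-entropy normalisation,
AMI = (MI − E[MI]) / (max(H(x), H(y)) − E[MI]) with the hypergeometric
expected MI (via scikit-learn, `average_method="max"`); continuous
variables are binned with three affinity edge sets (full and half decades
over 0–100 µM) crossed with three score binnings (geometric, linear,
quantile; 6 bins by default), and the grid maximum is the headline
statistic. A variable collapsing into a single bin yields AMI 0 with a
warning (no information can be shared; conventions differ here).
Sub-dataset selection uses a small expression language over anchor class
and window length (`TQT&len=14`, `!TQT`, `len<18`, `||` for OR).

The success rate of a run pair — the fraction of rank-paired structures
passing a threshold set — treats the prediction ensemble as a tiny
equilibrium ensemble; the pseudo-Kd (#unbound²/#bound) is provided but is
undefined when nothing is bound, which at 25–50 "molecules" per run
happens often enough that the success rate is the routine statistic.

## Evidence ledger

Hypothesis comparisons are expressed in decibels, 10·log₁₀ of a
likelihood ratio. Independent evidence adds; priors are additive offsets;
a third pairwise comparison sharing a base hypothesis follows by
subtraction. Totals are exact sums internally; rendering rounds to whole
dB. The packaged nine-item example ledger (YAML, data not code) scores
observations from an LC8 binder/nonbinder screen against three
hypotheses about the structure predictor — memorised structures (Hs),
learned the natural energy function (Hn), learned an inaccurate energy
function sharing the natural minima (Hi).

## Synthetic fixtures

The generator produces parseable prediction directories with exactly
controllable content: an idealised deterministic Cα trace for the LC8
dimer (straight chains 5 Å apart, 3.8 Å Cα spacing, with the true β3/G63
landmarks), a client trace placed at a configurable groove distance
(default 5 Å; 50 Å for unbound fixtures), block-structured PAE matrices
(interface blocks at configured means over a uniform background), a
constant pLDDT per structure, and pTM = ipTM chosen so the confidence
identity holds. In no-noise mode every extracted score equals its
configured mean to machine precision, which is what the round-trip tests
assert.

Labeled score datasets are class-conditional Gaussians clipped to the
physical ranges, with defaults chosen so that single-parameter AUROCs
fall in the high-0.8s to mid-0.9s — confident but imperfect separation,
binders scoring well and nonbinders poorly. A `separation` knob scales
the class gap (0 = null data), `sd_scale` scales the spread (used to
build cleanly separable test conditions without pushing means out of
range, where clipping would collide both classes onto a boundary value),
and an optional bimodal mode mixes a nonbinder-like component into the
binders' 1-client scores, mimicking weak binders whose half-bound
predictions look unconvincing.

What the fixtures deliberately do not emulate: realistic coordinates,
PAE textures beyond block means, correlations between the five scores,
or predictor failure modes. Passing tests therefore demonstrate the
correctness of extraction, linking, training and statistics — not that
any particular real predictor separates binders from nonbinders.

## Problem sizes and numerical choices

The test suite trains GAs at population 20–60 for 5–40 generations on
60–2000-vector datasets, which preserves every structural property of
the full-size configuration at a few seconds per run; the null-data
check uses 1000 vectors per class so that the frontier's overfitting
bias (~√(log K / n) for K archived evaluations) stays well inside the
assertion band. Ties in best-structure selection resolve to the lower
rank; anchor-distance ties resolve to the lower client index; ROC areas
always use the lower staircase. Degenerate inputs (single-class training
data, empty runs, constant predictors, single-bin collapses) raise
errors or defined results as documented per function rather than
propagating NaNs.

## Known limitations

- The shipped affinity calibrations carry the modest fit quality of
  their source data; predictions are order-of-magnitude guides, not
  measurements.
- The β3 span and contact cutoff are fixed configuration; real grooves
  flex, and per-structure adaptive interface definitions are not
  attempted.
- 2-client groove averaging discards per-groove asymmetry.
- The GA explores a 10-dimensional cut space non-exhaustively; the
  reported AUROC is a lower bound by construction.
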