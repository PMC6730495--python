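# Methods

`neurostage` re-implements, as a tested and reusable pipeline, a staging
analysis for Alzheimer's disease that combines resting-state functional
connectivity graph measures with structural morphometry to classify four
diagnostic groups — AD, MCI converters (MCI-C), MCI non-converters
(MCI-NC) and healthy controls (HC) — and to identify hub regions of the
functional brain network.  The original analysis was performed on
restricted clinical scans; this package pairs the analysis code with a
synthetic cohort generator so that every stage is exercised end to end
on data whose ground truth is known.

## Functional connectivity and thresholding

Each subject's functional network is the matrix of Pearson correlations
between all pairs of ROI time series (160 regions, 140 volumes at full
scale).  Binary topologies comparable across subjects are obtained by
thresholding at a network *density* (cost): the K = round(d·N(N−1)/2)
strongest edges are kept.  The subject-specific optimal density
maximizes global cost efficiency,

    GCE(d) = E_glob(d) − d,

where E_glob is the mean inverse shortest-path length (1/∞ = 0 for
disconnected pairs), and the cohort is binarized at the arithmetic mean
of per-subject optima (the reference analysis reports 19.2%).  Choices
made where the procedure was underdetermined:

* the threshold is a density/cost, not a correlation cutoff — this is
  the only reading consistent with the cost-efficiency framing;
* the GCE density grid is 0.01–0.50 in steps of 0.01 (no grid is
  prescribed); grid points whose edge budget rounds to zero are skipped;
* per-subject optima are averaged raw, without rounding;
* negative correlations rank below all positive ones and enter only
  when the edge budget exceeds the positive-edge count: binary
  topological measures assume positive association;
* argmax ties break toward the lower density; edge-rank ties break by
  (weight descending, lexicographic node pair), which makes binarization
  deterministic and edge sets nested across densities.

## Graph measures

Ten local measures per node (betweenness centrality as raw
unordered-pair counts; clustering coefficient; nodal path length;
Newman and Louvain per-node modularity contributions; eccentricity;
eigenvector centrality, unit L2 norm; rich-club coefficient at the
node's own degree; subgraph centrality; participation coefficient) and
thirteen global measures (assortativity; mean clustering;
characteristic path length; Newman and Louvain modularity Q; maximum
GCE and the cost at the maximum; density; global efficiency; radius;
diameter; transitivity; small-worldness σ).

Three local measures have no canonical nodal form and are defined here
explicitly (the choice is recorded in the output metadata rather than
asserted as anyone else's intent):

* *nodal path length* — mean shortest-path hops from the node to all
  reachable nodes;
* *community-structure contributions* — the per-node share
  q_i = Σ_j [a_ij − k_i k_j/2m]·δ(c_i,c_j)/2m of the partition's
  modularity, which sums to Q exactly; a raw module label is not a
  comparable scalar feature, the contribution is;
* *rich-club at degree* — φ(k_i), the density of the subgraph of nodes
  with degree > k_i, with φ = 1 when that subgraph has fewer than two
  nodes.

The Newman partition is the leading-eigenvector spectral method,
implemented as recursive bisection of the (generalized) modularity
matrix with dense eigendecompositions — deterministic and robust at
atlas scale.  Louvain is the seeded greedy multilevel algorithm run 10
times, keeping the max-Q partition.  The participation coefficient uses
the Louvain partition.  Small-worldness is
σ = (C/C_null)/(L/L_null) against a seeded ensemble of
degree-preserving rewired graphs (10·|E| double-edge-swap attempts per
null, 20 nulls by default; 10 in the reduced-scale profile).
Disconnected graphs: efficiency-type measures use 1/∞ = 0; path-based
measures are evaluated over reachable pairs on the largest component
with a logged warning.  Degenerate assortativity (regular graphs)
surfaces as NaN, never as a silent zero.

## Morphometry and fusion

The structural block is 5 measures × 148 cortical areas plus 34
subcortical volumes (774 values).  Volumes are divided by the subject's
estimated intracranial volume and areas by the total area of the same
hemisphere; thickness and curvature are not anatomically normalized.
Each subject's features are then normalized individually.  The original
description does not state whether subject-wise normalization was per
modality or across the whole vector; here it is a z-score within each
modality block (rs-fMRI graph features; sMRI features), which keeps the
two modalities commensurate before fusion, and the choice is recorded
in the feature matrix's normalization record.

## Feature selection

**MRMR** scores a feature set S against class labels c as

    (1/|S|)  Σ_{fi∈S} I(fi; c)  −  (1/|S|²) Σ_{fi,fj∈S} I(fi; fj)

with plug-in mutual information (bits) on 3-bin discretized features
(bin edges μ±σ from training data only; test values are binned with the
train statistics).  The redundancy sum runs over all ordered pairs
including i = j, exactly as the criterion is printed; some MRMR
variants normalize by |S|(|S|−1) instead — that variant is *not*
silently substituted.  Ranking is greedy: the first feature maximizes
relevance, each next feature maximizes the set score, ties break toward
the lower column index.

**SFC** is the filter+wrapper combination: rank all features by MRMR,
then evaluate the inner-CV accuracy of the classifier on each ranked
prefix k = 1..k_max (default 50) and keep the best prefix, smallest on
ties.  Whether the original wrapper used best-prefix or
add-if-improves is not recoverable; best-prefix is the default because
it is deterministic and reproduces small selected-subset sizes.

**DCA** is the fusion alternative: each modality block is projected
onto the whitened signal subspace of its between-class scatter
(dimension ≤ classes − 1), the projected blocks are aligned by an SVD
of their cross-covariance so corresponding components are maximally
correlated across modalities, and the aligned blocks are fused by
elementwise summation (concatenation available).

## Classification protocol

Per diagnostic group, 80% of subjects form the train/cross-validation
set and 20% an untouched test set (5 outer folds); the train set is
split 80/20 again into 5 inner folds for the SFC wrapper.  Per-group
counts use round-half-up, which reproduces the canonical partition
sizes for group sizes 34/25/69/49: outer train/test 141/36 with
per-group test counts 7/5/14/10, inner train/validation 113/28 with
per-group validation counts 5/4/11/8.  (The published description
prints an inner-validation total of 26 alongside per-group counts that
sum to 28; the per-group counts are internally consistent with
141 − 113 and are the ones reproduced here.)

Group imbalance is neutralized by balanced subsampling: each group
contributes exactly as many training subjects as the smallest group,
redrawn with an independent sub-seed for each repetition (1,000 in the
full protocol; 100 in the reduced test profile — accuracy differs by
well under the repetition noise).  Feature selection runs once per
outer fold on outer-train subjects only and is shared across
repetitions.  The classifier is a one-vs-one RBF-kernel SVM with C = 1
and γ = 1/n_features (no kernel or cost is prescribed by the reference;
all are exposed in the configuration).  The metric panel reports the
k×k confusion matrix, per-class sensitivity/specificity/PPV, one-vs-rest
AUC from aggregated decision values, per-class accuracy (the class's
recall — the reading under which published per-class accuracy equals
sensitivity), and overall accuracy (trace/total).  One-way ANOVA on
selected features reports raw, unadjusted p-values.

## Hub detection

A hub is a node whose betweenness centrality or eigenvector centrality
strictly exceeds the across-node mean plus two population standard
deviations.  Flags are computed at 21 densities (0.10–0.30, step 0.01)
and a node is reported as a hub when flagged at strictly more than 85%
of thresholds (≥ 18 of 21).  Group-level hubs are computed on the
group's mean weighted network (deterministic, one hub set per group);
a per-subject voting mode is available as a configuration switch since
the aggregation is not prescribed.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, not the
biology:

* **Networks** — per-group stochastic block models.  The default
  full-scale configuration uses contiguous modules of ~20 regions with
  group-graded probabilities (HC p_within 0.60/p_between 0.05 down to
  AD 0.45/0.08), the disconnection-syndrome direction.
* **Time series** — T i.i.d. rows of N(0, Σ) with
  Σ = I + ρ·A/(λ_max(A)+ε), positive definite for any symmetric
  nonnegative A and 0 ≤ ρ < 1, with a monotone link between edges and
  correlations.  Rows are i.i.d.: the generator makes no claim of
  temporal autocorrelation fidelity after band-pass filtering.
* **Morphometry** — region value = population mean + group shift ×
  population SD + N(0, SD²·heterogeneity).  Population means/SDs are
  fixture constants at plausible scales (e.g. thickness 2.5 ± 0.25 mm,
  eTIV 1.5×10⁶ mm³); units are nominal and exist to exercise
  normalization.  The MCI groups' planted-feature variance is inflated
  by `mci_heterogeneity` (default 4× in the strong-effect profile), so
  planted values cluster in AD/HC and scatter in MCI.
* **Hubs** — nodes listed in `hub_spec` receive additional random edges
  until their degree exceeds the remaining nodes' mean by 3 SDs, and
  their incident edges carry a `hub_strength` (default 1.5×) coupling
  multiplier.  The strength grading is essential, not cosmetic: under
  the covariance model every edge has the identical correlation, so
  thresholding below the graph's own density keeps an arbitrary
  tie-broken edge subset and a degree-only hub loses most of its edges
  at the low end of the 0.10–0.30 sweep.  Real cortical hubs are
  distinguished by strong connections as much as numerous ones; the
  graded hub makes the planted structure detectable at every sweep
  density.  The hub fixture additionally uses a ground-truth density
  near 0.3 so the top of the sweep still probes true structure rather
  than sampling noise.
* **Seeding** — all randomness derives from one integer seed through
  SeedSequence spawn keys, so any component (a group's graph, one
  subject's time series, one repetition's subsample) can be regenerated
  independently, and identical seeds give byte-identical cohorts.

### Reduced-scale profiles

Three named configurations support fast, deterministic end-to-end
checks; their sizes were chosen so the whole suite runs in minutes on
one CPU:

* `reduced_config` — strong-effect cohort: 4 × 15 subjects, 32 regions,
  140 volumes, ρ = 0.5, graded thickness/volume deficits on a 10-region
  subset (AD −2 SD, MCI-C −1.2, MCI-NC −0.6, HC 0) with 4× MCI variance
  inflation.  Four-group nested-CV accuracy on this cohort is expected
  well above the 25% chance level (≥ 50% is the acceptance bar).
* `null_config` — same shape, ρ = 0 and no morphometric effect; the
  pipeline must stay within the binomial 3σ band around 25%.  This is
  the honesty check that the nested protocol leaks nothing.
* `hub_config` — 32 regions, 4 modules (p_within 0.80 / p_between
  0.12), ρ = 0.6, one planted hub; recovery is measured as the fraction
  of seeds with consensus ≥ 0.9.

What passing these checks shows: the implementation recovers structure
it plants and reports chance when there is none.  What it does not
show: robustness to scanner artefacts, temporal autocorrelation, motion,
registration error, or any anatomical covariance structure of real
cohorts — none of which the generator models.

## Numerical conventions

Pearson matrices are symmetrized and clipped to [−1, 1] with a zero
diagonal; zero-variance time series columns are a hard error naming the
column.  Population (divide-by-N) SDs are used for hub flagging and
per-subject normalization.  Modularity contributions are exact to
machine precision against the partition Q.  The balanced-subsample and
Louvain/null-model streams derive from the pipeline seed via labelled
spawn keys (see `_rng.py`), keeping every derived integer seed below
2³¹.

## Known limitations

* The synthetic generator's i.i.d. rows overstate the effective sample
  size of real BOLD series at the same T.
* Small-worldness on graphs with zero clustering (trees, rings) is NaN
  by construction of σ.
* DCA follows the scatter + cross-covariance SVD construction; with
  fewer than two classes per block it is undefined, and rank-deficient
  between-class scatter reduces the output dimension with a warning.
* Published anatomical hub labels and the clinical accuracy tables
  depend on the restricted cohort and are out of scope; the package
  reproduces the protocol's arithmetic and its behaviour on synthetic
  ground truth instead.
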