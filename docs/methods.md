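# Methods

This note documents the models and procedures implemented in `pgpscreen`,
the parameters that matter, and the design choices made where the
workflow's published description left the design open.

## Assay labelling

Raw readouts are thresholded into Y/N class labels per endpoint:

| endpoint | readout (units) | Y when | non-confident zone |
|---|---|---|---|
| inhibition | % of elacridar maximum response | ≥ 10% | [6, 12] % |
| ATPase activation | fold-stimulation over DMSO control | > 2.0 | [1.5, 2.0] |
| monolayer efflux | B→A/A→B permeability ratio | ≥ 2.1 | [1.5, 2.0] (follow-up) |

Boundary conventions follow the literal inequalities: exactly 10% is Y
(only "< 10%" is defined as negative), exactly 2.0-fold is N ("> 2"),
exactly 2.1 is Y ("≥ 2.1").  The inhibition non-confident zone is known
only through the compounds observed in it (responses between 6% and 12%),
so [6, 12]% is used.  Efflux ratios in [1.5, 2.0] are decided by the
elacridar follow-up experiment and labelling without that flag is an
error; ratios in the gap (2.0, 2.1) are covered by neither published rule
and are labelled N with a non-confident flag and a logged warning.
Labels inside any non-confident zone keep a definite Y/N value but carry
`confident=False`.

The (inhibition, ATPase, efflux) triple maps to a profile: Y/N/N "true"
inhibitor, Y/Y/Y substrate, N/N/N non-substrate, anything else "other".

## Descriptor preprocessing

Constant columns (exact equality by default; `variance_epsilon`
configurable) are dropped first, then one member of every descriptor pair
with |Pearson r| > 0.95.  The pair scan is greedy in column order and
always drops the later column — the published workflow does not say which
member was discarded, and a deterministic rule is required for
reproducibility.

Subset selection maximises the CFS merit

    merit(S) = k · r̄cf / sqrt(k + k(k−1) · r̄ff)

with k = |S|, r̄cf the mean absolute descriptor–class correlation and
r̄ff the mean absolute within-subset descriptor correlation.  The class
correlation is point-biserial (Pearson against the 0/1-coded class): the
WEKA attribute evaluator used originally discretises descriptors and uses
symmetric uncertainty, but its exact settings are unrecoverable, so the
simpler, fully specified measure is used and documented here.  Note that
under this merit an exact duplicate of a selected descriptor leaves the
merit unchanged (2r/√(2+2·1) = r) rather than lowering it; redundancy is
penalised relative to the *uncorrelated* case.

The search is a generational GA over subset bitstrings (population 20,
20 generations, uniform crossover at 0.6, per-bit mutation 0.033, binary
tournament selection, one elite), followed by a single-bit-flip hill
climb of the run's best subset; the local refinement makes recovery of
strongly informative descriptors reliable at this small budget.  Ten runs
with distinct seeds are aggregated; descriptors selected in at least half
the runs (inclusion fraction 0.5) are kept, with a floor of the top five
by frequency if the threshold empties the selection.  The GA
hyperparameters mirror common CFS+GA practice; only the method and the
10-run averaging are fixed by the source workflow.

## Sphere-exclusion splitting

Descriptors are standardized to zero mean / unit variance (toggleable;
whether the original split standardized is unstated, but raw descriptor
scales differ by orders of magnitude).  Compounds are visited in order of
decreasing distance from the dataset centroid, ties broken by compound
id.  Each unassigned visit enters training and excludes unassigned
compounds within radius R into a test-candidate pool.  R is bisected
(60 iterations by default) until every class has at least
`test_per_class` candidates; per class, the candidates closest to their
nearest training compound are kept and the rest return to training.  The
construction guarantees the published invariants: both sets cover the
descriptor space, the test set holds exactly 10 compounds per class
(39/20 on the 59-compound design), and every test compound lies within R
of a training compound.  The procedure is deterministic and invariant to
row order.

## Tree induction

Both learners grow binary trees on numeric descriptors with thresholds at
midpoints between consecutive distinct sorted values; `value < t` routes
left, `value ≥ t` right (equality goes right, matching the reporting
style "XLogP ≥ 1.6").  Gain ties resolve to the lower descriptor index,
then the lower threshold.  There is no depth limit.

*Random Tree* samples K descriptors uniformly without replacement at each
node from a generator child keyed by (seed S, pre-order node index), so
trees are deterministic functions of (data, K, S) and independent of row
insertion order.  The best information-gain split among the K is taken;
growth stops at purity, zero gain, or children below `min_leaf_weight`
(default 1).  With K equal to the full descriptor count the tree is the
deterministic greedy tree.

*C4.5* grows by gain ratio honouring `min_instances` per child (default
2), then prunes.  Pessimistic pruning (default) collapses a subtree when
the node-as-leaf error estimate n·U_CF(e, n) does not exceed the sum over
its leaves, with U_CF the one-sided binomial (Clopper–Pearson) upper
confidence bound at `confidence_factor` (default 0.25).  Setting
`num_folds` switches to reduced-error pruning against a held-out
1/num_folds fraction (seeded shuffle).  Subtree raising and fractional
missing-value instances are not implemented; equivalence to WEKA output
is explicitly not claimed (its attribute-sampling and tie rules are
version-dependent).

Prediction returns the leaf majority (ties → N, flagged) and a
Laplace-corrected Y probability (nY + 1)/(n + 2), which feeds the ROC
analysis.

## Validation

Leave-one-out CV retrains the identical configuration on each n−1 fold —
including the same seed S for random trees, the only reading consistent
with naming one model per (S, K) pair.  Statistics pool over the n
held-out predictions; AUC is the rank-based probability that a random Y
outscores a random N (ties half), computed on the pooled leaf
probabilities (per-fold averaging would be the alternative; the source is
silent).  MCC with a zero denominator factor returns 0 with a flag
(WEKA-compatible).  Percentages are reported to 1 decimal and
MCC/kappa/AUC to 2, matching the published tables.  A model enters a
consensus only if its LOO statistics meet the gate: accuracy ≥ 70%,
MCC ≥ 0.40, kappa ≥ 0.40, AUC ≥ 0.60 (all inclusive).

## Applicability domain and consensus

The domain of a training set is the interval [d_min, d_max] of Euclidean
distances from the training centroid, in the model's own (optionally
standardized) descriptor space.  The literal allowed-range rule
(`strict_range`) excludes queries *closer* to the centroid than any
training compound — almost certainly unintended but stated verbatim in
the source — so `zero_to_max` ([0, d_max]) is provided as an alternative;
`strict_range` is the default to match the stated rule, without claiming
the original authors' intent.  A relative 1e-9 tolerance guards boundary
round-off so training compounds are always covered by their own domain.

Consensus prediction majority-votes the members whose domain covers the
query; zero covering members → out of domain; tied votes → N with a flag
(conservative for a screen whose positive claim should not rest on a tie;
the original consensus models had odd member counts and never faced
ties).  Averaging the members' Laplace probabilities is exposed as an
option and coincides with majority voting for equal-weight binary votes.
The three endpoint consensus models together assign a profile; any
out-of-domain endpoint leaves it undetermined.

The top-level `run_experiment` chains pruning → splitting → GA/CFS
selection (on the training set only) → a candidate grid (random-tree
seeds 1..20 × K ∈ {2, m/2, m} over the m selected descriptors, plus C4.5
with `min_instances` 1..5) → LOO gating → consensus → test-set
evaluation.  Test compounds that fall outside every member's strict
range are voted by all members and flagged.

## Synthetic data generator

The generator emulates the statistical shape of a PaDEL-style export for
an assay-profiled drug set: 59 compounds × 696 descriptors by default,
with 40 constant columns (descriptors that do not vary across a drug-like
series are common) and 60 near-duplicate column pairs (r ≈ 0.99,
exercising the 0.95 filter); remaining marginals alternate heavy-tailed
lognormal (LogP-, MR-like) and Poisson counts (ring-, H-bond-count-like).
Labels follow planted single-descriptor threshold rules with thresholds
calibrated at empirical quantiles so the class balances match the study
design exactly at zero noise — 26/33, 29/30, 34/25 Y/N — after which
5% label noise (default) emulates assay-call uncertainty.  The planted
descriptors are unit normals; the inhibition and ATPase rules sit on two
descriptors that load (0.9) on one shared latent variable, reproducing
the strong positive co-occurrence of those two endpoints while leaving
the Y/N/N profile region non-empty (identical-descriptor rules would
nest one endpoint inside the other and make true-inhibitor profiles
impossible).  An external-set generator resamples reference compounds
with 5% jitter (in-domain) and pushes a requested number of compounds far
beyond the reference's maximum centroid distance (out-of-domain), for
exercising AD rejection.

What the generator does *not* emulate: real inter-descriptor chemistry
(e.g. the true XLogP–AMR covariance), fingerprint bit structure, and
activity cliffs.  Tests passing on synthetic data therefore demonstrate
the correctness and determinism of the pipeline machinery and its
behaviour under the study's sample sizes and class balances — not
predictive performance on real chemistry.

## Problem sizes and numerical choices

The default test-and-demonstration sizes are the study's own: 59
compounds, 696 descriptors, 39/20 splits, 20 random-tree seeds; a full
three-endpoint pipeline run completes in well under a minute on one CPU.
Entropy uses natural logarithms (the base cancels in comparisons).
Zero-variance columns under standardization get unit scale with a logged
warning.  Compound ids match case-insensitively after whitespace
normalisation, and the two literature spellings of clarithromycin are
aliased to one id.

## Known limitations

- The original descriptor values are unpublished, so the exact published
  trees, AUCs and descriptor subsets (19/18/22) are not reproducible;
  they are treated as illustrative and checked only through the
  reconstructable confusion-matrix statistics and structural properties.
- C4.5 pessimistic pruning uses the Clopper–Pearson bound rather than
  Quinlan's continuity-corrected approximation; pruned trees may differ
  marginally from classic C4.5 output.
- The external set of the published study (47 synthesized derivatives)
  carries labels only; its table lists II_17b while the discussion also
  mentions II_17a — the fixture transcribes the table as printed.
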