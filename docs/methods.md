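# Methods

## Scope and model

`hmoflux` reconstructs candidate biosynthetic networks for human milk
oligosaccharides (HMOs) and assigns glycosyltransferase genes to the ten
elementary linkage reactions by testing the concordance between predicted
reaction flux and gene expression across milk samples.  The pipeline has
six stages: (1) rule-based network generation, (2) observed-HMO sink
attachment, (3) flux-variability reduction, (4) MILP enumeration of
subset-minimal candidate models, (5) per-sample flux estimation and
flux-expression scoring, and (6) gene-support aggregation with a
permutation background.

### Glycans and reaction rules

Glycans are rooted trees over five residues (Glc `G`, Gal `A`, GlcNAc
`GN`, Fuc `F`, Neu5Ac `NN`) with anomer/position-labelled edges; the
reducing-end glucose of lactose is the root.  The linear-code grammar
writes the reducing end rightmost and branches in parentheses.  Canonical
serialisation orders a node's children by (backbone sugar before
decoration, then position, anomer, subtree code) and continues the
backbone with the first child.  The position-only ordering used in some
notations is ambiguous for decorated residues (it would print 3FL as
`Fa3(Ab4)G`); preferring backbone sugars reproduces the conventional
strings (`Ab4(Fa3)G`, `GNb3(GNb6)Ab4G`, `Ab3(Fa4)GNb3A`).

Each of the ten rules adds one residue via a fixed linkage at sites
matched by an acceptor pattern, with two pattern extensions: a `(` prefix
marks a residue that must be childless ("terminal" — so a decorated
galactose can no longer be elongated, dead-ending e.g. 6'-sialyl-lactose),
and `~pattern` is a negated context constraint (e.g. alpha-1,3
fucosylation is blocked on a GlcNAc carrying a beta-1,3 galactose, where
the alpha-1,4 rule acts instead).  The attachment site of a rule is not
stored in the fixture; it is derived by diffing the acceptor and product
patterns, and a constraint's anchor by embedding the acceptor into the
constraint.  Both derivations are required to be unique and fail loudly
otherwise.

### Network generation and reduction

The Complete Network is the breadth-first closure of the rules from
lactose up to a residue-count cap (default 9, the size of the largest
measured HMO).  Determinism: species are processed in (size, canonical
code) order, rules in listed order, and reaction ids are
`substrate|rule|site-path`.  With the packaged rules the closure has 1758
species and 4296 reactions.

Observed HMOs enter as pooled sinks: every candidate isomer of a measured
peak feeds one sink pseudo-species through a pooling reaction, so
structural ambiguity is preserved rather than resolved up front.  Eleven
of the sixteen peaks have a single determined structure; the other five
ship with rule-enumerated candidate sets on the backbone implied by the
peak name (both tetraose cores for DFLNT; the lacto-N-hexaose core for
FLNH/DFLNH/DSLNH/FDSLNH), giving 5/6/10/8/28 candidates.  The fixture is
an editable TSV — structure curation is data, not algorithm.

Reduction removes reactions that cannot carry flux to any observed sink.
On this network class (acyclic, one substrate and one product per
reaction) a reaction's FVA maximum is positive exactly when its product
has a directed route to an observed structure, so a graph-reachability
pass performs the bulk pruning and an explicit per-reaction LP
(maximise v_r subject to S·v = 0, v >= 0, lactose input <= 1, sinks open)
certifies every survivor at tolerance 1e-9, iterating to fixpoint.  The
equivalence is also exercised in the tests against COBRApy as an
independent FBA oracle.

### Candidate models (MILP)

A candidate model is a subset-minimal reaction set that can carry at
least epsilon flux (default 1e-3) into every observed sink simultaneously
at steady state.  The MILP couples fluxes to binaries (v <= M·y) and
minimises the number of included *biosynthetic* reactions; pooling
binaries cost nothing (they only select which isomer feeds a sink), and
at most one pooling line per ambiguous HMO may be active (configurable).
Numerical safety: during enumeration the lactose input is bounded by 1 so
all fluxes live on a unit scale, and M defaults to 10 — with a loose M,
M times the solver's integrality tolerance can reach epsilon and sinks
would be fed through rounded-off binaries.  Every incumbent is verified
by an exact-exclusion feasibility LP and greedily pruned to
subset-minimality; an integer cut on the pruned model excludes it and all
its supersets, which provably never removes a different subset-minimal
model, so iterating to infeasibility enumerates the complete set (tested
against exhaustive subset enumeration on random networks).  HiGHS via
SciPy is deterministic and single-threaded.

### Flux fitting and normalisation

For each (model, sample), sink fluxes are pinned to the sample's relative
abundances (zero stays pinned at zero so flux vectors remain comparable
for non-secretors), the lactose input then equals 1 by mass balance, and
the residual degeneracy is resolved parsimoniously (minimise total flux).
Normalised flux divides a reaction's flux by the total flux entering its
substrate species (the lactose input for lactose consumers; 0/0 := 0),
limiting the influence of upstream reactions in the correlations.

### Scoring, selection, support

The gene-linkage score (GLS) is the Spearman correlation across a
cohort's samples between a candidate gene's expression and the summed
normalised flux of the linkage's included reactions (sum chosen because
it conserves pathway usage; mean/max are switchable).  Correlations
require at least 4 paired samples and return missing for constant
vectors.  A model's score is the mean over linkages of the best
candidate GLS; models with z-scored scores above 1.646 (upper 5% of a
normal; a Q-Q diagnostic is emitted) form the high-performing set, and
cross-cohort overlap is tested with an upper-tail hypergeometric.

Gene support aggregates three metrics per (linkage, gene) over each
cohort's high-performing set — PROP (share of models where the gene is
the linkage's best correlate, ties split), mean GLS, and MSC (Pearson
correlation of model score with the gene's GLS; defined as 0 when the
gene's GLS is constant across models, as for a linkage with a single
route shared by every model) — each z-scored against a
permutation background built by randomly remapping all GLS entries
(n = 27 by default; configurable upward, since 27 gives coarse sd
estimates) and rerunning scoring, selection and metrics per shuffle.
Per cohort, p = P(N(0,1) > z_sum/sqrt(3)) — the natural null for a sum of
three standardised metrics; their residual dependence is only partially
absorbed by the permutation z-scoring, which is why the FDR smoke test
below matters.  Cohort p-values are Fisher-pooled (df adapts when a
cohort lacks a metric) and Benjamini-Hochberg corrected across genes
within each linkage (a global-FDR switch exists); support = -log10(q),
significant at q < 0.1.

Candidate genes are pre-filtered by expression: a gene is excluded iff it
is undetected in >= 75% of some cohort's microarray samples and neither
RNA-Seq rescue criterion holds (75th-percentile TPM > 2, or above the
reference-tissue median); a linkage with a single survivor is assigned by
default.

### Summary network

Reaction importance is the mean of min-max-normalised inclusion
proportion among commonly high-performing models and min-max-normalised
-log10 hypergeometric enrichment (the aggregation is config-exposed; the
mean is symmetric and bounded).  For each observed HMO, all directed
paths from lactose to each candidate structure are scored by mean edge
importance (length-invariant; min and product offered) and the top 5%
(at least one) retained; the union of retained edges forms the summary
network.  Path explosion is guarded by a DP path-count pre-check.

## Synthetic cohorts

The generator emulates the study conditions: two cohorts of 8 and 10
sample-matched (glycoprofile, expression) pairs.  Abundances are
Dirichlet with concentration proportional to a typical 2'FL/LNT-dominant
profile (total concentration 30; both config-exposed); non-secretor
samples (secretor fraction 0.75) zero every HMO whose *every* candidate
structure carries an alpha-1,2 fucose, then renormalise.  True fluxes
come from fitting a fixed true model; each linkage's planted gene is
exp(standardised flux + noise), decoys are exp(noise), so Spearman-based
scoring is transform-free by construction.  The default noise sd 0.72
yields a planted flux-expression rank correlation near 0.8 (for a
bivariate normal, rho_s ≈ (6/pi)·asin(r/2), so r ≈ 0.81 needs
sd ≈ sqrt(1/r² - 1) ≈ 0.72).  What the generator does **not** emulate:
microarray probe/batch artifacts, longitudinal day-postpartum trends,
inter-gene correlation beyond the planted coupling, or compositional
measurement noise — passing recovery tests therefore demonstrate
statistical identifiability under the model's own assumptions, not
robustness to real measurement pathologies.

Benchmarks and smoke tests run on a trimmed network (nine observed HMOs
reachable within six residues; 30 biosynthetic + 14 pooling reactions
after reduction, 20 subset-minimal models) — chosen so a 20-replicate
recovery study and a 20-seed FDR null run complete in minutes while
preserving the full pipeline structure, including isomer pooling and
non-secretor zeros.

## Numerical choices and degenerate inputs

* LP/MILP: HiGHS (scipy.optimize), deterministic; FVA removal tolerance
  1e-9; enumeration epsilon 1e-3, M = 10, input bounded by 1.
* Ties: canonicalisation breaks child ties lexicographically; PROP splits
  exact GLS ties equally; greedy pruning scans reactions in sorted-id
  order.
* Degenerate inputs: empty observed set reduces to the bare input
  exchange; constant model scores select nothing (warning); constant
  expression or flux yields missing GLS; all-missing linkages are
  excluded from the model-score mean; infeasible (model, sample) pairs
  are dropped from correlations and logged.
* The permutation background canonicalises row/column order first, so
  support values are invariant to gene and model ordering.

## Known limitations

* The candidate-isomer fixture is a rule-based curation; published
  literature curation of the ambiguous peaks may be tighter, and minimum
  model cardinality is sensitive to it (more chainable isomer sets admit
  smaller models).
* The z_sum/sqrt(3) null treats PROP/GLS/MSC as independent; with n = 27
  permutations the background sd is coarse.  The FDR smoke test bounds
  the practical consequence but a larger n_perm is recommended for real
  analyses.
* The entry-permutation background is calibrated only against its own
  null (exchangeable GLS entries).  Because all models are scored on the
  same samples, GLS values are correlated *across models* even when
  expression carries no signal; the shuffle destroys that structure, so
  its sd underestimates the null spread of model-averaged metrics and
  q-values under an expression-level null are anti-conservative.
  Support scores should be read as a ranking with permutation-anchored
  scale, not as exact error rates — which is how the cross-cohort
  pooling and the wet-lab follow-up are meant to compensate.
* Exhaustive enumeration of all candidate models on the full fixture
  (tens of millions) is supported by the uncapped CLI path but is not a
  desk-scale computation; scoring-side code streams models in chunks but
  has only been exercised up to thousands of models.
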