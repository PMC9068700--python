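# hmoflux

Constraint-based reconstruction of **human milk oligosaccharide (HMO)
biosynthesis** and assignment of the glycosyltransferase genes behind it.

HMOs — 2'FL, LNT, DSLNT and their relatives — are free glycans built on a
lactose core from five monosaccharides (Glc, Gal, GlcNAc, Fuc, Neu5Ac).
Ten elementary linkage reactions (chain initiation/elongation, branching,
fucosylation, sialylation) suffice to build the sixteen HMOs that dominate
milk, but each reaction can be catalysed by several isozymes, and direct
correlation of isozyme expression with HMO concentrations fails (the
pathway is a network, not a set of independent reactions).  `hmoflux` is
for systems biologists who want to resolve those gene-reaction
assignments from sample-matched glycoprofiles and transcriptomes:

1. **Network generation** — apply the ten linkage rules iteratively from
   lactose to build every reachable glycan up to nine residues
   (`GNb3Ab4G`-style linear codes, rooted-tree canonicalisation).
2. **Observed sinks** — pool the candidate isomers of each measured HMO
   peak into one sink, so structural ambiguity is carried, not guessed.
3. **Reduction** — flux variability analysis removes every reaction that
   cannot carry flux to a measured HMO.
4. **Candidate models** — a MILP enumerates subset-minimal subnetworks
   (binary inclusion `y_r`, fluxes `v_r`):

       min Σ_r y_r   s.t.   S·v = 0,   0 ≤ v_r ≤ M·y_r,   sink_h ≥ ε ∀h

   with integer cuts sweeping the ensemble of alternative topologies.
5. **Flux fitting** — per sample, sink fluxes are pinned to measured
   relative abundances and resolved parsimoniously (pFBA); fluxes are
   normalised by substrate inflow.
6. **Scoring and gene support** — the gene-linkage score (GLS) is the
   Spearman correlation ρ(expression, normalised linkage flux) across a
   cohort's samples; a model score is the mean of per-linkage best GLS;
   models with z(score) > 1.646 are "high-performing"; genes are ranked
   by pooling PROP/GLS/MSC permutation z-scores across cohorts (Fisher)
   with Benjamini–Hochberg correction — support = −log₁₀(q).

A synthetic-cohort generator (`hmoflux.simulate`) plants known
gene-linkage couplings so that every stage is testable without any
external download.

## Worked example

Build a compact nine-HMO network, enumerate its candidate models,
simulate two sample-matched cohorts (8 + 10 samples, planted genes,
flux-expression rank correlation ≈ 0.8), and rank genes by support:

```python
from hmoflux.testnets import toy_reduced_network
from hmoflux.models import EnumConfig, enumerate_models, minimal_cardinality
from hmoflux.simulate import SimConfig, simulate
from hmoflux.scoring import (model_linkage_flux, gls_matrix, model_scores,
                             select_high_performing)
from hmoflux.support import PermConfig, support_analysis

net, true_model = toy_reduced_network()
models = enumerate_models(net, EnumConfig(cap=None))
sim = simulate(SimConfig(network=net, true_model=true_model, seed=1))
gls_by_cohort = {}
for cohort in ("cohort1", "cohort2"):
    lfs = {i: model_linkage_flux(net, m, sim.profile_for(cohort))
           for i, m in enumerate(models)}
    gls_by_cohort[cohort] = gls_matrix(lfs, sim.expression_for(cohort),
                                       sim.truth.candidates)
support = support_analysis(gls_by_cohort, perm=PermConfig(n_perm=27, seed=0))
```

Output of the full script (`minimal_cardinality`, selection and the
per-linkage winner):

```
reduced network: 22 glycans, 30 biosynthetic + 14 pooling reactions
minimum model cardinality: 10
subset-minimal candidate models: 20 (sizes 10 - 12 )
cohort1: 1/20 high-performing models (Q-Q r = 0.942)
cohort2: 0/20 high-performing models (Q-Q r = 0.874)
top-supported gene per linkage (planted gene in brackets):
    L1: B3GNT2       support=0.56 q=0.2734 [B3GNT2]
   L10: ST6GALNAC1   support=1.98 q=0.0105 [ST6GALNAC1]
    L2: FUT1         support=5.03 q=0.0000 [FUT1]
    L3: FUT3         support=2.50 q=0.0032 [FUT3]
    L4: ST3GAL1      support=1.50 q=0.0314 [ST3GAL1]
    L5: L5decoy3     support=1.48 q=0.0333 [ST6GAL1]
    L6: B3GALT1      support=1.57 q=0.0271 [B3GALT1]
    L7: B4GALT1      support=2.07 q=0.0085 [B4GALT1]
    L9: L9gene       support=1.80 q=0.0159 [L9gene]
```

Reading it: the toy network supports 20 alternative subset-minimal
topologies of 10–12 biosynthetic reactions each.  At this noise level the
planted gene wins 8 of 9 linkages (support is −log₁₀ of the pooled,
FDR-corrected p; q < 0.1 is called significant).  L5 is a miss at this
seed — recovery is statistical; across 20 seeds the planted gene ranks
first in ≥ 90% of linkage×seed cases (see `tests/test_acceptance.py`).
Synthetic decoy names like `L5decoy3` pad gene families whose real
members are already used by another linkage.

The same stages run from the shell:

```sh
hmoflux build-network --max-size 9 --out net.json
hmoflux reduce --network net.json --out reduced.json
hmoflux enumerate --network reduced.json --cap 100 --out models.json
hmoflux simulate --seed 1 --out simdata/
hmoflux run-all --config pipeline.yaml
```

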