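# dtni — dose-time gene regulatory network inference

Toxicogenomics experiments profile gene expression across both exposure
**time** and **dose** (the in vitro template: human hepatocytes at 2, 8
and 24 h, three doses at ratio 1:5:25, time-matched controls, duplicate
arrays).  Classic ODE-based network inference uses only the time axis;
`dtni` implements **dose-time network identification**: coupled
linear-ODE regression blocks over time derivatives *and* dose
derivatives sharing one interaction matrix,

    dx_i/dt          = Σ_j a_ij x_j + b_i^c u_c(d)       (time equations)
    dx_i/d(log10 d)  = Σ_j a_ij x_j + h_i^c t            (dose equations)

where x_i are log2 ratios treated/control, a_ij is the signed influence
of gene j on gene i, and u_c is the compound's perturbation input.
Sparse uneven designs are handled by spline interpolation with analytic
derivatives; collinearity by SVD dimension reduction; significance by a
permutation-of-residuals test that re-runs the whole pipeline per
permutation; and multi-compound panels by pooling into one network plus
a leave-one-compound-out (LOOCV) consensus filter.  Nodes with only
outgoing edges ("starting nodes") point at candidate molecular
initiating events.

The package ships everything needed to validate the method against
known truth: an exact linear-ODE oracle generator, a synthetic
mass-action NF-kB-like signalling module with drug actions (plus an
SBML reader for mass-action models), gold-standard extraction from
reaction structure, and the full evaluation protocol (sensitivity,
specificity, geometric mean, PPV, AUROC).

It is aimed at computational toxicologists and systems biologists who
have dose-time expression panels (or simulate them) and want directed,
significance-annotated interaction networks.

## Worked example

Simulate the synthetic NF-kB-like module under a four-compound panel
(six time points over 2-24 h, doses 1:5:25, two replicates, moderate
noise), infer the network, and score it against the module's own
reaction structure:

```python
import numpy as np, dtni

model  = dtni.add_drug_reactions(dtni.ikb_nfkb_module(), dtni.default_drug_spec())
tensor = dtni.simulate_dataset(model, times=np.linspace(2, 24, 6),
                               noise=dtni.NoiseModel(sigma=0.05, replicates=2, seed=42))

res = dtni.DTNI(tensor).fit(n_perm=500, seed=42)
print(res.summary())
```

```
DTNI results
==============================================
genes: 9   compounds: 4
regression rows: 960   reduced dim k: 8
permutations: 500   seed: 42
significant interactions at alpha=0.05: 43
----------------------------------------------
source       target         strength  sign              p
IkB          NFkBn           -0.1573  inhibition   0.0020
NFkB_IkB     IKK              0.1542  activation   0.0020
NFkBn        IkB              0.1507  activation   0.0020
IkB          NFkB_IkB         0.1469  activation   0.0020
NFkBn        A20_mRNA         0.1265  activation   0.0020
...
```

The strongest calls recover the module's biology: IkB inhibits nuclear
NF-kB, nuclear NF-kB activates IkB resynthesis (the negative feedback
loop) and induces the A20 transcript.  Scoring against the structural
gold standard and applying the LOOCV consensus:

```python
gold = dtni.gold_standard_from_model(model).restrict(tensor.genes)
ev   = dtni.classify_edges(res.network(0.05), gold)
sc   = dtni.edge_confidence(res.p_values, res.A, res.genes)

cons = dtni.loocv_consensus(tensor, alpha=0.05, n_perm=500, seed=42)
```

prints (via the evaluation helpers):

```
sensitivity 0.765  specificity 0.455  geometric mean 0.590  PPV 0.302
AUROC 0.714
LOOCV consensus: 16 edges, PPV 0.438
starting nodes: ['A20']
```

76% of true direct interactions are recovered, the consensus filter
raises the fraction of predicted edges that are true from 0.30 to 0.44,
and the remaining source-only node marks where the perturbation enters.

A command-line interface wraps the same pipeline:

```bash
dtni simulate --model nfkb --sigma 0.05 --seed 42 -o data.tsv --gold gold.tsv
dtni infer    --method dtni --n-perm 1000 --alpha 0.05 -i data.tsv -o net.tsv
dtni evaluate --gold gold.tsv -i net.tsv -o report.json
dtni benchmark -c config.json -o report.json
```

Edge tables are written as TSV, SIF or GraphML for downstream network
tools.

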