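# grncompare

Comparative modeling and reverse engineering of gene-regulatory
networks (GRNs) with three deterministic rate-law formalisms.

## The problem

Small GRNs are routinely modeled as systems of coupled ODEs for the
gene-product concentrations X_i(t), and routinely *reverse-engineered*
by fitting those ODEs to time-series expression data.  Three rate laws
dominate this literature, and they are not interchangeable:

* **ANN** (recurrent-network rate law)
  `dX_i/dt = v_i f(Σ_j w_ij X_j − ϑ_i) − k_i X_i` — additive input
  processing through a sigmoid f; production bounded by v_i.
* **S-system** (power-law kinetics)
  `dX_i/dt = α_i Π_j X_j^g_ij − β_i Π_j X_j^h_ij` — multiplicative
  input processing with real "kinetic order" exponents; unbounded
  rates; negative orders introduce singularities near zero
  concentrations.
* **GRLOT** (general rate law of transcription)
  `dX_i/dt = v_i Π_j Ki^n/(I_j^n+Ki^n) · Π_k A_k^n/(A_k^n+Ka^n) − k_i X_i`
  — one Hill-type saturating factor per regulator.

`grncompare` builds parameterized 5-gene reference networks in all
three formalisms (a uniform cascade, a branched cascade with
asymmetric co-regulation, and the same with positive and negative
feedback loops), simulates noise-free training data from them, fits
all three formalisms back to all datasets with a two-phase
evolutionary algorithm (per-gene *node models*, then a seeded
whole-network fit), and scores the results:

* `P_ver` / `P_val` — `1/(1+MSE)` fit score on training data /
  on unseen data generated under perturbed network input
  (`ΔP_fit = P_val − P_ver`);
* `P_inf` — `0.5(1+r)`, Pearson correlation between true and
  recovered free-parameter vectors (within-method only);
* `Q_com` — presence/absence of designed network features (uniform
  degradation, constant propagation, branching/co-regulation
  asymmetry, feedback loops).

The headline phenomenon these measures expose: a model can reproduce
its training data essentially perfectly and still have poorly
determined parameters, and the S-system's multiplied unbounded power
laws make its fits dramatically more fragile under input
perturbations than the two saturating formalisms.

## Worked example

```python
import numpy as np
import grncompare as g

reference = g.build_case("A", "ANN")      # printed cascade parameters
data = g.generate_sparse(reference)       # 200 samples, starting set 1

config = g.EAConfig(population=100, generations=100, repeats=3)
fit = g.two_phase_fit(data, reference.topology, "ANN",
                      config=config, rng=np.random.default_rng(1))
inferred = fit.model()

print(f"P_ver  = {g.verify(inferred, data):.4f}")
print(f"P_inf  = {g.p_inf_models(reference, inferred):.4f}")
val = g.validate(inferred, reference, data)
print(f"P_val  = {val.p_val:.4f}")
```

Output from this exact run (`examples/two_phase_inference.py` prints
the same quantities with commentary):

```
P_ver  = 1.0000
P_inf  = 0.9841
P_val  = 0.6335
```

`P_ver = 1.0000` says the fitted network reproduces its training
trajectories to four decimal places.  `P_inf = 0.984` says the
recovered parameter vector correlates with the generating one at
r ≈ 0.97 — close, but the single-trajectory dataset leaves some
parameter directions unconstrained.  `P_val = 0.63` shows the cost
of that: under a perturbed network input (the input gene's
degradation constant moved from 0.3 to 0.1 and 0.5) the model is
pushed into concentration ranges the training data never visited,
and its predictions degrade.  This verification-vs-validation gap is
exactly what the measures are designed to expose; with the detailed
five-trajectory datasets it largely disappears for the bounded
(ANN/GRLOT) formalisms and persists for the S-system.

The `examples/` directory contains one short script per capability
(rate laws, data generation, two-phase inference, qualitative
features).  A thin CLI wraps the same steps:

```
grncompare build-case A ANN --out ref.json
grncompare simulate ref.json --out data.csv
grncompare infer data.csv ANN --topology-json ref.json --seed 1 --out fit.json
grncompare evaluate fit.model.json ref.json data.csv --case A
grncompare study --out reports/          # full cross-method design
```

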