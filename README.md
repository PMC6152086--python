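# ppilm — protein–protein interaction prediction from PSSM Legendre moments

`ppilm` predicts whether two proteins interact using nothing but their
amino-acid sequences, for computational biologists who want a
sequence-only decision-support tool where experimental interaction
screens (two-hybrid, co-IP) are too expensive or noisy.

## Method

Each protein is represented by its position-specific scoring matrix
(PSSM): the R×20 evolutionary profile PSI-BLAST produces for a sequence
of length R, with entries d(i,j) = Σ_k p(i,k)·w(j,k) combining observed
residue frequencies p with a Dayhoff-family mutation matrix w. The
profile is treated as an image on [−1,1]² and summarized by its 2-D
Legendre moments

    L_mn = μ_mn ∫∫ V_m(x) V_n(y) f(x,y) dx dy,   μ_mn = (2m+1)(2n+1)/4,

where V_m is the Legendre polynomial of order m. Orthogonality of the
basis (∫V_mV_n = 2δ_mn/(2m+1)) makes the moments non-redundant, so the
441 values with m,n ≤ 20 form a compact, length-independent descriptor
of the conservation pattern. The piecewise-constant image is integrated
cell-exactly via ∫V_m = (V_{m+1} − V_{m−1})/(2m+1).

A protein pair is the 882-value concatenation of its two descriptors,
reduced to 100 coordinates by PCA (fitted on training pairs only).
Pairs are classified by a **probabilistic classification vector
machine** (PCVM): a sparse probit-link kernel model

    P(interacting | x) = Ω( Σ_i w_i K_θ(x, x_i) + b ),

with Gaussian RBF kernel K_θ, standard normal CDF Ω, and a truncated
Gaussian prior on each weight that constrains y_i·w_i ≥ 0 — every
retained training pair ("classification vector") supports its own
class. Fitting is by EM with probit data augmentation; Gamma
hyperpriors drive most weight precisions to infinity, pruning the basis
to a sparse set. Because EM is initialization-sensitive, the kernel
width θ can be chosen by the built-in multi-start protocol: 9 candidate
widths × 5 cross-validation folds, keeping each fold's best and
returning the median.

Evaluation follows the field's conventions: accuracy, sensitivity
TP/(TP+FN), precision TP/(TP+FP), Matthews correlation coefficient and
ROC/AUC, under stratified five-fold cross-validation, plus a
cross-species transfer protocol and an RBF-SVM baseline (c = 0.02,
g = 0.03) run on identical features.

Real PSSMs require PSI-BLAST and a large sequence database, so the
package ships a synthetic generator that emulates profile geometry:
smooth low-order Legendre fields with group-structured latent
coefficients, giving labelled pairs with a tunable class separation δ.

## Worked example

```python
import numpy as np, ppilm as P

# 1. simulate a dataset: 1000 labelled pairs over 800 proteins
cfg = P.SynthConfig(n_proteins=800, n_pairs=1000, delta=1.0,
                    sigma=0.1, length_range=(30, 60), seed=7)
pssms, pairs, _ = P.simulate_dataset(cfg)

# 2. cross-validate the full pipeline (moments -> PCA -> PCVM)
report = P.kfold_cv(pairs, pssms, P.PipelineConfig(), k=3, seed=0)
print(report.to_table())
```

prints (fold rows, then mean ± SD, all in percent):

```
Testing Set	Acc (%)	Sn (%)	Pe (%)	Mcc (%)	AUC (%)
1	90.42	92.81	88.57	80.93	97.04
2	93.39	92.77	93.90	86.79	97.99
3	91.59	97.60	87.17	83.78	97.03
Average	91.80 ± 1.50	94.40 ± 2.78	89.88 ± 3.55	83.84 ± 2.93	97.36 ± 0.55
```

i.e. the descriptor + classifier recover the planted interaction signal
at ~92 % accuracy with near-perfect ranking (AUC ≈ 97 %); accuracy
climbs toward 98 % at the 2000-pair scale the acceptance script uses.
Fitting a
single model exposes the statsmodels-style results object:

```python
X, y = P.build_pair_matrix(pairs, {p.protein_id: P.legendre_moments_exact(p) for p in pssms})
proj = P.fit_projection(X, 100)
res = P.PCVM(y, P.apply_projection(proj, X)).fit()
print(res.summary())          # basis size, theta, bias, convergence
p = res.predict_proba(P.apply_projection(proj, X[:5]))
```

The same pipeline is scriptable from the shell:

```sh
ppilm simulate --out data --n-proteins 300 --n-pairs 400 --seed 1
ppilm extract-features --pssm-dir data/pssms --out features.tsv
ppilm evaluate --pssm-dir data/pssms --pairs data/pairs.tsv --out eval --k 5
```

For real data, point `extract-features` at a directory of PSI-BLAST
ASCII profiles (`psiblast -evalue 0.001 -num_iterations 3
-out_ascii_pssm ...`; see `ppilm.psiblast_command`).

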