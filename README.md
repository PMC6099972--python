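# toxqsar

Grouped QSAR models for the acute toxicity of substituted aromatic
compounds to the ciliate *Tetrahymena pyriformis*.

The endpoint is −log IGC50, the negative log of the concentration causing
50 % growth inhibition (larger = more toxic). The package ships a
160-compound reference table split by substitution pattern into three
groups — nitro-substituted (46), halogen-substituted (75), and compounds
bearing both substituents (39) — each divided into four training subsets
(A–D) and an external test set (T), and implements the full modelling
workflow around that data:

- **Descriptor handling** (`toxqsar.descriptors`): the gravitation index
  over bonded atom pairs, G² = Σ m_i m_j / r_ij², the maximum
  nucleus–nucleus bond repulsion Enn(a–b) = max Z_a Z_b / R_ab, and the
  pre-selection screen that removes constant columns and prunes descriptor
  pairs with |r| ≥ 0.8, keeping the member better correlated with the
  response.
- **Stepwise MLR** (`toxqsar.mlr`): ordinary least squares
  Y = b0 + Σ b_i x_i with forward descriptor selection ranked by the
  regression F statistic under the same intercorrelation bound, plus
  coefficient standard errors, t values, and leave-one-out q² via the
  closed-form deleted residual e_i/(1 − h_ii).
- **Gaussian RBF network** (`toxqsar.rbfnn`): h_j(x) = exp(−‖x−c_j‖²/r²)
  hidden units recruited greedily from the training points with an exact
  least-squares output layer, and a width scan over r = 0.1…4.0 (step 0.1)
  scored by output-layer LOO q².
- **Validation** (`toxqsar.validation`): R² (squared Pearson correlation),
  RMS, Fisher F, external q², the Golbraikh–Tropsha predictivity block
  (through-origin slopes k/k′ and determination coefficients R0²/R0′² with
  the four pass conditions), and the five-fold subset rotation that holds
  out T, D, A, B and C in turn.
- **Applicability domain** (`toxqsar.applicability_domain`): leverages
  h_i = x_i(XᵀX)⁻¹x_iᵀ, warning leverage h* = 3m/n, ±3σ standardized
  residual bounds, Williams-plot coordinates and outlier removal/refit.
- **Synthetic data** (`toxqsar.synthetic_data`): seeded generators for
  descriptor matrices with planted linear signals, collinear nuisance
  blocks and Gaussian-bump nonlinearity, used to test every stage without
  proprietary descriptor software.

## Worked example

```python
import toxqsar as tq

group1 = tq.load_table1(1)              # 46 nitroaromatics
train, test = group1.training(), group1.test()

r2 = tq.r_squared(train.y, train.column("mlr"))
rms = tq.rms_error(train.y, train.column("mlr"))
f = tq.f_statistic(r2, n=len(train), p=3)
print(f"training R2={r2:.3f} RMS={rms:.3f} F={f:.1f}")

report = tq.external_validation(test.y, test.column("mlr"),
                                float(train.y.mean()))
ok, failed = tq.gt_check(report)
print(f"test R2={report.r2:.3f} k={report.k:.3f} k'={report.k_prime:.3f} "
      f"pass={ok} failed={failed}")
```

prints

```
training R2=0.828 RMS=0.234 F=51.2
test R2=0.629 k=0.681 k'=1.228 pass=False failed=['q2', 'k']
```

The training R² of 0.828 recomputes the published footer (0.829) from the
printed per-compound predictions. The external block for this group fails
the predictivity conditions when recomputed from the printed predictions:
two test compounds carry gross printed residuals (+0.80 and +1.08 log
units), so the published table does not support the published test-set
summary for this group — see `docs/methods.md` for the analysis. The other
two groups recompute cleanly (e.g. halogen group: training R² 0.803,
RMS 0.215, test RMS 0.262).

The same pipeline runs from the shell:

```sh
toxqsar simulate --seed 7 --out sim.csv
toxqsar preselect --data sim.csv --out pre.csv
toxqsar fit-mlr --data pre.csv --n-desc 3 --out model.json
toxqsar crossval --data pre.csv --out rotation.json
toxqsar ad --model model.json --data pre.csv --out williams.csv
```

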