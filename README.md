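# irfda

Identification of fentanyl-constituent functional groups — amide, aniline,
benzene and piperidine — from infrared absorption spectra, using functional
data analysis: roughness-penalized functional principal component analysis
(FPCA) followed by per-group functional logistic regression.

Fentanyl and its analogues share a small set of recurring substructures,
each with characteristic IR absorption bands. Treating a compound's
spectrum as a smooth curve ν(α) over wavenumber α rather than as hundreds
of independent predictors sidesteps the curse of dimensionality and ties
each classifier's coefficient function β(α) back to interpretable spectral
features. The package is aimed at chemometricians and forensic-spectroscopy
researchers who want a tested, reproducible reference pipeline they can run
end-to-end on synthetic corpora or on their own NIST-WebBook-style JCAMP-DX
exports.

## Method

For compound *i* with absorbance curve ν_i(α) observed at wavenumbers α_j:

1. **Preprocessing** — each curve is rescaled to unit sample standard
   deviation, linearly interpolated to the common grid 500–4000 cm⁻¹ with
   step 4 cm⁻¹ (p = 876 points), and, when visibly tilted, detrended by
   the straight line through its lowest point and its right endpoint. No
   smoothing is applied.
2. **FPCA** — the sample covariance function σ(s,t) (divisor n−1) is
   diagonalized under the trapezoid-rule inner product with a
   second-derivative roughness penalty, giving orthonormal eigenfunctions
   φ_k and eigenvalues λ_k. Scores are f_ik = ∫ φ_k(α)[ν_i(α) − ν̄(α)] dα,
   and K is the smallest number of components explaining ≥ 80 % of
   variance.
3. **Functional GLM** — one Bernoulli-logit model per group,
   logit p_i = β₀ + Σ_k β_k f_ik, fitted by IRLS maximum likelihood, with
   seeded with-replacement oversampling of rare positive classes
   (piperidine) and a ridge fallback under perfect separation. A compound
   is called positive when p̂ exceeds 0.5.
4. **Evaluation** — per-group confusion matrices, FPR/FNR, ROC/AUC, the
   joint nine-class composition label derived from the four binary calls,
   and a misclassification taxonomy (exact / partial / missed / spurious /
   disjoint).

A synthetic-spectrum generator with group-characteristic absorption bands,
compound-specific fingerprint bands, irregular native sampling, baseline
slopes and additive noise makes every stage testable without downloads.

## Worked example

Simulate a labeled corpus (400 training / 200 test spectra in the
reference class proportions), then train, predict and evaluate:

```bash
irfda simulate --out demo/data --seed 7 --train-total 400 --test-total 200
irfda run-all --spectra-dir demo/data/spectra \
              --manifest demo/data/manifest.csv \
              --out demo/run --seed 7
```

which prints

```
wrote 600 spectra and manifest to demo/data
K=11; joint accuracy 1.0000; average per-group accuracy 1.0000
```

Here K=11 components were needed to reach 80 % explained variance
(`train_report.json` shows 82.0 % at K=11), and on this clean synthetic
corpus every test compound's four group flags — and hence its joint
composition class — were predicted correctly (`evaluation.json` holds the
four confusion matrices, AUCs of 1.0, and the taxonomy with all 200
compounds classed "exact"). Real spectra are far harder: with realistic
corpora the benzene/aniline pair in particular trades errors because the
two groups share their aromatic band signature.

The same pipeline is callable as a library:

```python
from irfda import RunConfig, run_all, simulate_dataset, reduced_config

spectra, records = simulate_dataset(reduced_config(400, 200, seed=7))
result, predictions, report = run_all(spectra, records, RunConfig(seed=7))
print(result.k, report["average_accuracy"])
```

## Layout

```
src/irfda/io.py          JCAMP-DX + CSV spectra, label manifests
src/irfda/preprocess.py  rescaling, common grid, baseline correction
src/irfda/fpca.py        penalized FPCA, scores, K selection
src/irfda/glm.py         per-group logistic models, oversampling
src/irfda/evaluate.py    confusions, ROC/AUC, joint labels, taxonomy
src/irfda/synthetic.py   band library and corpus generator
src/irfda/pipeline.py    train / predict / evaluate orchestration
src/irfda/cli.py         irfda simulate|train|predict|evaluate|run-all
docs/methods.md          modeling assumptions and design notes
```
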