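# nirsimca

One-class SIMCA / DD-SIMCA brand authentication of pharmaceutical tablets
from handheld near-infrared (NIR) spectra.

Falsified medicines — products that misrepresent their identity, composition
or source — are a serious public-health problem, and antimalarials are among
the most falsified drug classes. Low-cost handheld NIR spectrometers
(900–1700 nm) combined with chemometric class models can screen tablets
non-destructively: a one-class model trained on genuine tablets of one brand
accepts tablets consistent with that brand and rejects everything else,
including fakes that contain none of the declared active ingredients.

`nirsimca` provides the full workflow for this kind of study:

- **Synthetic spectrum generator** — brand-specific Gaussian band structure,
  multiplicative/additive scatter, baseline drift, batch effects, noisy
  spectral edges, and falsified tablets without API bands, arranged in a
  realistic sampling design (8 products, 23 batches, 10 tablets per batch,
  230 spectra, two illicit falsified batches plus one falsified batch that
  infiltrated the licit supply chain).
- **Preprocessing** — crop to 1085–1601 nm, Savitzky–Golay second derivative
  (2nd-degree polynomial, spacing-aware), multiplicative scatter correction
  against the training mean.
- **PCA** — SVD with Hotelling T², Q residuals, and score-plot confidence
  ellipses.
- **Classical SIMCA** — per-brand PCA with 95% Jackson–Mudholkar Q and
  F-based T² limits; membership probability
  p = exp(−d² ln2/2), d² = (q/Q_lim)² + (t²/T²_lim)², thresholded at 0.8.
- **DD-SIMCA** — score distance h and orthogonal distance v modelled as
  scaled chi-squared by the method of moments; acceptance when
  c = N_h·h/h₀ + N_v·v/v₀ ≤ χ²₁₋α(N_h+N_v).
- **Selection & evaluation** — Kennard–Stone maximin splitting, batch-wise
  splitting (falsified batches never in training), venetian-blinds
  cross-validation for the component count, sensitivity/specificity reports.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from nirsimca.study import replicate_study

report = replicate_study(seed=42)
print(report.simca_report.table.to_string(index=False))
print(report.dd_report.table.to_string(index=False))
```

prints (classical SIMCA, then DD-SIMCA):

```
       brand  n_target  n_foreign  true_accept  true_reject  sensitivity  specificity
    Combimal         8        114            8          114        100.0        100.0
Duo-Cotecxin        20        102           11          102         55.0        100.0
     Laridox         8        114            8          114        100.0        100.0
     Malacur         8        114            8          114        100.0        100.0
    Maloxine        20        102            9          102         45.0        100.0
      Ridmal         8        114            8          114        100.0        100.0

       brand  n_target  n_foreign  true_accept  true_reject  sensitivity  specificity
Duo-Cotecxin        20        102           20          102        100.0        100.0
    Maloxine        20        102           20          102        100.0        100.0
```

Each row is one brand model scored on a common test pool of held-out target
tablets (`n_target`), other brands' tablets and falsified tablets
(`n_foreign`). Every model rejects all 100% of non-members — foreign brands
and fakes never pass. The two DD-SIMCA models (2 PCs, α = 10⁻⁶) also accept
all of their own held-out batches. Classical SIMCA sensitivity is lower for
the two batch-split brands because the 0.8 probability threshold is stricter
than the 95% limits it is built from (see `docs/methods.md`).

The same workflow is available from the shell:

```sh
nirsimca simulate --seed 42 --out spectra.csv     # 230-row spectra CSV
nirsimca replicate-study --seed 42 --out-dir out  # full study + artifacts
nirsimca train --in spectra.csv --brand Maloxine --model ddsimca \
         --alpha 1e-6 --ncomp 2 --out maloxine.json
nirsimca predict --model maloxine.json --in spectra.csv --out decisions.csv
nirsimca evaluate --decisions decisions.csv --truth spectra.csv --out report.csv
```

## File formats

Spectra travel as a documented CSV dialect: header
`sample_id,brand,batch_id,channel,falsified,<wl1>,<wl2>,...` with wavelength
column names in nm to 2 decimals, one row per tablet, `falsified` as 0/1.
Fitted models serialize to versioned JSON files that reload to bit-identical
decisions.

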