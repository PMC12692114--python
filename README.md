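# nirfuse

Multi-quality chemometrics for near-infrared (NIR) fruit spectroscopy:
partial least squares regression with cross-parameter band fusion and
Shapley-value band screening.

## The problem

Soluble solids content (SSC, °Brix), moisture content (MC, mass fraction)
and fruit firmness (FF, N) of stone fruit can all be predicted from a single
diffuse-transmission NIR spectrum, but they are usually modelled one at a
time, each from its own small set of characteristic wavelengths. Because the
three traits are tightly coupled physiologically (sugar accumulation, water
loss and cell-wall softening move together — pairwise correlations on the
order of |r| ≈ 0.8–0.96), wavelengths selected for the chemical traits carry
information about firmness that a firmness-only model never sees. `nirfuse`
implements the full workflow that exploits this:

1. **Preprocessing** — head/tail grid trimming, wavelength-range restriction,
   and the per-spectrum corrections min–max, SNV, MSC and Savitzky–Golay.
2. **Splitting & regression** — Kennard–Stone max–min calibration/validation
   splitting and single-response PLSR (NIPALS, X-deflation), with
   venetian-blind cross-validation for the component count (Rc², Rp², RMSE
   as metrics).
3. **Wavelength selection** — CARS (competitive adaptive reweighted sampling:
   an exponentially decreasing retention schedule over PLS coefficient
   magnitudes plus weighted resampling) and a binary shuffled frog leaping
   algorithm (SFLA).
4. **Cross-parameter fusion** — the de-duplicated union of the per-trait band
   sets, with provenance.
5. **Shapley screening** — every band in the fused model is attributed its
   Shapley value
   `φ_i = Σ_{S⊆N\{i}} |S|!(|N|−|S|−1)!/|N|! · [f(S∪{i}) − f(S)]`
   under a mean-imputation value function; bands whose mean |φ| falls below a
   threshold are dropped and the model refit, in stages, trading model size
   against accuracy with a full audit trail. For the affine PLSR predictor
   the closed form `φ_ij = B_j (x_ij − m_j)` is exact; the package also ships
   the full enumeration as an oracle.

Because the measured fruit spectra behind this workflow are not publicly
deposited, the package includes a first-class synthetic generator that
reproduces the study conditions: a 129-point 970–1700 nm grid (5.6 nm step),
absorption troughs at 1180/1445 nm and a peak at 1285 nm, edge-localised
baseline drift outside 1040–1625 nm, per-sample multiplicative scatter, and
the empirical trait correlation structure (SSC–MC −0.96, SSC–FF +0.81,
MC–FF −0.79) via a Gaussian copula.

## Worked example

```python
import nirfuse as nf

# 120 synthetic fruit on the 129-point instrument grid
block, traits = nf.generate(nf.default_config(seed=7))
C = nf.pearson_matrix(traits)
print(f"trait correlations: SSC-MC {C[0,1]:+.2f}, SSC-FF {C[0,2]:+.2f}, "
      f"MC-FF {C[1,2]:+.2f}")

pre = nf.snv(nf.trim_head_tail(block, 15, 15))        # 129 -> 99 bands
split = nf.kennard_stone(pre.values, 80)              # 80 cal / 40 val
cal, val = split.calibration_ids, split.validation_ids

y = traits.column("ff_newton")
sel = nf.cars(pre.values[cal], y[cal], nf.CarsConfig(seed=7))
X = pre.values[:, sel.selected]
a = nf.select_components(X[cal], y[cal], max_components=20)
m = nf.fit_plsr(X[cal], y[cal], a)
mv = nf.compute_metrics(y[val], nf.predict(m, X[val]))
print(f"FF model: {len(sel.selected)} bands, {a} components, "
      f"Rp2 = {mv.r2:.4f}, RMSE = {mv.rmse:.3f} N")
```

prints

```
trait correlations: SSC-MC -0.96, SSC-FF +0.83, MC-FF -0.84
FF model: 33 bands, 2 components, Rp2 = 0.9896, RMSE = 0.207 N
```

The correlations are the sample estimates at n = 120 of the configured
structure; the firmness model keeps 33 of 99 SNV-corrected bands and
explains ~99% of validation-set variance on this (deliberately clean)
synthetic data. The same flow is available from the shell:

```bash
nirfuse generate --n-samples 120 --seed 7 --spectra-out s.csv --traits-out t.csv
nirfuse preprocess s.csv --trim-head 15 --trim-tail 15 --methods minmax,snv --out pre.csv
nirfuse select pre.csv t.csv --trait ff_newton --method cars --seed 7 --out sel_ff.json
nirfuse select pre.csv t.csv --trait ssc_brix --method sfla --seed 7 --out sel_ssc.json
nirfuse fuse sel_ff.json sel_ssc.json --out fused.json
nirfuse shap-screen pre.csv t.csv fused.json --thresholds 0.02,0.05 --out stages.json
nirfuse run --config config.yaml --seed 1 --out results/   # whole pipeline
```

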