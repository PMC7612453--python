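# foldstab

Site-specific protein fold-stability analysis from temperature series of
2D-NMR peak volumes.

## The problem

A ¹⁵N-HSQC spectrum resolves one cross-peak per backbone amide, so a
temperature series of such spectra watches a protein melt **residue by
residue** instead of as the all-or-none average that CD or fluorescence
reports.  For a protein that shows both heat and cold denaturation above
0 °C — like the yeast frataxin homologue Yfh1 at low ionic strength — each
residue's peak-volume series yields a full *stability curve*

ΔG(T) = ΔHm (1 − T/Tm) + ΔCp [(T − Tm) − T ln(T/Tm)]

with both zeros measurable: the heat-melting temperature Tm and the
cold-denaturation temperature Tc, plus the maximum-stability temperature
Ts = Tm·exp(−ΔHm/(Tm·ΔCp)).  Comparing single-residue curves with the
average curve of the hydrophobic core then separates faithful reporters of
global unfolding from outliers — and the outliers carry their own signal
about how cold and heat unfolding differ.

`foldstab` is a library (plus a thin CLI) for NMR spectroscopists and
biophysicists that implements this pipeline:

* **thermo**: the two-state Gibbs–Helmholtz model in closed form —
  populations, Tm/Tc/Ts, curvature (−ΔCp/T), covariance-propagated σ_ΔG
  bands, and the "naive" intensity stability ΔG̃(T) = −RT ln((1−I_f)/I_f);
* **volumes**: reference-peak normalization, volume → population
  conversion with an explicit room-temperature anchor (default 70 %
  folded at ≈ 298 K), Levenberg–Marquardt fitting with flagged
  non-convergent/unphysical fits;
* **rad**: burial scoring of backbone amide nitrogens,
  RAD = D × RA × 100 (exteriority × relative N accessibility), from a PDB
  file or a precomputed table; residues with RAD < 0.1 are the
  hydrophobic-core reporters;
* **classify**: buried-core reference curve, ΔTm/ΔTc outlier
  classification (consistent < 1.5 K, outlier > 3 K), decomposition into
  the three stability-curve mechanisms (raise ΔHs / change ΔCp / shift the
  curve), secondary-structure summaries;
* **simulate**: synthetic melting series with known ground truth and the
  three NMR artefacts that corrupt apparent populations (exchange
  broadening, differential relaxation, solvent exchange), with
  parameter-recovery and Ts-robustness studies.

See `docs/methods.md` for the model, conventions and defaults.

## Worked example

```sh
python examples/fit_stability_curve.py
```

```
              dHm       Tm     dCp       Tc       Ts
generator   28.50   298.20    3.73   283.18   290.66
recovered   27.16   298.06    3.62   283.28   290.64
sigma_dG at 285/295/305 K (kcal/mol): 0.013 0.014 0.029
```

One synthetic residue is generated from the buried-core parameters of
Yfh1 (ΔHm = 28.5 kcal/mol, Tm = 298.2 K, ΔCp = 3.73 kcal/mol/K) with 3 %
volume noise and refitted: the melting temperature comes back within
0.14 K, the cold-denaturation temperature within 0.1 K, and the σ band
quantifies the fit uncertainty of ΔG(T).

The other examples show the remaining capabilities, each printing a short
interpretation: `rad_burial_scores.py` (structure → RAD),
`classify_outliers.py` (the packaged Yfh1 table → outlier anatomy: the
outliers' mean ΔTm ≈ −2.7 K but mean ΔTc ≈ −4.3 K, cold unfolding shifts
more than heat unfolding) and `artefact_robustness.py` (artefacts move
Tm/Tc by several K but Ts by < 0.5 K).

The same pipeline is scriptable from the shell:

```sh
foldstab simulate --out sim --seed 1
foldstab fit --volumes sim/synthetic_volumes.tsv --out fits
foldstab classify --volumes volumes.tsv --rad-table rad.tsv --out results
```

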