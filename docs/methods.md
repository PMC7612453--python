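# Methods

## The model

`foldstab` treats each backbone-amide cross-peak of a 2D ¹⁵N-HSQC melting
series as an independent reporter of a two-state folding equilibrium
F ⇌ U.  With a temperature-independent heat-capacity difference
ΔCp = Cp(U) − Cp(F), the unfolding free energy follows the modified
Gibbs–Helmholtz equation

    ΔG(T) = ΔHm (1 − T/Tm) + ΔCp [(T − Tm) − T ln(T/Tm)],

the protein's *stability curve*.  ΔG = G(U) − G(F) is positive where the
folded state is stable.  The curve has two zeros — the heat-melting
temperature Tm and, when ΔCp is large enough, the cold-denaturation
temperature Tc — and a maximum at the zero-entropy point

    Ts = Tm · exp(−ΔSm/ΔCp),   ΔSm = ΔHm/Tm.

Populations are Boltzmann: f_U(T) = e^(−ΔG/RT)/(1 + e^(−ΔG/RT)), with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ (all energies in kcal/mol, all temperatures
in absolute Kelvin; Celsius is accepted only at the CLI boundary behind an
explicit flag).  The curvature of the stability curve is ∂²ΔG/∂T² = −ΔCp/T,
which is why ΔCp controls how close Tc sits to Tm.

## From peak volumes to populations

Peak volumes are first divided by the volume of an internal-standard
reference peak recorded at the same temperature, cancelling instrumental
non-linearity.  The default population transform then follows the
melting-experiment convention: the normalized volume at the highest grid
temperature is the unfolded baseline V_U (the protein is taken as fully
unfolded there, so that temperature is excluded from fitting), the maximum
normalized volume is the folded plateau V_F, and the apparent folded
fraction a(T) = (V − V_U)/(V_F − V_U) is rescaled multiplicatively so the
folded fraction at the measured temperature nearest the anchor (default
298.15 K) equals an independently known value (default 0.70, the
low-ionic-strength room-temperature folded population of Yfh1 known from
CD).  How exactly the original analysis imposed the 70 % anchor is not
specified anywhere we could follow; a multiplicative rescale of the
apparent folded fraction is one self-consistent choice and is logged
prominently.  Populations are clipped to [0, 1] with the clipped count
reported.

Two alternative policies exist because the default transform is not
invertible against a generator that emits volumes proportional to f_F:
`v_u_rule="zero"` (no baseline subtraction) and `scale_mode="direct"`
(volumes are already on the population scale).  The simulation studies use
these so that parameter recovery measures the estimator, not the
baseline-transform mismatch.  For real data the default remains the
anchored transform.

## Fitting

(ΔHm, Tm, ΔCp) are estimated by unweighted damped least squares
(Levenberg–Marquardt, `scipy.optimize.least_squares`) on the unfolded
fractions of the retained temperatures, requiring at least 6 of them.
Populations are fitted directly, not log-transformed; no weighting scheme
is applied.  Initialization: Tm₀ at the steepest high-temperature drop of
f_F, ΔHm₀ = 25 kcal/mol, ΔCp₀ = 2.5 kcal/mol/K (the centre of the observed
per-residue ranges); on failure up to 5 restarts jitter the start by
±30 % under a fixed seed.  The parameter covariance is s²(JᵀJ)⁻¹ from the
final Jacobian with s² the residual variance.  Fits with ΔHm ≤ 0, ΔCp ≤ 0,
Tm outside [250, 400] K, or a flat population series are flagged, never
silently reported.  σ_ΔG(T) bands come from first-order covariance
propagation with the closed-form gradient of the Gibbs–Helmholtz curve;
the propagation is verified against brute-force parameter sampling.

Tc is found by bracketed root search (Brent) on [150 K, Ts] to
|ΔG| < 10⁻⁹ kcal/mol; below ~150 K the solution model is meaningless, so
"no zero above the floor" is reported as absence of observable cold
denaturation rather than a number.

## Burial scoring (RAD)

RAD = D × RA × 100 for each backbone amide nitrogen:

* **D**, exteriority ∈ [0, 1]: the fraction of 960 quasi-uniform points on
  a 4 Å probe sphere around the atom lying outside the union of heavy-atom
  van der Waals spheres.  The 4 Å radius must exceed contact distances so
  the index senses burial rather than packing; it is configurable.  D is a
  normalized exteriority, not a Euclidean depth in Å — large RAD must mean
  exposed, which fixes the orientation of the index.
* **RA**, relative accessibility ∈ [0, 1]: Shrake–Rupley SASA (probe
  1.4 Å, ≥ 960 sphere points per atom, fixed radii N 1.55 / C 1.70 /
  O 1.52 / S 1.80 Å, hydrogens ignored) of the nitrogen divided by the
  SASA of its whole residue; 0 by convention when the residue is fully
  buried.

Published RAD values can be supplied as a precomputed table (residue_label
with either D and RA or RAD directly), bypassing structure computation;
this path reproduces published reporter selections exactly, which the
built-in calculators — deliberately simple, not replicas of any external
depth program — need not.

## Reference curve and classification

The buried-core reference averages the folded fractions of residues with
RAD < 0.1 temperature by temperature (arithmetic mean over members present
at each temperature, flagged fits excluded) and fits the averaged series;
a parameter-mean mode (average ΔHm, Tm, ΔCp of the members) exists for
working from parameter tables alone.  Residues are compared to the
reference through ΔTm and ΔTc; the category boundary is the arithmetic
mean of |ΔTm| and |ΔTc| — below 1.5 K consistent, above 3 K outlier,
otherwise an explicit "intermediate" band that the source analysis left
unassigned.

Outlier curves are decomposed into three canonical mechanisms: raising the
maximal-stability enthalpy ΔHs (I), changing ΔCp (II), translating the
curve in temperature (III, reported as ΔTs).  ΔHs is the
Kirchhoff-consistent ΔH(Ts) = ΔHm + ΔCp(Ts − Tm).  A component is labelled
when its magnitude exceeds 10 % (configurable) of the reference scale; for
ΔTs the scale is the reference curve's width Tm − Tc (≈ 18 K for Yfh1),
the natural temperature scale of the problem — a fraction of absolute
Kelvin would be meaningless.

## Synthetic data

The generator emits folded-peak volumes V(T) = f_F(T) (population scale,
reference peaks at 1.0 or an optional smooth polynomial drift applied to
both peak and reference) on the measured grid, 278–313 K in 2.5 K steps,
with multiplicative log-normal noise (default σ = 3 %, typical of volume
integration repeatability).  The default generating parameters are the
buried-core values ΔHm = 28.5 kcal/mol, Tm = 298.2 K, ΔCp = 3.73
kcal/mol/K.  Three artefact mechanisms multiply the folded-peak volume:

1. exchange broadening in the fast-exchange limit,
   exp(−f_F f_U Δω²/k_ex · τ_INEPT), defaults Δω = 300 s⁻¹,
   k_ex = 2000 s⁻¹ at 298.2 K scaling ×1.07 per K, τ = 5.4 ms
   (= 1/(2·93 Hz), one INEPT delay);
2. Bloch decay exp(−R2(T)·τ) with R2 linear in T (folded default 12 s⁻¹ at
   298 K, slope −0.15 s⁻¹/K, τ = 20 ms);
3. pseudo-first-order amide–water exchange exp(−k_hx(T)·w·τ), k_hx
   doubling per 10 K (default 1 s⁻¹ at 298 K, exposure weight 0.5,
   τ = 0.1 s).

These are standard first-order attenuation models with every constant
configurable; the defaults keep each factor ≥ 0.7 over the grid (the
"moderate" regime).  The generator does **not** emulate full
Bloch–McConnell evolution during the pulse sequence, slow- or
intermediate-exchange lineshapes, field-strength effects, baseline or
peak-overlap errors, or three-state unfolding — so passing recovery tests
demonstrate the estimator under the stated noise model, not immunity to
every pathology of real spectra.

## Simulation studies and problem sizes

* *Parameter recovery*: 100 replicates on the 15-temperature grid at 3 %
  noise.  Observed medians ≈ 0.10 K for |T̂m − Tm| and ≈ 0.11 K for
  |T̂c − Tc|.
* *Ts robustness*: 25 replicates per artefact setting (none, each
  mechanism alone, all combined).  Both the naive route — trusting
  intensities, ΔG̃(T) = −RT ln((1−I_f)/I_f), fitted in free-energy
  space — and the population pipeline are run.  Median |T̂s − Ts| stays
  below ~0.5 K in every setting while median |T̂m − Tm| reaches ~7 K under
  combined distortion: the maximum of the stability curve is the robust
  observable, its zeros are not.  Replicates whose folded peak falls below
  5 % of the reference in the lower half of the grid (where only an
  extreme artefact can kill it) are reported as failures, not fitted.
* *Error-band oracle*: 10⁵ parameter draws; propagated σ_ΔG agrees with
  the sampled standard deviation to < 0.5 %.

These sizes were chosen to make the medians stable at the few-hundredths-
of-a-Kelvin level; the full studies run in seconds.

## Known limitations

* The anchoring transform is one consistent reading of an underspecified
  published procedure; an alternative no-anchor policy is available and the
  choice is recorded in every run log.
* The exteriority index is not numerically interchangeable with published
  depth indices; cross-tool comparisons should use the precomputed-table
  path.
* The two-state model with constant ΔCp is assumed, not tested; residues
  violating it show up only indirectly, as flagged or outlier fits.
* Published per-residue tables are printed to 3 significant figures;
  quantities derived from them (e.g. ΔSm = ΔHm/Tm) can differ in the last
  printed digit from the published value through input rounding alone.
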