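"""Fit a per-residue stability curve from a synthetic HSQC melting series.

Generates one residue's folded-peak volumes on the 278-313 K grid from
known two-state parameters with 3 % multiplicative noise, converts them to
populations and fits the Gibbs-Helmholtz model.  The printed table compares
the generating parameters with the recovered ones; Tm/Tc are the heat/cold
unfolding temperatures and Ts the temperature of maximum stability.
"""

from foldstab import (
    ThermoParams,
    SyntheticSpec,
    generate_series,
    normalize_volumes,
    volumes_to_populations,
    fit_stability,
    propagate_errors,
    max_stability_temp,
    cold_denaturation_temp,
)

truth = ThermoParams(dH_m=28.5, T_m=298.2, dCp=3.73)
series, _ = generate_series(SyntheticSpec(true_params=truth, seed=42))
pop = volumes_to_populations(normalize_volumes(series), anchor_T=None,
                             v_u_rule="zero", scale_mode="direct")
fit = fit_stability(pop)

print(f"{'':14s}{'dHm':>8s}{'Tm':>9s}{'dCp':>8s}{'Tc':>9s}{'Ts':>9s}")
for name, p in [("generator", truth), ("recovered", fit.params)]:
    print(f"{name:14s}{p.dH_m:8.2f}{p.T_m:9.2f}{p.dCp:8.2f}"
          f"{cold_denaturation_temp(p):9.2f}{max_stability_temp(p):9.2f}")
sig = propagate_errors(fit, [285.0, 295.0, 305.0])
print("sigma_dG at 285/295/305 K (kcal/mol):",
      " ".join(f"{s:.3f}" for s in sig))
print("\nA good fit recovers Tm within ~0.1 K at this noise level; the")
print("sigma band is the covariance-propagated uncertainty of dG(T).")
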