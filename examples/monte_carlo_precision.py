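"""Monte Carlo comparison of the two carbon-density estimators.

Simulates repeated measurement of sediments spanning the mineral-to-peat
gradient with 10% relative error on both carbon fraction and bulk density,
then summarises per-level dispersion of (a) the gravimetric product
estimator and (b) the mixing-model estimator.  A second run probes the
bias the mixing estimator incurs when its assumed self-packing densities
are at the upper limit of reported values while the truth sits at the
literature mean.
"""

from scipy.stats import spearmanr

from sedcarbon import MixingParams, MonteCarloSpec, bias_probe, run_monte_carlo

truth = MixingParams(0.09, 1.75, 2.2)
spec = MonteCarloSpec(n_per_level=2000, true_params=truth, seed=7)
result = run_monte_carlo(spec)
s = result.summaries

rho_grav = spearmanr(s["true_c"], s["sd_grav"]).statistic
rho_mix = spearmanr(s["true_c"], s["rel_sd_mix"]).statistic
print(f"{len(result.records)} draws over {len(s)} carbon levels, cv = 10%")
print(f"gravimetric SD:  {s['sd_grav'].iloc[0]:.5f} -> {s['sd_grav'].iloc[-1]:.5f} "
      f"g C/cm^3 (Spearman rho vs C = {rho_grav:+.2f})")
print(f"mixing rel. SD:  {100 * s['rel_sd_mix'].iloc[0]:.1f} % -> "
      f"{100 * s['rel_sd_mix'].iloc[-1]:.1f} % (rho = {rho_mix:+.2f})")
print("The product estimator funnels out with carbon; the carbon-only "
      "estimator tightens.\n")

# parameter misspecification: precise but biased
assumed = MixingParams(0.10, 2.00, 2.2)  # upper limit of reported values
probe = bias_probe(
    MonteCarloSpec(n_per_level=2000, true_params=truth,
                   assumed_params=assumed, seed=8)
)
top = probe.iloc[-1]
print(f"with assumed (delta_p, delta_m) = (0.10, 2.00) vs true (0.09, 1.75):")
print(f"  at C = {top['true_c']:.2f}, bias = {top['bias']:+.5f} g C/cm^3 "
      f"({100 * top['bias'] / top['true_d']:+.1f}% of truth)")
print("High precision does not protect against wrong parameters: accuracy "
      "of delta_p and delta_m is what the carbon-only route depends on.")
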