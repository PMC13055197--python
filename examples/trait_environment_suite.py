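"""Trait-environment convergence: the phylogenetic regression suite.

Simulates 18 species with photosynthetic capacity (A_mass) generated as a
known linear function of mean annual potential evapotranspiration plus
Brownian-motion noise on the phylogeny, then fits the full suite of
phylogenetic linear regressions (A_mass against 12 habit-synthesized
climate summaries, plus desiccation rate against A_mass).
"""

import pandas as pd

import fernexpand as fx

scenario = fx.SyntheticScenario(seed=3, n_species=18, n_zero_cep=0,
                                expansion_category="none",
                                lambda_true=1.0, trait_slope_true=0.004,
                                noise_sd=0.05)
data = fx.simulate_scenario_dataset(scenario)

env = {}
for sp, recs in data["records"].items():
    pts = [(r.longitude, r.latitude) for r in recs]
    sample = fx.extract_env(pts, data["climate"].summaries)
    env[sp] = fx.synthesize_habit_environment(sample, data["habits"][sp])
env = pd.DataFrame(env).T

traits = fx.simulate_traits(data["tree"], env, scenario)
table = fx.run_trait_env_regressions(traits, data["tree"])

cols = ["response", "predictor", "n", "slope", "lambda", "r_squared", "p_value"]
print(table[cols].round(4).to_string(index=False))
print()
mapet = table[table.predictor == "mapet"].iloc[0]
print(f"The MAPET regression recovers the generating slope 0.004 "
      f"(fitted {mapet.slope:.4f}, R^2 = {mapet.r_squared:.2f}); predictors "
      f"unrelated to the generating gradient come out flat.")
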