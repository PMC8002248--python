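"""Evaluate a packaged broadband heart model at the microwave-ablation band.

Loads the fitted three-pole Debye model for the endocardium of heart A1,
evaluates it on the 81-point 500 MHz-20 GHz instrument grid, and extracts the
single-frequency values at 2.4 GHz.  The printed permittivity/conductivity
pair is what a single-frequency electromagnetic simulation of this tissue
would use.
"""

from dielspec import TissuePart, evaluate_model, load_heart_models, value_at_frequency, vna1_grid

models = load_heart_models()
params = models[("A1", TissuePart.ENDOCARDIUM)]
print("model:", params)

spectrum = evaluate_model(params, vna1_grid())
print(f"grid: {len(spectrum)} points, "
      f"{spectrum.grid.f_min/1e9:.1f}-{spectrum.grid.f_max/1e9:.0f} GHz")

eps, sigma = value_at_frequency(spectrum, 2.4e9)
print(f"at 2.4 GHz: eps_r = {eps:.2f}, sigma = {sigma:.3f} S/m")
print("eps_r is the real relative permittivity; sigma is the total effective")
print("conductivity (ionic + dipolar losses), the pair used in SAR simulations.")
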