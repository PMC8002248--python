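# dielspec

Analysis toolkit for broadband dielectric characterization of heterogeneous
cardiac tissue at microwave frequencies.

Electromagnetic treatment planning — microwave and radiofrequency cardiac
ablation in particular — needs the dielectric properties (relative
permittivity εr and effective conductivity σ) of the tissues the field passes
through. The heart is not dielectrically homogeneous: its parts (epicardium,
endocardium, myocardium, atrial-appendage surfaces, luminal surfaces of the
great vessels) can differ by more than 25% in both quantities. `dielspec`
implements the analysis pipeline for open-ended coaxial-probe measurement
campaigns on excised hearts: forward dispersion models, multi-pole Debye
fitting, campaign summary statistics, probe validation, and a seeded
synthetic-campaign generator so that every stage is testable without measured
data.

## The model

Broadband spectra are parameterized by the n-pole Debye dispersion with a
static ionic conduction term,

```
ε̂(ω) = ε∞ + Σₚ Δεₚ / (1 + jωτₚ) + σₛ / (jωε₀),
```

with ε∞ the high-frequency permittivity, Δεₚ and τₚ the magnitude and
relaxation time of the p-th dispersion, σₛ the static ionic conductivity and
ε₀ the vacuum permittivity (engineering e^{+jωt} convention). Spectra are
stored as the measured pair (εr, σ), where σ = −Im(ε̂)·ω·ε₀ is the *total*
effective conductivity (ionic plus dipolar losses). Fitting minimizes the
joint relative least-squares objective over εr and σ with seeded multistart
initialization; fit quality is the mean percentage difference between model
and measurement across all frequency points, per quantity. The Cole–Cole
generalization ((jωτ)^{1−α}) is available for forward evaluation and as a
pluggable reference model.

## Worked example

```python
from dielspec import (TissuePart, evaluate_model, load_heart_models,
                      value_at_frequency, vna1_grid)

params = load_heart_models()[("A1", TissuePart.ENDOCARDIUM)]
spectrum = evaluate_model(params, vna1_grid())        # 81 points, 0.5-20 GHz
eps, sigma = value_at_frequency(spectrum, 2.4e9)
print(f"at 2.4 GHz: eps_r = {eps:.2f}, sigma = {sigma:.3f} S/m")
```

prints

```
at 2.4 GHz: eps_r = 57.98, sigma = 2.057 S/m
```

— the single-frequency dielectric pair for the endocardium of heart sample
A1 at the common microwave-ablation frequency, obtained by evaluating the
packaged fitted three-pole Debye model. The 24 packaged parameter sets (four
hearts × six tissue parts) are loaded with `load_heart_models()`.

The `examples/` directory holds one short narrative script per capability:
model evaluation, Debye fitting, campaign simulation + summary tables, the
ANOVA battery and drift diagnostic, and probe validation. A thin CLI wraps
the same functions:

```sh
dielspec simulate --seed 0 --out-dir campaign/
dielspec summarize --campaign campaign/campaign.csv --freq 2.4e9 --out table.csv
dielspec anova --campaign campaign/campaign.csv
dielspec fit --input spectrum.csv --poles 3 --starts 32 --seed 0 --out params.json
dielspec validate --measured meas.csv --reference ref_model.json
```

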