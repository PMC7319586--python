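# irbind

Equilibrium operator-occupancy modeling and EMSA/reporter analysis for
autoregulating DNA-binding proteins.

Many bacterial antitoxins double as transcriptional repressors of their own
toxin–antitoxin operon. The *Mycobacterium tuberculosis* antitoxin Rv2827c
binds four tandem 23 bp inverted repeats (IR1–IR4) upstream of the
*rv2827c–rv2826c* start codon, with per-repeat dissociation constants
spanning almost three orders of magnitude (IR1 0.0205 µM > IR4 0.121 µM >
IR2 0.862 µM > IR3 11.0 µM). Even without any site–site interaction, such
an affinity ladder makes occupancy accumulate in ordered, ever-weaker
steps, which shows up in a Hill plot as *apparent negative cooperativity*
(n<sub>H</sub> < 1) — in contrast with the positively cooperative homolog
AbiEi of *Streptococcus agalactiae*. `irbind` packages the quantitative
side of that analysis for anyone studying multi-operator repression:

- **`binding_model`** — statistical-thermodynamic model of a repressor on
  *n* ≤ 8 operator sites. A configuration *S* of occupied sites has weight
  ∏<sub>i∈S</sub>(c/K<sub>d,i</sub>) · ∏<sub>i<j∈S</sub> ω<sub>ij</sub>;
  probabilities follow by normalization over all 2<sup>n</sup>
  configurations. Predicts gel band distributions (number of sites bound),
  fractional saturation Y(c) = E[k]/n, the apparent Hill coefficient
  (slope of log θ vs log c at θ = Y/(1−Y) = 1), and fits per-site
  K<sub>d</sub>s from titrations (single-site isotherm or a global
  multisite band fit).
- **`hill_analysis`** — the EMSA pipeline: quantified band table →
  fractional saturation (replicates averaged, SEM reported) → Hill
  transform → OLS line near half-saturation → n<sub>H</sub>,
  K<sub>d</sub> = 10<sup>x-intercept</sup>, and a
  negative/non-cooperative/positive classification.
- **`ir_scanner`** — exhaustive inverted-repeat (palindromic operator)
  detection with mismatch budgets, promoter-relative (−1 = base upstream of
  the start codon) coordinates, and position-frequency consensus matrices.
- **`reporter_assay`** — Miller units from kinetic β-galactosidase reads
  (mU = OD420/min slope × 5000 / OD600 at the first time point),
  normalization to a vector control with delta-method error propagation,
  and repression ratios.
- **`synthetic_data`** — seeded generators for everything the pipeline
  consumes: EMSA titrations with lognormal densitometry noise, polyC-style
  site-knockout probes, promoters with planted inverted repeats, and
  occupancy-gated reporter kinetics.

## Worked example

```python
import numpy as np
from irbind import (rv2827c_promoter_model, mutate_probe, simulate_emsa,
                    TitrationDesign, NoiseModel, band_table_to_saturation,
                    hill_transform, hill_fit, apparent_hill_coefficient)

model = rv2827c_promoter_model()          # IR1..IR4 with the measured Kds

# single-repeat probe: knock the other three repeats out (polyC replacement)
probe = mutate_probe(model, ["IR2", "IR3", "IR4"])
table = simulate_emsa(probe, TitrationDesign.log_spaced(probe.kds[0]),
                      NoiseModel(multiplicative_sigma=0.05, seed=100))
result = hill_fit(hill_transform(band_table_to_saturation(table)))
print(result.kd, result.n_h, result.classification)
# 0.02118 0.9992 non-cooperative   (true Kd 0.0205 µM, 5% noise, triplicates)

print(apparent_hill_coefficient(model))
# 0.4788   -> the four-repeat promoter is apparently negatively cooperative
```

The same workflow is available from the shell. `irbind demo --seed 1
--outdir demo` regenerates a full synthetic study; its `summary.json`
reports, among others:

```
per-repeat fits   IR1 0.0212, IR4 0.1219, IR2 0.8376, IR3 11.35 µM
full promoter     n_H = 0.540, classification "negative",
                  global 4-site fit [0.0206, 0.1229, 0.827, 10.86] µM
reporter          uninduced 112.9 mU vs induced ≈ 0 mU (full repression)
ir scan           2 planted repeat pairs found / 2 planted
```

i.e. the per-repeat affinities round-trip through the gel-analysis
formulas under realistic noise, the intact four-repeat promoter shows the
negative-cooperativity signature, and saturating repressor silences the
reporter. Other subcommands: `simulate-emsa`, `analyze-emsa`, `fit-sites`,
`scan-ir`, `miller` (see `irbind --help`).

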