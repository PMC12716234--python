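# guvmech

Membrane mechanics of giant unilamellar vesicles (GUVs) from real-time
deformability cytometry (RT-DC).

## The problem

GUVs are cell-sized lipid-bilayer compartments used throughout membrane
biophysics and synthetic biology. Their dominant mechanical parameter in an
RT-DC channel is the **area expansion modulus** *K* (N/m) — the membrane's
resistance to areal stretching; bending is negligible at RT-DC stresses
(the bending capillary number η·γ̇·r³/κ exceeds 10⁵). Classical methods
(micropipette aspiration, AFM indentation) measure *K* one vesicle at a
time; RT-DC images thousands of vesicles per minute, contact-free, but
needs a model to turn shape into mechanics — and existing RT-DC models for
solid bodies or elastic shells do not apply to fluid membranes.

`guvmech` implements a simulation-calibrated framework for this inversion.
Each imaged vesicle contributes a projected area *A* and a deformation

    D = 1 − 2·√(πA) / P        (0 for a circle)

with *P* the contour perimeter. In dimensionless variables
*K̂* = K·L²/(ηQ) and *Â* = A/L² (channel side *L*, flow rate *Q*, buffer
viscosity *η* — so everything transfers across setups), the package ships
two calibrated laws:

* **direct surface** (per event): K̂ = Γ · D^(−β·Â^α) · Â^(−δ), with
  α = 0.5, β = 2.16, δ = 1 and Γ from the calibrated prefactor
  γ = 3.40·10⁻⁴ N/m at the reference setup (Q′ = 0.04 µL/s, L′ = 20 µm,
  η′ = 0.015 Pa·s);
* **slope law** (per population): K̂ = â · (dD/dÂ)^(−b), b = 1.75,
  exploiting that the stationary deformation is nearly linear in the
  vesicle area.

Three estimators build on them: **direct** (per-event inversion, noisy but
resolves heterogeneity), **collective** (regression slope of D vs A,
averages contour noise out), and **combined** — per-event moduli → Gaussian
mixture on ln K → drop the lowest-modulus component (doublets and
missegmented contours masquerade as anomalously soft vesicles) → collective
refit on the survivors. A synthetic-data generator with lognormal
deformation noise and configurable outliers makes the whole pipeline
testable offline, and quality gates (A ∈ [60, 225] µm², D ≤ 0.1,
porosity ≤ 1.03) plus a pluggable pixelation correction mirror standard
RT-DC post-processing.

## Worked example

Simulate a DOPC-like population (true K = 0.2 N/m, 2000 events, 15%
multiplicative deformation noise, 5% outliers) and extract K with the
combined method:

```sh
guvmech simulate -n 2000 -k 0.2 --seed 4 -o guv_sim.csv
guvmech extract guv_sim.csv --method combined --seed 4 \
        --no-pixelation-correction -o guv_report.json
```

which prints

```
combined: K = 0.2183 N/m (n = 1899)
```

The JSON report records the full pipeline: 2000 events survived the gates,
the two-component mixture on ln K assigned weights (0.054, 0.946) to
components at 0.073 and 0.200 N/m, the 101 events of the low-modulus
(outlier) component were discarded, and the collective refit on the
remaining 1899 events gives K = 0.218 N/m — within the ~13% band expected
for the soft modulus from the residual disagreement between the two
calibrated laws (see `docs/methods.md`). The same commands accept
`--flow-ul-s`, `--channel-um` and `--viscosity-mpa-s`/`--medium
"CellCarrier B"` to analyse data from any setup; `guvmech classify` writes
per-event mixture classes, and `guvmech calibrate` refits the constants
from a simulation table.

The same pipeline is available as a library:

```python
from guvmech import REFERENCE_SETUP, PopulationSpec, generate_events, combined_K

events, truth = generate_events(PopulationSpec(n=2000, K=0.2, seed=4), REFERENCE_SETUP)
result = combined_K(events["area_um"].to_numpy(), events["deform"].to_numpy(),
                    REFERENCE_SETUP, seed=4)
print(result.K)  # 0.218... N/m
```

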