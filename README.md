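# bafkit

Analysis toolkit for the quantitative assays used to study lipid-triggered
BAX activation: liposome (LUV) dye-release kinetics, two-agent Bliss
synergy, FLAMBE kinetic fluorescence polarization, microscale thermophoresis
(MST), HSQC chemical-shift perturbation (CSP) mapping, and thermal-shift
(DSF) melting temperatures. It is written for biochemists and biophysicists
who run these plate-based assays and want the whole analysis — normalization,
fitting, derived statistics, significance calls — as reproducible, scriptable
code rather than a chain of spreadsheet and GUI steps.

Every stage is paired with a seeded synthetic-data generator that draws from
the same model family the stage assumes, so the entire pipeline is testable
against known ground truth without any instrument export.

## The quantities it computes

**LUV permeabilization.** Raw dye-release fluorescence is normalized against
the plate's own controls,

    %perm = (F − F₀) / (F₁₀₀ − F₀) · 100,

with F₀ the minimum buffer-control reading over the whole assay and F₁₀₀ the
mean 1% CHAPS (detergent-solubilized) reading. Kinetics are fit with an
asymmetric five-parameter sigmoid

    y(x) = B + (T − B) / (1 + (E/x)^H)^S ,   0 < S ≤ 10,  T ≥ B,

and the slope at the inflection point ("maximal rate") is reported in closed
form:

    dy/dx|ᵢₚ = H·S·(T−B)·((H+1)/(H·S−1))^((H+1)/H) / (E·(1 + (H+1)/(H·S−1))^(S+1)),
    x_ip = E·((H·S−1)/(H+1))^(1/H),          defined when H·S > 1.

**Bliss synergy.** Endpoint percent permeabilization on a two-compound dose
grid is converted to response fractions and each combination cell is scored
against the Bliss independence expectation e = a + b − a·b built from its
own monotherapy margins; the matrix score is the mean excess over
combination cells, in percentage points.

**FLAMBE.** Polarization mP = (I∥ − I⊥)/(I∥ + I⊥)·1000; each
replicate-averaged trace is reduced to Tmax (time of peak polarization, set
to 0 for traces with no binding kinetics) and EP (endpoint polarization),
normalized so the free-peptide control maps to 0 and the protein vehicle
control to 1, with treatment effects measured as the Euclidean shift
Δs = √(ΔTmax² + ΔEP²) and a control-normalized AUC.

**MST.** Timetraces are fit with a one-phase decay
y = (Y₀ − Y_plateau)e^(−Kx) + Y_plateau inside a 5–35 s window; the decay
constant can be read off any single point as
K = −ln((y − Y_plateau)/(Y₀ − Y_plateau))/x. Temperature-jump responses
across a ligand titration are fit with a four-parameter log-logistic curve
for the EC50, or summarized as a linear concentration-response slope.

**NMR CSP.** Per residue, Δδ = √((Δ¹H² + 0.2·Δ¹⁵N²)/2); prolines and
unassigned/overlapped residues are carried as statuses and excluded from
statistics; significance thresholds are the mean Δδ over measurable residues
plus 1 or 2 standard deviations, optionally after averaging a titration
series per residue.

**Thermal shift.** Tm is the temperature of the maximal first derivative
dF/dT (central differences after optional moving-average smoothing), with
boundary and tie flags, plus condition-versus-reference ΔTm.

## Worked example

```python
from bafkit.synthetic_data import ConditionSpec, SimPlateSpec, gen_luv_plate
from bafkit.luv_kinetics import fit_plate

spec = SimPlateSpec(
    time_start=55.0, time_step=55.0, time_count=98,   # 90 min, 55 s reads
    conditions=[
        ConditionSpec("buffer", "buffer", {"level": 10.0}, replicate_count=2),
        ConditionSpec("chaps", "detergent_max", {"level": 510.0}, replicate_count=2),
        ConditionSpec("bax_2t16_bim", "sample",
                      {"b": 12.0, "t": 500.0, "e": 600.0, "h": 2.5, "s": 1.0},
                      replicate_count=3),
    ],
    noise_sd=2.0, seed=42,
)
(row,) = fit_plate(gen_luv_plate(spec))
print(f"endpoint  : {row['endpoint_percent']:.1f} %")
print(f"T, E      : {row['t']:.1f} %, {row['e']:.0f} s")
print(f"max rate  : {row['max_rate']:.3f} %/s at t = {row['x_ip']:.0f} s")
```

prints

```
endpoint  : 97.5 %
T, E      : 98.0 %, 602 s
max rate  : 0.118 %/s at t = 430 s
```

i.e. the triplicate-mean trace, normalized to the buffer/CHAPS controls,
plateaus at 98% permeabilization, crosses half-rise at ~10 min, and releases
dye fastest at ~7 min (0.118 %/s) — recovering the generating parameters
(top 500 on the raw scale ≈ 98% of the CHAPS mean, E = 600 s) from noisy
data. The same plate, map and result schemas are available from the shell:

```sh
bafkit simulate --seed 1 --out-dir sim
bafkit luv-fit --input sim/luv_plate.csv --plate-map sim/luv_plate_map.csv --out-dir out
bafkit synergy --input sim/luv_endpoints.csv --out-dir out
```

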