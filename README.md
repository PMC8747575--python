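# vapsol

**Heat-of-vaporization QSPR and Hildebrand solubility parameters for small
molecules and polymer repeating elements.**

Reliable cohesive-energy-density data for polymers are hard to measure, so
a practical route to polymer solubility parameters is indirect: predict the
heat of vaporization ΔHvap of a small molecule that structurally matches
the polymer's repeating element (RE), convert it to a Hildebrand solubility
parameter, and map that value onto the polymer scale. `vapsol` implements
this chain end to end:

1. **Descriptors.** From a molecular structure (SMILES subset over C/N/O/Cl
   or MOL/SDF V2000) it computes electrotopological-state (E-state) sums and
   count descriptors; from user-supplied quantum-chemical output it derives
   atomization energy AE, quadrupole moment QM = tr(Q)/3, chemical hardness
   η = E_LUMO − E_HOMO and electronegativity χ = −(E_LUMO + E_HOMO)/2 —
   fifteen descriptors in a fixed canonical order. Each heavy atom's
   intrinsic state is I = ((2/N)²δᵛ + 1)/δ and its E-state is
   S_i = I_i + Σ_j (I_i − I_j)/(r_ij + 1)².
2. **Feature selection.** Pearson correlation analysis with a deterministic
   greedy multicollinearity filter (|r| ≤ 0.75 among retained descriptors,
   keeping the member better correlated with ΔHvap).
3. **Models.** Multilinear regression (θ·x + θ₀, ordinary least squares) and
   kernel ridge regression with the polynomial kernel k(x,x′) = (x·x′ + c)^d
   (defaults α = 0.001, c = 1), plus a packaged published MLR instance with
   its thirteen printed coefficients and intercept (kJ/mol).
4. **Validation.** Leave-one-out cross-validation, RMSE / MAE / ARE / R²
   metrics, and an exhaustive (c, d) grid search scored by LOOCV RMSE.
5. **Solubility.** Ecoh = ΔHvap − RT, δ = √(Ecoh/Vm) in MPa^1/2, the RE →
   polymer calibration δ_polymer = 0.602·δ_RE + 5.915, and the empirical
   2 MPa^1/2 miscibility rule.

## Worked example

```python
import numpy as np
from vapsol import (parse_smiles, estate_sums, published_model,
                    cohesive_energy, hildebrand_delta, polymer_sp_from_re,
                    miscibility)

ether = parse_smiles("COC", "dimethyl ether")   # RE of poly(ethylene glycol)
print(estate_sums(ether)["SssO"])               # 4.25  (ether-oxygen E-state)

model = published_model()
x = np.zeros(13)                                # model's 13-descriptor order
x[model.names.index("nHeavyAtom")] = 3
dhvap = model.predict(x[None])[0]
print(round(dhvap, 3))                          # 57.257  kJ/mol

ecoh = cohesive_energy(dhvap)                   # 54778.04 J/mol at 298.15 K
delta_re = hildebrand_delta(ecoh, 80.0)         # 26.167  MPa^1/2 (Vm = 80)
delta_poly = polymer_sp_from_re(delta_re)       # 21.668  MPa^1/2
print(round(delta_re, 3), round(delta_poly, 3))
print(miscibility(delta_poly, 20.0))            # miscible (|Δδ| < 2)
```

The printed numbers mean: the ether oxygen of dimethyl ether carries an
E-state sum of 4.25; a hypothetical three-heavy-atom molecule with all other
descriptors zero is predicted to vaporize at 57.257 kJ/mol; at a molar
volume of 80 cm³/mol that corresponds to an RE solubility parameter of
26.167 MPa^1/2 and a calibrated polymer value of 21.668 MPa^1/2, within
2 MPa^1/2 of a δ = 20 reference and therefore deemed miscible with it.

The same workflow is available from the shell:

```bash
vapsol descriptors --structures mols.smi --quantum qm.csv --out desc.csv
vapsol train --table desc.csv --target-col dhvap --model mlr --out model.json
vapsol loocv --table desc.csv --report report.json
vapsol predict --table desc_new.csv --published --out preds.csv
vapsol sp --table sp_in.csv --reference polystyrene --out sp_out.csv
vapsol simulate --n 61 --p 15 --sigma 2 --seed 1 --out synth.csv
```

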