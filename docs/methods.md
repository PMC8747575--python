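# Methods

## Scope and model

`vapsol` predicts the molar heat of vaporization ΔHvap (kJ/mol) of small
organic molecules from fifteen atomistic descriptors and converts
predictions into Hildebrand solubility parameters δ (MPa^1/2) and
polymer-miscibility calls. ΔHvap serves as a proxy for cohesive energy:
for a low-molecular-weight liquid, Ecoh ≈ ΔHvap − RT and
δ = √(Ecoh/Vm). A polymer's δ is then estimated from the δ of a small
molecule matching its repeating element (RE) through a linear calibration.

The statistical model is deliberately simple: a multilinear regression
(MLR) ŷ = θ·x + θ₀ fit by ordinary least squares, and kernel ridge
regression (KRR) with the polynomial kernel k(x, x′) = (x·x′ + c)^d as the
nonlinear alternative. With only a few dozen training molecules,
leave-one-out cross-validation (LOOCV) is the validation protocol, and the
degree-2 kernel serves mostly as an overfitting control.

## Descriptors

The fifteen descriptors, in the canonical order used everywhere (matrices,
CSV headers, model fingerprints):

| name | meaning | units |
|---|---|---|
| AE | atomization energy (user-supplied) | as supplied |
| QM | ⅓·tr of the second-moment-of-charge tensor | as supplied |
| nAromBond | aromatic bond count | — |
| nHeavyAtom | heavy-atom (non-H) count | — |
| nAcid | carboxylic-acid group count (C(=O)OH) | — |
| SsOH, SssO, SsCH3, SsNH2, SssCH2 | E-state sums over atoms of one type | — |
| SHBa | E-state sum over H-bond acceptors (N, O) | — |
| SHdsCH | hydrogen E-state sum over H on =CH− carbons | — |
| SHBd | hydrogen E-state sum over H on N/O (donors) | — |
| eta (η) | E_LUMO − E_HOMO | as supplied |
| chi (χ) | −(E_LUMO + E_HOMO)/2 | as supplied |

Heavy-atom E-states follow the standard Kier–Hall construction on the
hydrogen-suppressed graph: intrinsic state I = ((2/N)²δᵛ + 1)/δ with
δᵛ = Zᵛ − h, δ the heavy-atom sigma degree and N the principal quantum
number (δ = 1 by convention for a single-heavy-atom molecule), perturbed as
S_i = I_i + Σ_j (I_i − I_j)/(r_ij + 1)² over topological bond distances
r_ij. The perturbation is antisymmetric, so Σ S = Σ I for every molecule —
enforced as a test invariant. The heavy-atom values are cross-checked in
the test suite against RDKit's independent E-state implementation (1e-6
agreement on the 16-molecule RE fixture set).

**Hydrogen E-state convention.** The hydrogen-atom descriptors (SHBd,
SHdsCH) have no universally fixed published formula at the level of detail
needed here, so the package adopts and documents one: a hydrogen carries
the intrinsic state obtained from the same formula with δᵛ = δ = 1 and
N = 1 (I_H = 5) and is perturbed against the heavy-atom intrinsic states at
hydrogen-augmented distances (one bond to its parent, parent distance + 1
beyond). Heavy-atom values are unaffected. Any fixed, monotone convention
serves the purpose of these descriptors — ranking donor-hydrogen
environments consistently; results using SHBd/SHdsCH are comparable only
within this convention.

**Quantum block units.** AE and QM pass through in whatever units the
user's electronic-structure code emits; nothing is converted. Consequently
the packaged published-model coefficients are only meaningful with AE/QM
in the original training units; evaluations of that model in the package's
own tests use descriptor-space anchor points (zero vector, unit
increments), which are unit-free statements about the coefficients
themselves.

## Descriptor selection

`selection.multicollinearity_filter` makes reproducible what is often a
manual step: compute the Pearson correlation matrix (constant columns are
an error, not NaN), then repeatedly locate the retained pair with the
largest |r| above the threshold (default 0.75) and drop its member with the
smaller |correlation with the target|, ties resolved toward keeping the
earlier column in canonical order. The procedure is deterministic and
idempotent, and the filtered set provably contains no pair above the
threshold. The fifteen-name registry shipped in the package is a fixed
curated outcome, not something the filter is expected to rediscover.

## Models and numerics

- **MLR** solves least squares via economy QR (`scipy.linalg.lstsq`), with
  a column-pivoted QR rank check beforehand; rank deficiency raises an
  error naming the collinear columns. The one degenerate case handled
  specially is an all-zero design matrix, which yields the intercept-only
  model θ₀ = ȳ.
- **KRR** solves (K + αI)a = y − ȳ by Cholesky factorization (α > 0 makes
  the system positive definite); prediction is Σ a_i k(x_i, x) + ȳ.
  Defaults α = 0.001, c = 1, d ∈ {1, 2}. Descriptors are z-scored before
  the kernel by default — raw atomization energies would otherwise dominate
  the inner product — and the flag, means and scales are stored in the
  model file. Targets are centred and the mean restored at prediction; both
  choices are recorded so models are self-describing.
- **Kernel–primal equivalence.** For d = 1 the kernel feature map is affine,
  so KRR training-set predictions converge to the OLS fit as α → 0. The
  test suite checks this at α = 1e-7: small enough that the ridge bias
  (∝ α/λ_min of the Gram matrix) is far below the 1e-4 comparison
  tolerance, large enough to avoid the floating-point cancellation that
  dominates below α ≈ 1e-9 at this problem size.
- **Model files** are schema-versioned JSON carrying a descriptor-order
  fingerprint (SHA-256 prefix of the joined names); prediction on a table
  whose column order mismatches the fingerprint is refused. Registry
  coefficients are stored as their printed decimal strings and round-trip
  bit-exactly.

## Validation

Metrics: RMSE = √(Σ(y−ŷ)²/n), MAE = Σ|y−ŷ|/n, ARE = Σ|1 − ŷ/y|/n,
R² = 1 − SSres/SStot. ARE takes the absolute value — the quantity is an
error magnitude, and a signed version would let over- and under-prediction
cancel; a zero reference value is an explicit error. LOOCV metrics are
computed on the pooled vector of the n held-out predictions (the common
convention; per-fold averaging of single-point folds would make RMSE = MAE
trivially). Training and LOOCV splits are always reported separately. The
LOOCV driver is validated against the exact PRESS hat-matrix identity
ŷ₍₋ᵢ₎ = (ŷᵢ − hᵢᵢyᵢ)/(1 − hᵢᵢ) for linear trainers. Grid search over
(c, d) is exhaustive, scored by LOOCV RMSE, ties broken toward smaller d
then smaller c.

## Solubility chain

Fixed unit conventions: ΔHvap in kJ/mol, T in K (default 298.15 K,
configurable and recorded in every record — the approximation is commonly
applied near ambient conditions and the reference temperature is a user
choice), R = 8.314462618 J mol⁻¹ K⁻¹, Ecoh in J/mol, Vm in cm³/mol, δ in
MPa^1/2 (J/cm³ ≡ MPa). Non-positive Ecoh or Vm is an error rather than a
NaN. The packaged RE→polymer calibration is δ_polymer = 0.602·δ_RE + 5.915
(R² = 0.855, n = 16); `fit_calibration` refits it from user pairs by least
squares and requires ≥ 3 non-degenerate points. Miscibility: immiscible iff
|δ₁ − δ₂| > 2 MPa^1/2; the boundary |Δδ| = 2 is classified miscible, a
documented convention since the empirical rule leaves equality open. Molar
volumes are always explicit user inputs; the package deliberately does not
estimate Vm.

## Synthetic data

The generator (`synthdata.generate_regression_data`, versioned "pcg64-v1")
emulates a descriptor table at the study scale — 61 molecules × 15
descriptors is the default protocol size throughout the tests and the
acceptance script. Columns cycle through archetypes matching the magnitude
mix of real descriptor tables: Poisson(3) counts, |N(5, 3²)| E-state-like
sums, N(−5, 1.5²) atomization-energy-like values and N(0.3, 0.1²)
orbital-gap-like values. The target is exactly linear in the features plus
N(0, σ²) noise with σ = 2 kJ/mol by default, i.e. of the order of the
experimental scatter in vaporization enthalpies. Default coefficients are
drawn once per seed and scaled inversely to the column magnitude so each
descriptor contributes comparably.

What this emulates — and what it does not: the synthetic tables reproduce
the dimensions, column scales and noise level of the real problem, so they
exercise the full fitting/validation machinery and expose the expected
qualitative behaviour (KRR d = 1 ≈ MLR; KRR d = 2 overfits: best training
RMSE, worst LOOCV RMSE). They are linear by construction, with independent
columns; real descriptor tables are correlated and at best approximately
linear in ΔHvap. Passing the synthetic suites therefore demonstrates the
correctness of the machinery, not the accuracy of the descriptor set on
real molecules. The per-molecule experimental ΔHvap values of the original
training set were published only in an appendix and are not reproduced or
fabricated here; the fixture tables carry exactly the printed composition
summaries, the RE list, the descriptor and coefficient registries, and the
two printed range anchors (8.19 kJ/mol methane, 69.00 kJ/mol heptanoic
acid).

## Structure input

The supported SMILES subset covers the chemistry of the fixture sets:
C, N, O, Cl with implicit hydrogens, branches, rings, bond orders 1–3,
aromatic (lowercase or Kekulé benzene-like) rings; no stereochemistry,
isotopes, charges or multi-fragment input — unsupported tokens are rejected
by name and position rather than guessed at. MOL/SDF V2000 is accepted as
the exchange format. RDKit performs the parsing and aromaticity perception
behind this validation layer; descriptors are 2-D/topological throughout,
so any 3-D coordinates in input files are ignored.

## Known limitations

- The published-model coefficients cannot be applied to freshly computed
  AE/QM values without knowing the original units/scaling of those inputs;
  the package stores unit strings but refuses to guess conversions.
- Hansen three-component parameters, Flory–Huggins interaction estimates,
  internal Vm estimation, and kernels beyond the polynomial family are out
  of scope.
- The hydrogen E-state convention is package-defined (see above);
  SHBd/SHdsCH values are not numerically interchangeable with other codes'
  hydrogen E-states, though orderings of similar environments agree.
- The miscibility rule is a coarse empirical screen; a 2 MPa^1/2 window on
  δ ignores polarity/H-bonding decomposition, polymer molecular weight and
  end-group effects.
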