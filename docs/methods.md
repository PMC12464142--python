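# Methods

## The model

The package treats the hydration of imidazole with a cluster-continuum
(hybrid explicit/implicit) scheme: a few explicit water molecules around
the solute carry the specific hydrogen-bond physics, while the remaining
solvent is summarized in the energies of "solvent-phase" species supplied
as input. The hydration enthalpy and free energy at cluster size n are the
reaction quantities of

    IMZ(gas) + (H₂O)_n(aq) → IMZ(H₂O)_n(aq)

ΔH_solv(n) = H[IMZ(H₂O)_n]_water − H[(H₂O)_n]_water − H[IMZ]_gas, and the
same with G. H and G of the solvated species are Boltzmann-weighted
averages over the located structures of that composition. The profiles
converge in n; the headline estimates are plain means over a stable window
(defaults n = 5–7 for ΔH, n = 3–7 for ΔG, where "variation" of a window is
max − min). Because the waters appear on both sides of the reaction,
systematic per-water errors in the solvent-phase energies cancel; this
error-cancellation structure is property-tested.

## Thermochemistry

Single-structure H, S, G come from the standard RRHO ideal-gas partition
function: translational (Sackur–Tetrode at pressure P), classical
rigid-rotor with symmetry number σ, and quantum harmonic oscillators with
the zero-point energy kept separate. H includes the pV term
(H = E_elec + ZPE + E_thermal + RT), and G = H − T·S identically.

Defaults and their rationale:

* **standard state 1 atm** for every species, gas and solvent-phase alike;
  no 1 atm → 1 M correction is applied by default because the reaction
  deltas are taken exactly as the partition functions produce them. The
  correction would shift ΔG by a constant; callers who need it can apply
  it to the inputs.
* **σ = 1** for all clusters (hydrogen-bonded clusters are asymmetric);
  override per species where appropriate (e.g. σ = 2 for an isolated
  water). Entropies of symmetric species therefore differ from a
  σ-detecting code by R ln σ.
* **frequency scale factor 1.0**; harmonic frequencies are used as given.
* **low-frequency modes fully harmonic** — no quasi-RRHO damping. This is
  the plainest reading of the rigid-rotor/harmonic-oscillator model; it
  overestimates low-mode entropies, but the hydration deltas largely
  cancel the effect between complex and water cluster.
* **imaginary modes are an error** unless explicitly dropped
  (`drop_imaginary=True`), which logs a warning.
* constants from scipy (CODATA); 1 hartree = 627.5095 kcal/mol
  = 2625.4996 kJ/mol.

## Ensembles

Populations use wᵢ ∝ exp(−(Gᵢ − G_min)/kT) (min-shifted for stability).
Weighting is by **Gibbs free energy at the evaluation temperature**; an
electronic-energy weighting can be had by passing E values instead, since
the weight function only sees a vector. T = 0 is the limit: all mass on
the minimum, degenerate minima (within 1e-10 hartree) split equally.
Ensemble ⟨G⟩ is the weighted average of member G values; the
partition-function form −kT ln Σ exp(−Gᵢ/kT) (always lower, by the Gibbs
inequality) is available behind a flag for comparison. Population curves
report members exceeding a 5 % threshold anywhere on the grid.

## Energetics and CBS

Binding energies ΔE_n = E_n − E(IMZ) − n·E(H₂O); stepwise energies
ΔE_n = E_n − E_{n−1} − E(H₂O) with E_0 := E(IMZ), so the stepwise values
telescope exactly to the binding energy (tested to 1e-10 hartree). The
same operations serve enthalpies. No BSSE/counterpoise correction is
applied anywhere.

CBS extrapolation is the two-point scheme with E_SCF(∞) from the
exponential-in-√X form and E_corr(∞) from the X^β power law; the defaults
α = 5.79, β = 3.05 are calibrated to the cardinal pair (N, M) = (3, 4)
(aug-cc-pVTZ/aug-cc-pVQZ) and other pairs require explicit parameters.
Both formulas are affine in the energies (property-tested), so they
commute with unit changes and shifts.

## Benchmark statistics

Per-method deviations are value − reference per cluster size. MAD is the
mean absolute deviation, MAX the maximum absolute deviation, and STD the
**population** (divide-by-K) standard deviation of the signed deviations
about their mean. The population form was adopted because it reproduces
the printed reference value for the best functional (1.6 kcal/mol for
M06L-D3) where the sample (K−1) form gives 1.7. Display rounding is
half-away-from-zero to one decimal, matching how such tables are printed;
two cells of the packaged table (PW6B95D3 STD, MN15 MAX) differ by one
display unit when recomputed from the 1-decimal table entries, consistent
with the original statistics having been computed on unrounded energies.
Ranking is by ascending MAD (ties: STD, then name), reference excluded.

## Hydrogen-bond geometry

QTAIM-style density analysis needs SCF densities and is out of scope;
contacts are typed geometrically instead, which recovers the same four
imidazole–water interaction classes. A D–H···A triple is a contact when
d(H···A) ≤ 2.6 Å (O/N acceptors) and ∠DHA ≥ 120°, common crystallographic
practice; OH···π uses the ring centroid as acceptor with a 3.0 Å cutoff.
A hydrogen already engaged in a σ contact is not re-counted toward the
centroid. Collinearity of N1H···O is reported as the angle, not
thresholded. Cutoffs are conventions — the package's own defaults, since
density-based criteria define no distances — and tightening any cutoff can
only remove contacts (property-tested monotonicity). The out-of-plane
angle of an N3-ward donor is the angle between the N3→O vector and the
best-fit ring plane (0° = in-plane).

## Synthetic data

The generator emulates the study's workflow end to end, desk-scale:

* **Sampler.** Rigid imidazole (9-site planar template) and rigid 3-site
  waters interact through Lennard-Jones + Coulomb site terms
  (Lorentz–Berthelot combination; inter-fragment pairs only). TIP3P-like
  water and CHARMM-style ring charges are package fixtures — a reasonable
  classical surrogate, not a validated force field. Global search is
  seeded basin-hopping: random rigid-body placements, L-BFGS-B local
  minimization, perturbation moves, and an elitist pool of distinct
  minima. This plays the role of a population-based global optimizer —
  producing diverse low-energy candidates — without reproducing any
  specific search algorithm. Candidates whose fragment partition changes
  (a water fusing with the solute under the covalent-bond cutoff) are
  rejected as composition errors. Budgets (default 25 hops, pool 4) are
  desk-scale choices; determinism for a fixed seed is tested bit-for-bit.
* **Mock QM.** Method energies are the classical energy plus a per-method
  systematic bias applied once per bound molecule (fragments − 1), plus
  Gaussian noise (default sd 0.2 kcal/mol). Isolated monomers are
  bias-free, so binding-energy deviations grow linearly in n and the
  benchmark statistics have a closed-form expectation (tested by
  Monte-Carlo against the folded-normal formula). Frequencies are drawn
  class-wise: water stretches 3600–3900 cm⁻¹, bends 1550–1700, ring modes
  600–3500, intermolecular modes 30–800, always totalling 3N−6.
* **Implanted hydration profile.** The solvent-phase species implant a
  target profile that defines the study conditions: plateaus
  ΔH = −58.9 kJ/mol and ΔG = −13.6 kJ/mol at 298.15 K with per-size
  offsets giving overall variations of 15.8 (ΔH, n = 1–8) and 7.3 kJ/mol
  (ΔG), and stable windows n = 5–7 / n = 3–7 whose means equal the
  plateaus. Mechanically, each solvent-phase complex is the matched water
  cluster plus the solute; its six intermolecular modes are set to a
  common frequency solved (Brent's method) so the reaction entropy equals
  (ΔH* − ΔG*)/T, then its electronic energy is solved so the reaction
  enthalpy equals ΔH* at 298.15 K. Both targets are then recovered
  *exactly* through the real RRHO/ensemble/hydration machinery at zero
  noise, and within sampling error under noise (noise enters as a Gaussian
  perturbation of the complex electronic energy, the stand-in for
  run-to-run QM/continuum scatter). Away from 298.15 K the residual
  temperature dependence of ΔH comes from the unmatched thermal terms
  (six low modes vs. one lost set of translations/rotations, net ≈ 2RT),
  so ΔH(T) drifts only a few kJ/mol over 200–400 K while ΔG(T) rises
  nearly linearly and crosses zero near 390 K.

What the generator does **not** emulate: real anharmonicity, cooperative
polarization of hydrogen-bond networks, basis-set or density-functional
error structure beyond a linear-in-n bias, and continuum-solvation physics
(the "solvent" tag carries an implanted shift, not an electrostatic
model). Passing tests therefore demonstrate the correctness of the
analysis pipeline under controlled conditions, not the accuracy of any
force field or electronic-structure method on real data.

## Numerical choices

* Bond detection: covalent-radius sum × 1.2 — robust for H/C/N/O organics.
* Fragment ids ordered by lowest atom index → deterministic,
  permutation-consistent partitions.
* Boltzmann degeneracy tolerance at T = 0: 1e-10 hartree.
* Stiff-mode exponentials clamped at x = 500 to avoid overflow; a mode at
  5·10⁴ cm⁻¹ contributes exactly zero vibrational entropy in double
  precision.
* Stable-range suggestion: the largest trailing window with variation
  below 2.5 kJ/mol (a single point if even the last two sizes disagree).
* Pipeline artifacts are written with fixed `%.10g` formatting and sorted
  JSON keys so fixed-seed reruns are byte-identical.

## Problem sizes

Default analyses run cluster sizes n = 1–8 with sampler budgets of order
10 hops per size and ensembles of up to a handful of minima per size —
enough to exercise every stage while keeping a full study in the
minutes range on one core. The test suite uses smaller budgets (2–4 hops,
pools of 1–2); the implant construction is exact regardless of sampler
effort, since it conditions on whatever geometry the sampler returns.

## Known limitations

* The rigid-body sampler explores far less of the landscape than a
  population-based global optimizer; its minima are illustrative, not
  exhaustive.
* Free energies of low-frequency cluster modes are harmonic; real
  intermolecular modes are strongly anharmonic.
* The 1 atm standard state is applied uniformly; comparing ΔG_hyd against
  solution-phase conventions (1 M) requires an external correction.
* Geometric hydrogen-bond typing is a surrogate for density-based bonding
  analysis; quantitative comparison of contact strengths is outside its
  reach.
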