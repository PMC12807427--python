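# Methods

## Scope and model

The package post-processes (accelerated) molecular-dynamics output of a
protein–RNA complex: it does not run solvated MD itself.  Its five analysis
pillars — aMD boost/reweighting, free-energy surfaces, Cartesian PCA,
native-contact analysis, and contact PCA — operate on three kinds of input:
a reference structure (multi-model PDB; analyses conventionally use model
1), coordinate trajectories (multi-model PDB or plain per-frame coordinate
tables, Å), and per-frame energy logs (kcal mol⁻¹).  A synthetic generator
supplies trajectories with exact ground truth for validation.

## aMD boost and parameter heuristics

The boost ΔV = (E − V)²/(α + E − V) applies only below the threshold E; the
boosted surface V* = V + ΔV is continuous and once-differentiable at V = E,
stays below E, and is strictly increasing in V, so basins are flattened but
never reordered.  Forces on the boosted surface scale by dV*/dV =
α²/(α + E − V)², which is the factor the toy sampler applies.

Dual-boost parameters come from conventional-MD averages via the standard
linear heuristics:

- `E_tot = ⟨V_tot⟩ + 0.16 kcal mol⁻¹ atom⁻¹ × N_atoms`
- `α_tot = 0.2 kcal mol⁻¹ atom⁻¹ × N_atoms`
- `E_dih = ⟨V_dih⟩ + 3.5 kcal mol⁻¹ residue⁻¹ × N_residues`
- `α_dih = 0.2 × 3.5 kcal mol⁻¹ residue⁻¹ × N_residues`

`N_atoms` is taken verbatim (solvated systems count water); `N_residues`
counts solute residues plus nucleotides.  Full precision is kept internally;
values are rounded to the nearest integer only at report time, which is how
such parameters are conventionally quoted.  The dual-boost evaluation order
follows the Amber convention: the dihedral boost is computed first and the
total-potential boost is evaluated on the dihedral-boosted total.  The toy
sampler exercises only the total channel, because analytic toy potentials
have no dihedral term.

## Reweighting and free-energy surfaces

Exponential reweighting (w ∝ exp(βΔV), max-subtracted before
exponentiation) is the default; a Maclaurin partial sum of configurable
order is provided because the exponential estimator is noisy at large βΔV.
Both agree to <1e-6 at order 30 for βΔV ≤ 5, which is the regime the toy
systems operate in.  kB is fixed at 0.0019872041 kcal mol⁻¹ K⁻¹ and the
temperature defaults to 300 K.

Surfaces are weighted histograms, G = −kT ln ρ, min-shifted to zero, with
+∞ on empty bins.  Basin ΔG is the difference of basin-minimum bin values;
the barrier is the minimax ("lowest saddle") path value between the two
basin minima over face-adjacent occupied bins, found with a Dijkstra-style
search that works in any dimension (in 1D it reduces to the maximum over the
interval between minima).

## Toy Langevin sampler

BAOAB splitting; defaults: mass 12 amu, friction 1 ps⁻¹, dt 0.002 ps,
samples stored every 10 steps after 2000 equilibration steps, positions in
Å, energies in kcal mol⁻¹ (1 kcal mol⁻¹ = 418.4 amu Ų ps⁻²).  dt × max(ω,
γ) is validated against the stiffest curvature of the double well (ω ≈ 29
ps⁻¹ at the default barrier height of 3 kcal mol⁻¹), and a guard radius
aborts cleanly on divergence.  These numerical choices were fixed once for
stability and ergodicity: at 2 × 10⁵ stored samples the unboosted sampler
crosses the 3 kcal mol⁻¹ barrier ~10² times, enough for a converged
two-basin surface, while the boosted sampler (E at the barrier top, α = 1
kcal mol⁻¹) crosses an order of magnitude more often.  The
boosted-reweighted and unboosted surfaces agree to ~0.1 kcal mol⁻¹ RMS over
shared bins at that sample count, and basin ΔG on a tilted well matches 1D
quadrature to well under 0.3 kcal mol⁻¹; these figures are recomputed by the
test suite and `scripts/acceptance.py`, never assumed.

## Cartesian PCA

Population covariance (divide by F) of the selected coordinates — protein
Cα by convention — after rigid-fitting every frame to the starting
structure over the same selection.  Fitting to the reference (rather than
the ensemble mean) is the default because the reference structure anchors
every other analysis; a one-iteration mean-fit variant is available.
Replicas are concatenated before averaging.  No mass weighting.  The
eigensolver is `numpy.linalg.eigh` with eigenvalues sorted descending and
each eigenvector's sign fixed so its largest-magnitude component is
positive; Cartesian PCA and contact PCA share this solver so identical
matrices give identical spectra.  Rigid fitting removes six degrees of
freedom, leaving ≥ 6 numerically null modes.  Full decomposition is cheap at
the target sizes (3N ≲ 1500), so no truncated solvers are used.

Superposition is the closed-form proper-rotation least-squares fit
(reflection-corrected, via `scipy.spatial.transform.Rotation.align_vectors`);
collinear or coincident fit sets are rejected.  RMSD series fit and measure
on the same selection; per-frame means and sample standard deviations across
replicas summarise multi-replica runs.

## Contacts and contact PCA

Native contacts use the strict rule (min heavy-atom distance < cutoff,
default 6.0 Å) on the reference; contact *counting* uses the inclusive rule
(≤), matching the "within" phrasing that typically accompanies count
reports — the difference is measure-zero in practice and both are
configurable.  Hydrogens are excluded on both sides.  No periodic-image
handling: analysis trajectories are assumed solute-only.  Counting is
offered per residue (default) and per atom pair, since published contact
counts do not always say which granularity was used.  Methylated-adenosine
residue names (6MA, 6MZ, M6A, MA6, A2M, …) are classified as nucleotides via
an extensible alias table.

Contact PCA diagonalises the covariance of raw distances (no switching
function, no standardisation), so a contact's weight scales with the square
of its fluctuation in Å; a correlation option exists but is off by default.
Components are ranked by |component| with ties kept in native-contact order
and signs preserved; a coherence flag reports whether the top-k components
share a sign (simultaneous forming/breaking).  Representative frames are the
extreme PC1 projections, the same convention as Cartesian-PCA extreme
conformations.

## Synthetic generator

The template plants a closed-state contact shell: nucleotide 3 sits at the
pocket centre with one heavy atom each from the 7 pocket residues (inward
from below) and the 12 loop residues (inward from above) at ~4.6 Å, i.e. 19
native contacts, the maximal shell consistent with keeping every contact
inside the loop ∪ pocket ranges.  Other nucleotides trail away in the
equatorial plane and touch one designated peripheral residue each; the
remaining residues sit on a distant arc.  A seed-derived global rotation
fixes the opening direction, so PC1 has a known target for
cosine-similarity checks.

Dynamics: a stationary two-state Markov chain (switch probabilities
`rate × occupancy` and `rate × (1 − occupancy)`, defaults rate 0.05, target
occupancy 0.5 for `two_state`, 0.15 for `partial_opening`, pinned closed
for `closed_stable`), 1000 frames × 3 replicas by default — the ensemble
size at which the PCA conventions here are routinely applied — with replica
r seeded by `seed + r`.  Open frames displace all loop atoms rigidly by the
open amplitude (default 8 Å) along the opening direction; every atom gets
isotropic Gaussian noise (default σ = 0.2 Å).  The generator verifies that
opening clears every planted loop contact beyond the cutoff by ≥ 2σ and
raises otherwise; an achieved-occupancy warning fires when the finite chain
strays more than 0.1 from target.

The Markov construction (rather than Langevin on a loop coordinate) gives
closed-form occupancy expectations, which the validation needs.  What the
generator does *not* emulate: sterics, bonded energetics, correlated or
anisotropic fluctuations, gradual (non-two-state) opening, and solvent.
Passing tests therefore demonstrate that the analysis machinery recovers
planted statistical structure exactly; they do not certify behaviour on
real force-field trajectories, whose noise is correlated and whose states
are not cleanly two-valued.

## Pipeline

One validated config (pydantic; unknown keys rejected, defaults filled
explicitly) drives RMSD → PCA/cross-projection → contacts → contact PCA →
optional reweighted FES over (PC1, PC2).  Exactly one system defines the
PCA subspace; all systems are cross-projected onto it.  Replicas are
concatenated for PCA and contact PCA but summarised frame-wise across
replicas for RMSD.  Outputs are CSV/PDB files registered in a manifest
keyed by a sha256 hash of the canonical config; reruns with the same config
and seed are byte-identical.  A stage failure aborts with the stage name.

## Numerical notes and edge cases

- Superposition rejects fit sets whose centered coordinates are rank < 2.
- Covariances are symmetrised (0.5(C + Cᵀ)) before decomposition; PSD is
  enforced to −1e-8 × trace.
- Weight normalisation subtracts max(βΔV) before exponentiation, so
  arbitrarily large boosts cannot overflow.
- Empty FES bins carry +∞ and are excluded from min-shifting and from
  basin/barrier searches; a degenerate all-in-one-bin surface warns.
- Argmin/argmax tie-breaks always resolve to the lowest frame index.
- Selections are conjunctive only (`name CA and protein`); an empty result
  is an error unless explicitly allowed.

## Known limitations

- The real reference complex (a deposited NMR structure) is not bundled;
  structure-specific results, such as that complex's 20-contact native set,
  can be reproduced by pointing `read_pdb`/`native_contacts` at a local
  copy.  The synthetic template's 19-contact shell is a constructed
  stand-in, not that structure.
- Quantities that require microsecond explicit-solvent trajectories
  (basin ΔG/barriers of the real receptor, PC1/PC2 contribution
  percentages, binding free energies) are out of scope by design; the toy
  and synthetic systems validate the *methods*, not those numbers.
- Binary trajectory formats (DCD/XTC/NetCDF) are not read; convert to
  multi-model PDB or coordinate tables first.
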