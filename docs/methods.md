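# Methods

This note documents the models implemented in `helioproton`, the defaults
that matter, the numerical choices, and what the synthetic-data suite does
and does not establish about real data.

## Protonation-microstate model (`microstates`)

A titratable site is a two-state proton-binding unit. Acids carry charge
0/−1 (protonated/deprotonated), bases +1/0. The microstate energy is

E(x; pH) = Σ_μ x_μ·ΔG_int,μ + ½ Σ_{ν≠μ} q_μ q_ν W_μν,  with
ΔG_int,μ = k_B·T·ln10·(pH − pKa_int,μ).

The same sign convention holds for acids and bases — the kinds differ only
through their charge pairs — which reproduces Henderson–Hasselbalch for
both when W = 0. Probabilities are Boltzmann averages at T = 300 K.

*Enumeration* sums all 2^N states (capped at N = 25; energies are shifted
by their minimum before exponentiation). *Monte Carlo* runs Metropolis
sweeps: N single-site flips in random order per sweep, plus one paired flip
per strongly coupled pair (|W| > 2.5 kcal/mol) so that anticorrelated
proton arrangements are not frozen out. The first 10% of sweeps are
discarded; standard errors come from 20 batch means, which absorb the
sweep-to-sweep autocorrelation. The seed is mandatory; identical inputs
give bit-identical results. Pinned sites (probability exactly 0 or 1 in
every batch) report SE = 0; comparisons against exact values therefore add
a small absolute floor.

*Half-titration pKa.* Curves are evaluated on an ascending pH grid; the
per-site pKa_half is the linear interpolation of the descending ⟨x⟩ curve
through 0.5, with an exact grid hit taking the lower pH, and NaN when the
curve never crosses (flagged rather than extrapolated).

*Histidine.* The imidazole is two coupled basic sites (Nε, reference pKa
7.0; Nδ, 6.6). The physically absent imidazolate (both sites deprotonated
below pH ~14) is suppressed by a penalty c on the (0,0) configuration.
Within the q·q·W energy form this is implemented exactly by setting
W(Nε,Nδ) = c and raising both intrinsic pKa values by c/(k_B·T·ln10): the
three physical states keep their relative energies and only the anion is
penalized. Default c = 12 kcal/mol keeps the anion population below 2% up
to pH 12 while leaving the doubly protonated cation reachable at low pH.
The coupling is a documented model default, not a literature value.

## Continuum electrostatics (`electrostatics`)

The linearized Poisson–Boltzmann equation ∇·(ε∇φ) − εκ²φ = −4πCρ is
discretized with the 7-point stencil on cubic-cell grids; φ is in
kcal/(mol·e) with C = 332.06 kcal·Å/(mol·e²).

- **Dielectric boundary**: van der Waals union of atom spheres (radii C
  1.7, N 1.55, O 1.52, S 1.8, P 1.8, H 1.0 Å), ε = 4 inside, 80 outside.
  Edge permittivities are assigned from edge-midpoint membership, which
  resolves the boundary half a cell finer than the node map; no reentrant
  (molecular) surface and no boundary smoothing.
- **Salt**: κ² takes its bulk Debye value (100 mM 1:1 at 300 K gives a
  9.74 Å Debye length) outside the solute expanded by a 2.0 Å
  ion-exclusion layer, zero inside.
- **Charges** spread to the 8 surrounding nodes trilinearly (total charge
  conserved exactly).
- **Solver**: checkerboard (red/black) Gauss–Seidel with over-relaxation,
  ω = 1.6, stopping when the largest per-sweep update falls below 1e-6
  kcal/(mol·e), hard cap 10⁴ iterations (an explicit error, never a silent
  partial solve).
- **Focusing**: default schedule 2.5 → 1.0 → 0.3 Å. The coarsest grid takes
  analytic screened-Coulomb Dirichlet boundaries in bulk solvent; each
  finer grid interpolates its boundary trilinearly from the parent
  solution. Boxes are sized so the solute spans at most 60% of the coarse
  box (at least 30 Å) and the finest box wraps the solute plus 3 Å, with
  an odd node count so the solute center sits on a node.

Sphere radii, the Stern layer, box fill and the boundary treatment are
package defaults chosen from common practice for this solver family; they
are configurable and validated only at toy scale (the Born ion lands within
5% of the analytic energy on the default schedule, with monotone error
reduction across the levels).

**Energetics.** Solvation (reaction-field) energies subtract a homogeneous
salt-free solve (ε = 4 everywhere) on the *identical* grids, so the grid
self-energy of the spread charges cancels exactly. Intrinsic pKa values
close the thermodynamic cycle protein-vs-model-compound,
protonated-vs-deprotonated:

pKa_int = pKa_ref − ΔΔG/(k_B·T·ln10),
ΔΔG = [G_prot − G_deprot]_protein − [G_prot − G_deprot]_model,

with the model compound being the site's own atoms at unchanged geometry.
Fixed background charges contribute through the protein-leg potential
only (the model compound has none). When the protein *is* the model
compound the cycle closes identically — bit-equal solves — which the
acceptance suite checks to < 0.01 pK. W_μν is the interaction of site μ's
protonated-minus-deprotonated charge difference (obtained from the two
environment solves by linearity) with site ν's; the discrete Green's
function makes W symmetric up to interpolation error, asserted < 0.05
kcal/mol and then symmetrized.

## Proton-transfer scan (`ptscan`)

The scanned coordinate is d(H–A), reduced in 0.05 Å steps from the initial
geometry to a terminal 1.0 Å (a covalent H–A bond; the protocol's stopping
point "H reaches A" is not a number, so the default is the bond length and
is configurable). The constraint is eliminated exactly: H is parameterized
on the sphere of the target radius around the acceptor, and its two
angular coordinates are relaxed by Nelder–Mead (coordinate tolerance
1e-10) warm-started from the previous point. Donor and acceptor stay
fixed. Profiles are reported relative to the first point; statistics are
the maximum (barrier), the endpoint difference, and a downhill flag.

The surrogate surface is a two-diabat empirical-valence-bond construction:
harmonic diabats in d(D–H) and d(H–A) (default stiffness 300 kcal/mol/Å²,
bond length 1.0 Å), constant coupling (10 kcal/mol), adiabatic ground
state as the lower 2×2 eigenvalue. Its symmetric case has provably equal
endpoints and a midpoint barrier, and closed-form endpoint energies at the
collinear geometry serve as an independent oracle for asymmetric cases.
Note the endpoint asymmetry of the adiabatic profile is not exactly the
diabat offset — the coupling contributes differently at the two ends — so
tests derive the expected value from the closed form rather than from the
offset parameter.

## Trajectory statistics (`trajectory`)

Classifications are distance-only and total: Trp246 frames fall into
in(+H-bond) (d < 3.5 Å), in(−H-bond) (3.5 ≤ d ≤ 6.0 Å) and out
(d > 6.0 Å) on the Gln26 side-chain O to Trp246 side-chain N distance
(default atom names OE1/NE1 — the published rule names the side-chain
atoms but not the PDB atom names; both are configurable). The gate
classifier needs both d(O_Glu230–O_Tyr92) and d(O_Tyr92–N_Asn16) below
3.5 Å for "closed" and both at/above for "open"; frames satisfying
neither pure class are reported as "mixed" rather than silently folded
into either, so the two pure classes stay directly comparable. Population
tables report per-replicate fractions and a pooled row weighting every
frame equally (5 × 1000 frames by default).

RMSF superposes frames onto the iterated mean structure over backbone Cα
(first-frame reference by flag; which alignment the original analysis used
is not stated, so both are exposed), takes per-atom root-mean-square
deviations from the mean position, and averages heavy side-chain atoms
per residue without weights. Replicate tables carry the across-run mean
and SD; ΔRMSF subtracts the reference-state mean per residue.

## Synthetic data (`synthetic`)

Generators are pure functions of their spec (seed mandatory, streams for
system generation and noise spawned separately); all bundled ground truth
comes from independent code paths — a plain nested-loop Boltzmann sum for
titration fixtures, the eigenvector stationary distribution for Markov
chains.

The trajectory generator emulates the replicate design of the MD analysis:
5 runs × 1000 frames × 0.15 ns, a hidden two-state (or k-state) Markov
chain switching the monitored distances, Gaussian per-state distance
distributions (defaults: in 3.0 ± 0.15 Å, out 7.5 ± 0.4 Å, spanning the
classifier thresholds the way the real conformers do), and isotropic
Gaussian positional noise on all atoms. What it does *not* emulate:
force-field dynamics, solvent and membrane, correlated side-chain motion,
periodic boundaries. Passing recovery tests therefore demonstrates that
the estimators are unbiased and correctly normalized on data with the
stated statistical structure — not that real MD trajectories satisfy that
structure.

Analysis drivers use stay-probabilities chosen to emulate the qualitative
pattern of the study conditions (ground-like runs dominated by the
in/closed classes, M-like runs shifted toward out/open); these are
generator settings with known stationary distributions, not fitted values.

## Problem sizes and tolerances

Validation solves run on toy solutes (1–30 spheres) where the focusing
boxes stay below ~40³ nodes at the finest level; exact enumeration backs
systems up to 10 sites in randomized tests; Monte-Carlo validation uses
10⁴ sweeps against 3 batch-mean SEs plus a 5e-3 floor for pinned sites.
Closed-form solver checks assert 2% (Coulomb), 3% (screened Coulomb) and
5% (Born) relative error. The crystal-structure measurement tests require
the deposited PDB entries, which are not redistributed with the package;
without the files under `data/reference_structures/` they fail with a
pointer message.

## Known limitations

- Linear PB only; no molecular surface, membrane dielectric slab, or
  protein-scale production runs.
- The microstate model has two-state sites (histidine as a coupled pair);
  no tautomer-resolved rotamers or conformational flexibility.
- PDB support covers ATOM/HETATM/MODEL/TER with altloc collapse; no mmCIF,
  insertion codes, or symmetry expansion.
- The scan driver relaxes only the hydrogen's angular coordinates; donor
  and acceptor are clamped (sufficient for surrogate surfaces; a richer
  free-coordinate contract would be needed for polyatomic surfaces).
- Absorption predictions start from a supplied excitation energy; the
  calibration line is shipped, not refit.
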