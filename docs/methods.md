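# Methods

## Scope and model

The package implements the desk side of a terpenoid-toxicity QSAR study:
percent-inhibition processing of *Vibrio fischeri* bioluminescence kinetics,
CODESSA-style molecular descriptors from 3D structures, and heuristic-method
(HM) multilinear model selection with leave-one-out and external validation.
The statistical model is ordinary least squares,

y = β₀ + Σ βⱼ xⱼ + ε,

with y the 20-min percent inhibition at one assay concentration and xⱼ a
small descriptor subset (at most min(4, n_train/4) terms, keeping at least
four training compounds per fitted descriptor). Subset choice is by training
r² under the HM's admissibility rules; the assumptions are those of OLS plus
the implicit claim that a 4-term linear surface in descriptor space captures
the toxicity mechanism well enough to interpolate within the chemical series.

## Structures and conformers

Input SMILES are embedded with ETKDGv3 and relaxed with MMFF94 (UFF for the
rare molecule without full MMFF parameters); the lowest-energy of `n_conf`
(default 20) seeded conformers is kept, with explicit hydrogens throughout.
One geometry per molecule feeds every geometric descriptor — no Boltzmann
averaging.

Two caveats are worth stating plainly:

- A classical gas-phase force field over-stabilizes folded chain conformers
  (intramolecular dispersion contacts) relative to the extended geometries a
  semiempirical refinement of a sketched structure produces. For flexible
  acyclic terpenoids the lowest-energy basin is therefore often folded, and
  shape descriptors such as asphericity computed from it are systematically
  lower than values derived from extended geometries. β-citronellol, for
  example, has near-degenerate MMFF basins spanning Ω ≈ 0.36–0.66.
- At `n_conf = 20` which basin wins is seed-dependent for molecules with many
  rotatable bonds (the basins sit within ~0.3 kcal/mol). Reported asphericity
  values for flexible compounds should consequently be read with a ±0.1
  tolerance, and comparisons across software with different geometry
  provenance can disagree by more.

Principal-axis alignment centers the molecule at its center of mass and
rotates onto the inertia eigenvectors with moments ascending on X, Y, Z (the
long axis lands on X); the atom with the largest absolute coordinate on each
axis is given a positive sign, which makes the orientation deterministic and
the operation idempotent. The XY shadow is then the projection with the
largest footprint.

## Descriptors

**Zefirov/Sanderson charges.** One-shot electronegativity equalization:
χ_M is the geometric mean of atomic Sanderson electronegativities and
q_i = (χ_M − χ_i)/(2.08 √χ_i) in elementary charges. The raw formula does not
conserve charge exactly (for CH₄ the residual is ≈ 1.6 × 10⁻⁴ e); by default
the residual is redistributed uniformly over the atoms so Σq equals the net
formal charge to machine precision. `conserve=False` returns the raw values.

**Surfaces and CPSA.** Per-atom exposed area on the bare van der Waals
surface (Bondi radii, probe 0) by Shrake–Rupley sampling with a deterministic
golden-spiral point set, 960 points/atom by default (≈1% area accuracy for
isolated spheres; rotation-invariant only to the sampling resolution, ≈1–2%).
PNSA-1 and PPSA-1 partition the total area TMSA by charge sign (exact zeros
count as positive, so PNSA1 + PPSA1 = TMSA is an identity);
WNSA-1 = PNSA1·TMSA/1000.

**Asphericity.** Ω = [(λ₁−λ₂)² + (λ₁−λ₃)² + (λ₂−λ₃)²] / [2(λ₁+λ₂+λ₃)²] with
λᵢ the eigenvalues of the mass-weighted gyration tensor. This normalization
maps a perfectly linear arrangement to exactly 1 and any spherically
symmetric point set (tetrahedron, octahedron) to exactly 0, and is invariant
to rigid motion. A unit-weight variant (`weights="unit"`) is provided because
descriptor packages disagree on the weighting; the mass-weighted form is the
default.

**Shadows.** Union-of-disks areas of the projected atomic vdW disks on the
three coordinate planes of the aligned molecule, rasterized at a 0.05 Å grid
(converges to the analytic union area as the grid shrinks; 2% agreement with
closed-form lens areas at the default grid). Unaligned input is rejected
rather than silently aligned, so the caller controls geometry provenance.

**Topological indices.** Kier shape indices on the hydrogen-suppressed graph
without the α-modification: ¹κ = A(A−1)²/P₁², ²κ = (A−1)(A−2)²/P₂², and
³κ = (A−1)(A−3)²/P₃² for odd A, (A−3)(A−2)²/P₃² for even A, with Pₘ the
number of m-edge simple paths counted once per path. Kier–Hall connectivity
ᵐχ(ᵛ) sums (Π δ)^(−1/2) over m-edge subpaths, δᵛ = Zᵛ − h for second-row
atoms and (Zᵛ − h)/(Z − Zᵛ − 1) beyond; an empty path set gives 0 by
convention. Both are verified in the test suite against exhaustive
networkx path enumeration on every tree skeleton up to 8 heavy atoms.

**Constitutional / physicochemical.** Counts are taken with explicit
hydrogens; the relative number of single bonds counts aromatic bonds as
non-single (a convention — flagged in the matrix metadata by name only, and
chosen because an aromatic bond is not a saturated linkage). log P is the
Wildman–Crippen atomic-contribution sum.

**External columns.** Quantum-chemical descriptors (orbital electronic
populations) require a semiempirical SCF and are accepted only as external
CSV columns keyed by compound id; compounds without a value get NaN, which
the prescreen's missing-value rule then removes.

## Heuristic method

Pre-screening applies, in order: (i) drop columns with any missing value;
(ii) drop exactly constant columns; (iii) drop columns whose one-descriptor
regression on y has F < 1; (iv) drop columns with slope |t| < 0.1; (v)
greedily resolve pairs with |r| > 0.80, keeping the member more correlated
with y (ties keep the lexicographically first name). Every elimination is
tagged with its rule (and, for collinearity, the retained partner), and the
report partitions the input columns exactly. Because the univariate F equals
t², rule (iv) can only fire when the F threshold is lowered below t_min²;
at the defaults it is a formal guard.

The search is stagewise beam search: rank single-descriptor models by r²,
extend each of the top `beam_width` (default 50) states by every descriptor
whose pairwise |r| with current members stays within 0.80, keep the top
`beam_width` per size, stop at the descriptor cap. Subset r² is evaluated
from centered Gram matrices (solve of a k×k system per subset), with
singular or ill-conditioned (cond > 10¹²) blocks skipped, so the search
scales to the pool sizes the prescreen produces. `exhaustive_search`
enumerates all subsets of the target size and is the exact oracle: on
pre-screened pools (where no admissible pair exceeds the correlation bound)
a sufficiently wide beam provably explores a superset of every greedy path,
and the suite checks equality of the top model on 200 random instances.

Validation: t = B/SE from s² = SSE/(n−p−1); F = (SSR/p)/s²;
Q² = 1 − PRESS/SST with PRESS through the exact hat-matrix identity
e₍ᵢ₎ = eᵢ/(1−hᵢᵢ) (algebraically identical to n refits, and tested against a
literal refit loop at 10⁻¹⁰); r²_test is the squared Pearson correlation
between predicted and observed on the hold-out (`method="predictive"` gives
the training-mean-anchored R² instead — stricter, shift-sensitive). The
hold-out is drawn one-per-stratum from n_test contiguous activity strata so
it spans the activity range. Outlier handling mirrors the single-removal
practice of the era: one pass flagging |internally studentized residual| >
2.5, then one refit.

## Synthetic data

`gen_descriptor_matrix` draws equicorrelated Gaussian blocks (block size 5,
within-block ρ = 0.3 by default) and appends planted pathological columns —
constant, missing-value, and an exact duplicate of an active column — with
their expected prescreen tags recorded. `gen_activity` adds the linear signal
plus Gaussian noise. Defaults are 27 compounds, 60 columns, 4 active columns
with coefficients ±2 (equal magnitude keeps each active equally identifiable
at a fixed population R²) and noise σ = 4/3, i.e. population R² = 0.9, which
is the regime in which the recovery experiments in the acceptance suite run:
at n = 22 training compounds the planted subset wins the search in ≈90% of
replicates, with the failures being genuine training-r² overfits, not search
misses. For recovery runs the pool is generated with ρ = 0 — a pool that has
passed the collinearity screen is by construction decorrelated, and with
correlated blocks (ρ = 0.3) block-mates substitute for actives often enough
to push recovery to ≈88%.

`gen_luminescence` emulates the assay: control Gc(t) = Gc₀ e^(−k_c t) and
sample Gs(t) = Gc(t)(1 − I_max(1 − e^(−t/τ))), both with multiplicative
lognormal noise of coefficient of variation `cv`, three replicates, on the
{0,20,40,60,80,100} min grid. Defaults: Gc₀ = 2×10⁵ RLU (typical luminometer
scale; the endpoint is scale-free), k_c = 0.002 min⁻¹ (slow control drift),
τ = 6 min (≈96% of the plateau reached by the first 20-min sample,
reproducing inhibition that saturates within the first interval), cv = 0.05.
A packaged scenario table carries per-compound plateau fractions at the four
assay concentrations (1, 10, 50, 100 µM) so the generator can imitate the
study set's qualitative pattern; these are scenario parameters for
simulation, not ground truth for any model coefficient. What the generator
does **not** emulate: hormesis (negative inhibition), solvent-control
effects, plate-position or time-drift artifacts, and any mechanistic link
between a compound's descriptors and its plateau — so pipeline tests prove
the plumbing and the statistics, not that real terpenoid toxicity is
linearly descriptor-determined.

## Numerical choices and degenerate inputs

- Embedding is deterministic per (molecule, n_conf, seed); seed 42 is the
  package default. Embedding failure retries once with random-coordinate
  initialization before raising.
- Zero-variance y raises in Q² (SST = 0) and prescreen; saturated designs
  (n ≤ p + 1) and rank-deficient subsets raise rather than returning r² = 1.
- Leverage hᵢᵢ = 1 (a leave-one-out refit would be rank-deficient) raises.
- Model ranking ties break by F, then by fewer descriptors, then by
  descriptor names, so results are reproducible across runs and platforms.
- Shadow rasterization and surface sampling resolutions are arguments, not
  constants, and their convergence is what the geometry tests assert.

## Pipeline problem sizes

The packaged end-to-end run uses the 27-compound fixture, 20 conformers per
compound, 960 surface points per atom, beam width 50 and the 22/5 split —
a few seconds per concentration on a laptop core. The acceptance suite's
simulation studies (200 search-oracle instances, 100 recovery replicates, 50
cross-validation oracles) complete in about a minute.

## Known limitations

- Conformer-sensitive geometric descriptors inherit the force-field caveats
  above; values for flexible chains carry real uncertainty (±0.1 in Ω).
- The Zefirov scheme is topological (element identity only): it cannot
  distinguish carbons in different environments beyond the molecule-wide
  equalization, which is the historical scheme's known coarseness, and the
  package applies it as the era's software did.
- The fixture SMILES were curated by hand; two rare sesquiterpene skeletons
  ((-)-α-cedrene, (-)-α-neoclovene) were reconstructed from nomenclature and
  are formula- and ring-count-validated best efforts.
- The HM optimizes training r²; with dozens of candidate columns and ~22
  observations, moderate overfitting of the selected subset is intrinsic to
  the method (the recovery experiments quantify exactly this), which is why
  Q² and the external hold-out are first-class outputs rather than optional
  extras.
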