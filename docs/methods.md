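# Methods

This note documents the models and numerical choices behind `icpca`, the
defaults and why they were chosen, and what the synthetic generators do and
do not emulate.

## Internal coordinates from the molecular graph

All feature enumeration is purely topological: given atoms and covalent
bonds, bonds are graph edges, angles are unordered neighbor pairs around a
central atom (Σ C(deg, 2) over atoms), and dihedrals are all *proper*
torsions — 4-paths a-b-c-d around a central bond b-c, each counted once
after canonicalization (first endpoint index < last). Improper torsions are
deliberately excluded; on the built-in all-atom cholesterol connectivity
(C27H46O, 74 atoms, tetracyclic) the proper-torsion definition yields the
reference totals 77 bonds / 157 angles / 259 dihedrals exactly, which is
the strongest available validation of that choice.

Connectivity is never perceived from distances: it comes from the built-in
fixture or a user bond-list file (two 1-based indices per line). Distance
thresholds would silently change the feature counts, which are the
backbone of the whole analysis.

Measurement conventions: bond lengths in Å; angles as the interior angle at
the central atom in [0°, 180°]; dihedrals signed by the right-hand rule
about the central bond with cis = 0°, range (−180°, 180°]. A torsion whose
defining planes collapse (three collinear atoms) is masked per cell rather
than raised — a single pathological frame must not abort a 250-frame
analysis. Masked cells are imputed with the column circular mean during
preprocessing and counted in the ranking diagnostics.

## The ranking statistic

The covariance matrix of the centered frames × features matrix is
eigendecomposed (sample covariance, n−1 denominator; `numpy.linalg.eigh`,
eigenvalues clipped at 0 against roundoff, descending order, sign fixed so
each loading column's dominant entry is positive). The PC subset *J* is the
smallest leading prefix whose cumulative explained-variance fraction
reaches the threshold (default 0.90). Each feature is scored
S_i = Σ_{j∈J} λ_j |c_ij| and the top ceil(0.10 · n_features) features by
S_i form the top set; ties break by ascending feature index so results are
platform-independent.

Design choices made where the design was genuinely open:

- **Covariance, not correlation.** The statistic ranks features by
  fluctuation magnitude and weights PCs by their eigenvalue; both only make
  sense on covariances. Each matrix holds a single feature kind, so units
  are homogeneous. A correlation option (`scale=True`) exists but is not
  the default.
- **Dihedral periodicity.** Each dihedral column is re-wrapped into
  (μ−180°, μ+180°] about its circular mean μ before centering, removing the
  artificial variance a ±180° branch cut would otherwise inject (e.g. the
  column {179°, −179°} becomes {179°, 181°}, variance 2 deg² rather than
  ~64000 deg²). Columns whose circular variance exceeds 0.9 — close to the
  uniform limit, where any linearization is questionable — are listed as
  unreliable in the diagnostics rather than dropped.
- **Top-set rounding.** ceil guarantees a non-empty top set for any feature
  count and fraction.
- **90% threshold semantics.** The threshold applies to cumulative
  explained variance, the standard reading of "recovering 90% of the data".
- **Aggregated scoring.** S_i aggregates over the selected subset *J*
  before the top-10% cut is applied; a per-PC variant (top coefficients
  within each PC separately) would be a different statistic and is not
  implemented.

Cross-ensemble comparison intersects top sets feature-by-feature and
reports multiplicities; the test suite checks the random-overlap baseline
against the hypergeometric null (expected overlap t²/n for two independent
rankings) so that observed multiplicities can be judged against chance.

## Superposition and representative structures

Rigid-body fits use the weighted Kabsch solution via
`scipy.spatial.transform.Rotation.align_vectors` after removing the
weighted centroids; reflections are excluded by construction, which is
mandatory for chiral molecules. Weights default to atomic masses and all
atoms, hydrogens included, participate. The ensemble mean is single-pass by
default — fit every frame to a chosen reference frame, average — matching
the common protocol; because an arbitrary reference can bias the mean, an
iterative mode re-fits to the running mean until it moves < 1e-6 Å. The
representative frame minimizes the mass-weighted RMSD to the mean after
re-superposition, ties going to the lowest frame index.

## Two-dielectric surface potentials

The membrane-internal electrostatic map is a deliberately transparent
stand-in for a continuum solver: atoms are tagged `polar_head` (the
hydroxyl end that faces the lipid head groups) or `core` (the part buried
in the hydrophobic interior), and the potential at a surface point p is the
screened Coulomb sum φ(p) = k_C/ε(p) · Σ_i q_i/|p−r_i| with the dielectric
of the point's parent atom's region. There is no boundary condition at the
sharp region interface, so *magnitudes* are approximate; the sign and
location of positive/negative patches, and the relative screening of the
two domains, are the quantities the model preserves.

Defaults, all configurable: ε_polar = 32.6 (methanol-like) and
ε_core = 2.02 (cyclohexane-like), the handbook values for the two solvents
conventionally used to mimic the membrane domains; Bondi-style vdW radii
with a 1.1 radius scale ("slightly increased"); T = 300 K for the kT/e
conversion (k_C = 14.3996 eV·Å/e², k_B = 8.6173·10⁻⁵ eV/K, so a +1 e
charge seen through ε = 2 at 10 Å gives 27.85 kT/e); display clamp ±5 kT/e.
The default polar set for the sterol fixture follows the rule "hydroxyl
group plus ring positions 2, 3, 4, with their bonded hydrogens", which on
the all-atom fixture is 10 atoms (O, HO, C2+2H, C3+1H, C4+2H).

The dot surface is a per-atom golden-spiral (Fibonacci) lattice at
`density` points/Å² (default 5); points strictly inside any other atom's
scaled sphere (tolerance 1e-9 Å) are discarded, and each surviving point
inherits its parent atom's region. A surface point numerically coincident
with an atom center is masked (NaN), not raised. One consequence of sharp
two-domain screening worth knowing: with a charge pattern localized on the
hydroxyl, the most extreme surface potentials appear on *core-region*
points adjacent to the head group (screened by ε ≈ 2) rather than on the
head-group points themselves (screened by ε ≈ 33) — the monotonic-screening
test pins this down.

## Energy summaries

Kinetic/potential fractions are computed per frame with |K| + |P| as the
denominator and then averaged; the absolute-value denominator keeps frames
with near-cancelling totals finite, and frames where it is not positive
are flagged and excluded (all-flagged is an error). Bonded shares are
|bond| : |angle| : |dihedral| of their per-frame sum, with Urey–Bradley
folded into angle when present (declining to guess when an angle column is
absent). The "three types of motion" denominator is read as the bonded sum
— bond, angle and dihedral are bonded terms. A force field that constrains
all bonds simply omits the bond column; the share is then reported as zero
with an explicit `absent` flag.

## Synthetic generators: what they emulate and what they do not

No MD trajectories ship with the package; the generators stand in for them.

- `generate_matrix` draws frames i.i.d. Gaussian per feature about a fixed
  baseline, with a designated hot subset at σ_hot and the rest at σ_cold.
  Defaults are the study-scale conditions the ranking targets: 250 frames,
  77 features, σ_hot/σ_cold = 10 (a 100× variance ratio); the dihedral
  variant wraps into (−180°, 180°] and can center hot features at ±180° to
  exercise the branch-cut handling.
- `generate_chain_ensemble` builds an unbranched chain from fixed internal
  coordinates (bonds 1.53 Å, angles 111°, torsions 180° base) with one
  torsion oscillating sinusoidally plus Gaussian jitter, and rebuilds
  Cartesians by sequential placement. The placement uses the same torsion
  sign convention as the measurement code, and the round-trip
  (generator → Cartesians → measured torsions) reproduces the inputs to
  ≤ 1e-6°. Branched reconstruction is out of scope; molecule-scale
  end-to-end tests use the matrix generator instead.
- Charge patterns are toys (all-zero, a ±q pair, a hydroxyl-localized
  triplet); energy tables are Gaussian series about stated means.

What passing tests therefore demonstrate: the machinery — enumeration,
measurement, circular preprocessing, the ranking statistic, superposition,
the potential model — is correct on ensembles with *known* variance
structure. What they do not demonstrate: that any particular force field's
real conformational distribution is reproduced. Real MD frames are
time-correlated, anharmonic and cross-correlated between features; the
generators are i.i.d. and (optionally) share only a single common factor.
The ranking itself is distribution-free in the sense that it only consumes
the empirical covariance, which is why the i.i.d. harness is a fair test
of it.

## Problem sizes and determinism

The shipped tests and the reproduction script run at the analysis's native
scale — 250-frame ensembles, up to a few hundred features, 100 recovery
replicates — which completes in seconds on a single CPU. Every stochastic
path takes an explicit integer seed through `numpy.random.default_rng`; no
hidden global state, so identical inputs and seeds give byte-identical
outputs (the pipeline test asserts this on whole output directories).

## Known limitations

- Dihedral columns near the circular-uniform limit have no useful
  linearization; they are flagged, not fixed.
- The single-pass mean structure depends (weakly) on the reference frame;
  use `iterative=True` when that matters.
- The surface-potential model has no reaction field and no interface
  boundary conditions; compare patch signs and locations, never absolute
  magnitudes, against continuum solvers.
- The graph is trusted as given: united-atom topologies will of course
  yield different feature counts than all-atom ones.
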