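# Methods

`conformscape` re-implements, as a reusable and testable pipeline, the
computational analyses used to characterize the conformational landscape of
the angiotensin II type 2 receptor (AT2R), a class A GPCR whose inactive
state is unusual in that helix 8 (H8) packs into the transmembrane bundle
instead of lying along the membrane. The pipeline has five scientific
stages — collective-variable featurization, free-energy landscapes, Markov
state models (MSM) with transition-path analysis, statistical coupling
analysis (SCA) of a sequence alignment, and nudged-elastic-band (NEB)
minimum-energy paths — plus synthetic-data generators that provide ground
truth for every stage, since the microsecond MD trajectory ensembles such
analyses usually consume are not shippable.

## Collective variables and featurization

Conformation is summarized by two internal coordinates of the intracellular
face:

* **distance_sum** = |r(2.40) − r(5.63)| + |r(2.40) − r(6.25)| over Cα
  positions — the opening of intracellular TM5/TM6 measured against the
  stable TM2 helix;
* **dihedral** — the torsion over the Cα atoms of Ballesteros–Weinstein (BW)
  positions 8.54, 7.56, 7.54, 7.47 — the orientation of H8 relative to the
  TM7 stalk.

BW codes are resolved purely arithmetically, `residue(x.n) = anchor(x) +
(n − 50)`, against per-helix anchors and validated helix ranges; resolutions
outside a helix's range are rejected rather than extrapolated. The default
map encodes the AT2R anchors (e.g. 2.60 = W100 ⇒ 2.50 = 90; 3.50 = R142;
6.50 = P271; 7.50 = N315; 8.49 = R324).

The torsion uses the standard atan2 construction and is reported in
[0, 360) rather than (−180, 180]: the H8 dihedral of interest takes values
above 200°, which a signed convention would fold. Both CVs are internal
coordinates and therefore exactly invariant under rigid motion; this is
asserted to 1e−9 in the tests.

RMSF, PCA and the dynamic cross-correlation matrix (DCCM) all operate on
Cα displacements after superposition onto the mean structure (optimal
proper rotation, iterated twice — mean → fit → mean — because the mean is
itself orientation-dependent; superposition can be disabled). DCCM entries
are normalized covariances of displacement vectors; zero-variance residues
produce NaN rather than a fabricated 0, and the 0.3 display mask affects
only exports, never stored values. Ligand contacts use a 4 Å distance
threshold and a 60% frame-fraction rule, over all available atoms (Cα-only
in reduced fixtures).

## Free-energy landscape

The landscape is a Boltzmann inversion of the binned CV density,
F(bin) = −kT ln(n_bin/n_max), so the modal bin sits at exactly 0 and empty
bins carry +inf (never 0). Defaults: 100×100 bins over the observed range
padded 2%, kcal/mol at 300 K (k_B = 0.0019872041 kcal mol⁻¹ K⁻¹), with a
kT-units switch. Bins are half-open [lo, hi); a point on an interior edge
belongs to the higher bin. No smoothing or reweighting is applied — the
intended inputs are unbiased trajectories.

## Markov state model

The two CVs are z-scored (they live on incommensurate scales, Å vs degrees)
and clustered by k-means into k = 500 microstates (seeded; k is capped at
one tenth of the frame count for small inputs). Transitions are counted at
lag τ inside each trajectory only. The default estimator symmetrizes counts,
(C + Cᵀ)/2, before row-normalizing — a simple deterministic reversible
estimator; the naive estimator is retained for oracle tests. Estimation is
restricted to the largest strongly connected component of the count graph.

Markovianity is checked by the implied timescale test
t_i = −τ / ln λ_i: the slowest timescale must be lag-independent. The lag
chooser takes the smallest lag whose slowest timescale stays within 10% of
its value at all larger scanned lags, flagging the model non-Markovian when
none qualifies.

Macrostates come from PCCA+ on the first m right eigenvectors of the
reversible transition matrix (computed through the π-weighted symmetric
form), using the inner-simplex vertex search and crisp assignment by
membership argmax. Macrostate proportions are reported both
stationary-weighted (Σπ over member microstates) and by raw frame counts.

Transition-path analysis solves the standard committor linear system
(q = 0 on the source, 1 on the sink) and reports the mean first passage
time from the first-passage linear system with the sink absorbing, averaged
over source states weighted by the stationary law restricted to the source.
Representative conformations maximize the summed similarity
S_ij = exp(−d_ij/d_scale), where d_scale is the standard deviation of the
pairwise distances (RMSD between frames when coordinates exist, Euclidean
distance in standardized CV space otherwise); ties break to the lowest
index.

## Statistical coupling analysis

Conservation of position i is the relative entropy of the dominant
residue's frequency f against a background q:

    D = f ln(f/q) + (1 − f) ln((1 − f)/(1 − q)),

with the 0·ln 0 = 0 convention at the boundary. The background defaults to
the uniform q = 0.05 for every residue (a supplied table can override it).
One all-gap row is appended to the alignment before any frequency is
computed — the zero-frequency guard — so all frequencies are strictly
inside (0, 1). Gaps never dominate a column; dominance ties break
alphabetically.

Co-evolution couples the conservation gradients with the deviation of the
joint frequency from independence:

    C_ij = ln[f_i(1−q)/(q(1−f_i))] · ln[f_j(1−q)/(q(1−f_j))] · |f_ij − f_i f_j|.

The diagonal (pure self-conservation) is zeroed before eigendecomposition
(switchable) so sectors are driven by coupling. Sectors are read off the
signed loadings of eigenvectors 2–4 (the first mode carries the global
phylogenetic signal and is dropped), each eigenvector sign-fixed so its
largest-magnitude component is positive:

    red  = {i : v2_i > v4_i and v2_i > ε},
    blue = {i : (v2_i < v4_i and v2_i < −ε) or (v4_i > v2_i and v4_i > ε)},

with ε = 0.05. Domain summaries report mean ± sample standard deviation of
D over named residue ranges; composite rows pool their member ranges.

## Nudged elastic band

A band of replicas between two fixed endpoints is relaxed so that the true
force acts only perpendicular to the local tangent and the spring force
only parallel to it. The tangent is energy-weighted with four cases:
the uphill difference on monotonic segments, and a ΔV^max/ΔV^min-weighted
mix of forward and backward differences at local extrema, the weight
ΔV^max attaching to the difference toward the higher-energy neighbor.
Tangents are normalized to unit length (the projections require a
direction). The spring magnitude is k(|R_{i+1}−R_i| − |R_i−R_{i−1}|), the
canonical choice for the parallel projection.

Relaxation runs an annealing schedule of noisy overdamped steps (noise
amplitude √(2Tδ), interior replicas only) whose phase structure mirrors
the usual recipe — heat at soft springs (k = 10), equilibrate at stiff
springs (k = 50), anneal hot to cold, hold at zero temperature — expressed
in optimizer steps and surface energy units since the artifact relaxes
analytic surfaces, not solvated proteins. A zero-temperature FIRE descent
then runs until max interior |F_perp| < 1e−3 (default); non-convergence
returns a flagged band with its residual instead of raising. Endpoints are
bit-identical before and after.

Replica-band utilities: optimal proper-rotation alignment of each replica
onto its predecessor (determinant-corrected), all-pairs best-fit RMSD, and
diverse-replica selection by greedy max–min with the endpoints forced and
ties broken toward the lower index (an adjacent-gap reading of "most
different replicas" is a plausible alternative; greedy max–min was chosen
because it guarantees spread).

## Synthetic data: what it emulates and what it does not

**CV surface and Brownian trajectories.** The default surface has three
Gaussian wells centered at the receptor's free-energy basins — active-like
(54 Å, 105°), intermediate (53.5 Å, 188°), inactive-like (55.5 Å, 216°) —
with depths near 6 kT, plus a weak harmonic confinement (stiffness 1.3 kT)
standing in for the finite conformational range a real receptor explores.
Without confinement the flat plateau between basins is an entropic sink
holding most of the Boltzmann weight, which no MD free-energy surface of a
folded receptor resembles. The overdamped integrator
x ← x − μ∇V dt + √(2 kT μ dt) ξ uses a diagonal per-axis mobility
(1, 36): relaxation is then isotropic in the width-scaled coordinates that
the MSM's z-scored clustering works in, reflecting that the dihedral
coordinate spans a numerically ~100× larger range than the distance
coordinate. Any positive diagonal mobility leaves the Boltzmann law
unchanged. Frames are saved every 40 integration sub-steps — the analogue
of MD saving frames every many integrator steps — so intra-basin relaxation
(a few sub-steps) is sub-frame and the saved-frame process is Markovian
from lag 1. Every frame carries its nearest-well label (width-scaled
distance) as ground truth, and `boltzmann_well_weights` integrates
exp(−V/kT) on a dense grid under the same partition as the equilibrium
oracle. The canonical study is 10 trajectories × 50,000 saved frames.

What this does not emulate: non-Markovian memory from projecting many
orthogonal degrees of freedom onto two CVs, force-field and sampling
artifacts, and state-dependent diffusion. Passing the recovery tests shows
the estimators are correct on data satisfying their assumptions, not that
two CVs suffice for any particular receptor.

**Synthetic MSA.** Background positions draw i.i.d. from a uniform
background; conserved positions emit a designated residue at a target
frequency; each planted sector group shares a per-sequence hidden binary
state, each member copying its state residue with probability =
coupling. A `clade_coupling` term (off by default) gives every background
position a weak shared clade preference — the phylogenetic structure that
makes the leading SCA eigenvector a global mode, as in real alignments.
The sector-recovery study (`default_sector_msa_spec`) uses 500 sequences ×
100 positions, clade coupling 0.65, and one 10-position sector at coupling
0.9: without the clade term the planted sector itself claims the first
eigenvector, which the sector rule drops by construction. The generator
does not model gaps within sequences, phylogenetic tree topology beyond a
two-clade split, or position-specific background frequencies.

**Toy helix bundle.** Ideal helices (3.6 residues/turn, 1.5 Å rise, 2.3 Å
helical radius) on a circle, one pseudo-ligand HETATM placed 3 Å inside a
mid-helix Cα, and a matching BW map anchored at each helix's middle
residue. It exercises parsing, BW resolution, featurization and contact
code paths, not protein geometry beyond the Cα backbone.

## Numerical choices

* Eigen-decompositions of symmetric matrices use `eigh`; the reversible
  transition matrix is symmetrized in the π-weighted inner product before
  decomposition so eigenvectors are real.
* Stationary laws of the symmetrized estimator use the exact closed form
  (row sums of the symmetrized counts); general chains use the leading left
  eigenvector.
* Implied timescales: λ ≥ 1 → ∞ marker; λ ≤ 0 or materially complex → NaN
  ("undefined for that mode"), never an exception.
* Degenerate inputs: all-identical CV samples give a single-occupied-bin
  landscape with a warning; all-gap MSA columns give zero SCA rows with a
  warning; an all-zero distance matrix returns frame 0.
* k-means runs one seeded initialization (`n_init=1`); determinism is part
  of the clustering contract.
* NEB step sizes are auto-scaled from the initial gradient magnitude and
  replica spacing; per-step displacements are capped at half the initial
  spacing to keep annealing stable on stiff surfaces.

## Worked-example structures

The collective variables of the two deposited crystal structures (the
agonist-bound active-like and antagonist-bound inactive-like receptor) are
checked against their published (distance_sum, dihedral) values within
±1 Å / ±5° — a tolerance that absorbs structure-preparation differences
(capping, back-mutation) the publication does not fully specify. The
trimmed Cα coordinate fixtures are produced by
`scripts/fetch_reference_structures.py`, which requires network access and
is therefore run separately from the main suite; without the fixtures the
corresponding acceptance test fails with instructions rather than being
skipped.

## Known limitations

* The reversible estimator is count-symmetrization, not maximum-likelihood
  reversible estimation; at desk scale the difference is far below the
  tolerances used here.
* PCCA+ memberships come from the inner-simplex algorithm without the
  subsequent constrained optimization refinement; crisp assignments are
  what downstream consumers use.
* MFPTs are reported between macrostate sets under the source-stationary
  weighting convention; inverse-rate definitions differ by bounded factors.
* The NEB implementation targets analytic surfaces (2–3 dimensions tested);
  no climbing-image variant is provided, so saddle localization is limited
  by replica density.
* Table-style domain conservation of the real 121-sequence receptor
  alignment depends on an alignment that is not redistributable; the domain
  machinery is exercised on synthetic alignments only.
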