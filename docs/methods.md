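# Methods

## The model system

A hexameric AAA+ ATPase (NSF) disassembles SNARE complexes by threading a
substrate polypeptide through the pore of its catalytic D1 ring. The six
protomers occupy ring positions A–F (from the bottom of the ring split to
the top) and cycle through conformational states coupled to their
nucleotide state: under hydrolyzing conditions position E is the
ATP+Mg²⁺-bound, substrate-engaged protomer poised for hydrolysis; down-ring
positions carry ADP (with variable Pi and Mg²⁺); position F is the site of
nucleotide exchange and substrate re-engagement. The package's job is to
recover this state structure quantitatively from an ensemble of atomic
coordinate models.

## Landscape pipeline

1. **Protomer extraction** (`model_io`). Models are parsed with gemmi (PDB
   or mmCIF). Residue numbering is taken verbatim from the file
   (author numbering; 1-based inclusive intervals); hydrogens are dropped;
   alternate locations resolve to the highest-occupancy conformer with
   alphabetical altloc id as the tie-break; insertion codes are rejected
   rather than silently renumbered. The D1 subdomains default to large
   224–373 and small 400–486, with the Walker A helix α3 at 350–358, helix
   α8 at 442–452 and the latch loop at 457–467; all intervals and the
   catalytic marker residues (P262, T267, Y294, D328, E329, N374, R385,
   R388, I209, S207) are configuration. Chain→position mapping comes from a
   per-ensemble YAML manifest because depositions label ring chains
   inconsistently.

2. **Nucleotide states**. Assignment is geometric: any recognized ligand
   residue (ATP, ADP, PO4/PI, MG) with an atom within 6 Å (configurable) of
   the protomer's P-loop Cα atoms (residues 261–268) contributes to the
   state label; ATP and ADP together raise an ambiguity error, Pi and Mg
   are modifiers, and no ligand means apo. Manifest overrides exist for
   models whose annotations disagree with geometry.

3. **Subdomain superposition** (`landscape`). Each protomer's large-range
   Cα set is fitted onto the reference protomer's large subdomain and the
   small range onto the reference small subdomain (rotation + translation
   only; Kabsch via `scipy.spatial.transform.Rotation.align_vectors`,
   cross-checked in the tests against an independent quaternion
   eigenvalue oracle). Splitting removes the rigid-body hinge motion of
   the two subdomains, the dominant but — for state discovery — trivial
   variance source. Only residues present in every protomer are used;
   missing residues are never imputed. The reference (first manifest row
   by default) is first placed in a deterministic canonical frame:
   principal axes of its large subdomain, each axis sign fixed by the
   third moment of the point projections, third axis rebuilt by cross
   product for right-handedness. This makes the coordinate matrix — and
   everything downstream — invariant to a global rigid motion of all
   inputs (verified to 1e-6 Å), so the reference choice only anchors an
   arbitrary frame.

4. **PCA and clustering.** `C_flat` is column-standardized
   (zero-variance columns are centered and left at unit scale) and
   decomposed with scikit-learn's PCA. The retained dimensionality k is
   the smallest component count whose cumulative explained variance
   reaches the target (default 0.99), with `k_override` available because
   the appropriate fixed dimensionality is a judgment call that should be
   stated per analysis, not guessed by the software. Component signs
   follow the convention that each component's largest-magnitude loading
   is positive, making latent coordinates reproducible across library
   versions. HDBSCAN (minimum cluster size 3, the smallest value at which
   a "state" is more than a coincidence of two models) clusters the
   latent coordinates; noise is −1 and labels are renumbered by
   descending cluster size for determinism.

## Geometry statistics

Helix axes are the first right-singular vector of mean-centered Cα
coordinates, oriented N→C. The α3–α8 angle — the hinge proxy — uses the
half-angle form `2·atan2(‖û−v̂‖, ‖û+v̂‖)`, which equals `arccos(û·v̂)`
exactly for unit vectors but is stable near 0° and 180°. (A printed
formula for this angle circulating with the original analysis reduces to a
constant for unit vectors and is evidently a typesetting casualty; the
half-angle form implements what the accompanying prose describes.) Ring
planarity is a total-least-squares plane through subdomain Cα centroids
(normal = smallest singular vector), with the rms orthogonal residual as
the flatness measure. Distances are Euclidean norms between named atoms;
the Sensor 1 (N374) distance atom defaults to the side-chain Cγ and is
configurable per pair spec, since conventions differ. Pβ is the phosphorus
named PB of the bound ATP/ADP; apo protomers contribute no Pβ rows.
Position E is compared against each other position with Welch's
unequal-variance t-test (two-sided, Welch–Satterthwaite df), flagged at
0.05 and 0.005.

## Assay analytics

Chromatograms are smoothed with a Savitzky–Golay filter, default window
1000 points and polynomial order 2; the window presumes finely sampled
traces (the synthetic default is 0.002 mL/point over 0–25 mL, so 1000
points ≈ 2 mL) and is clamped to the series length. Peaks are local maxima
above 10 mAU, separated by ≥ 1 mL, with prominence above 0.5 mAU — the
prominence threshold is stated in absorbance units because prominence is an
absorbance quantity, even though source material sometimes prints it with a
volume unit. Windowed areas (IAUC) use the trapezoidal rule with linear
interpolation at the window edges; integration windows are explicit inputs,
not inferred from peak bases, and both raw and filtered integrals are
reported since either convention is defensible. No baseline is subtracted
by default; an optional linear baseline over a stated flat region is
provided. Dequenching traces are summarized by the OLS slope over the
stated linear window (default 95–350 s); relative activity is a slope
ratio with first-order error propagation.

## Particle splitting

Per-particle latent coordinates of one 3D-variability mode are fitted by a
maximum-likelihood normal (sample mean, population sd) and sliced at
μ ± kσ (default k = 1.5); boundary ties go to the tails, and the two tails
plus the middle partition the particle set exactly. Signed coordinates are
the default — slicing both tails presumes sign carries meaning — with an
absolute-value mode available. Input/output is plain CSV/TSV; proprietary
single-particle metadata containers are deliberately out of scope (export
the table from the processing package instead).

## Synthetic data: what it emulates, and what it does not

The scaffold is a poly-Cα chain (residues 200–486) of short ideal helical
segments (1.5 Å rise, 100°/residue, 2.3 Å radius) whose directions cycle so
the fold stays compact (~40 Å); α3 is pinned along +z and α8 at 30° from +z
in the xz-plane, so a hinge rotation about +y adds directly to the α3–α8
angle. Marker residues carry minimal side-chain atoms and a nucleotide site
(ATP/ADP Pα/Pβ/Pγ, optional PO4 and Mg) sits near the Walker A region.

An ensemble plants `n_clusters` conformational states, each defined by
three features applied to scaffold copies:

- a rigid hinge rotation of the small subdomain about an axis through the
  inter-subdomain linker midpoint (default angles 0–24° in 6° steps,
  comfortably above the ~5° separations a landscape analysis should
  resolve);
- a translation of helix α3 along its own axis through the discrete
  up/intermediate/down positions (0 / 1.5 / 3.0 Å), cycling over clusters;
- a state-specific distributed loop-remodeling field: a smooth per-residue
  displacement (three incommensurate sinusoids in residue number, phase
  advanced by the golden angle per state, amplitude 1.5 Å — the scale of
  real loop remodeling between states) applied to all non-helix subdomain
  residues. Real conformational states differ in *which* loops move, so
  states get distinct patterns rather than scaled versions of one mode;
  this internal signature is what survives rigid-body subdomain
  superposition and makes the states separable by PCA. Helix windows are
  exempt so the measured hinge angle reports the planted rotation exactly.

Isotropic Gaussian noise (default σ = 0.3 Å) is added to every atom and
residues may be deleted at a configurable rate (default 0). The
largest-hinge state plays the pre-hydrolysis position E: it keeps ATP+Mg
with the ligand seated 2 Å deeper in the site than the ADP-bound other
states, giving the distance statistics a known effect to detect. Chains of
one synthetic model are arranged around a ring — a per-chain rigid motion
that keeps ligands spatially separated, exactly as invisible to the
pipeline as a real ring's geometry.

What passing on this generator demonstrates: the pipeline separates states
whose internal deformation exceeds the coordinate noise, recovers planted
hinge steps from helix geometry, detects a 2 Å active-site contraction with
n = 6 per group, and is deterministic and rigid-motion invariant. What it
does not demonstrate: performance under realistic correlated coordinate
error (modeling error concentrates in poorly resolved regions and
covaries along the chain, while the generator's noise is iid), under
heterogeneous model rosters with systematically missing regions, or for
effect sizes smaller than the planted ones. In particular, with iid noise
every standardized coordinate carries equal variance, so the latent
dimensionality at a 99% variance target lands near the sample count
(~26 of 29 possible) rather than at the much smaller values typical of
real ensembles, whose variance is dominated by a few correlated modes.

Chromatograms are sums of Gaussians (default apexes 9.6/11.6/13.6/15.8 mL,
heights 20–50 mAU, σ 0.15–0.25 mL) with 0.5 mAU white noise on a flat
baseline (drift is available but defaults to zero; detector baselines over
a 25 mL isocratic run are near-flat, and the peak-detection property suite
handles offsets explicitly). Latent tables are normal draws; kinetic traces
are straight lines over 0–600 s at 2.5 s sampling with optional noise. All
generators are bit-deterministic given their seed.

## Numerical choices and degenerate inputs

- Superposition and plane/axis fits reject collinear point sets
  (second singular value ≤ 1e-8 relative) instead of returning an
  arbitrary solution; fewer than three points is an error.
- HDBSCAN on fewer points than the minimum cluster size returns all-noise
  with a warning; a degenerate all-identical input returns a single
  cluster directly, since density clustering is undefined there.
- Peak-distance thresholds convert mL to samples by the median volume
  step; >5% step spread triggers a warning that the conversion is
  approximate.
- Integration windows outside the recorded volume range are errors, not
  extrapolations.
- Tail splitting sends boundary ties to the tails, so the reported tail
  fraction is conservative from above.
- The acceptance script reduces its seed modulo 2³¹−1 before deriving
  per-stage seeds.

## Problem sizes

The test suite and the acceptance script run on 30-protomer ensembles
(5 states × 6 protomers, ~240 shared residues), 12,501-point
chromatograms, 10⁶-draw latent tables and 241-point kinetic traces —
sizes chosen to match the study conditions the statistics are designed
for while keeping a full run in seconds on one CPU.

## Known limitations

- Reproduction of published ensemble statistics requires the deposited
  coordinate models and chromatography traces, which cannot be
  redistributed with the package; the shipped manifest for the deposited
  accessions is a template whose chain mappings must be verified against
  the downloaded files. The corresponding acceptance checks fail with a
  diagnostic until those inputs are provided.
- The exact model roster behind the published 132-protomer ensemble is
  ambiguous in the source material (132/22, 130/23 and 25-model counts
  appear in different places); the manifest makes the roster explicit
  rather than guessing.
- Whether published IAUCs were integrated on raw or filtered absorbance is
  unstated; both are computed and reported.
- Whether 3D-variability "eigenvector magnitudes" were signed or absolute
  before fitting is unstated; signed is the default with an absolute mode.
- No nonlinear embeddings, hydrogen-bond/contact analysis, or map-space
  processing; upstream single-particle processing and model building are
  out of scope.
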