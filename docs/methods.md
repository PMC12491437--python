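# Methods

This note records the models behind each stage, the conventions and
defaults that are genuinely choices, and what the synthetic-data tests do
and do not demonstrate about real data.

## Localization census

**Input model.**  A localization map is an ordered set of (x, y)
coordinates in nm inside a half-open rectangular ROI
`[0, W) × [0, H)` (default 7000 × 7000 nm, the ROI size typical of
TIRF-PALM oligomer studies).  Points exactly on the right/top edge are
outside; this makes density exactly count/area and keeps file round-trips
unambiguous.

**Canonical ordering.**  Both greedy passes iterate points sorted by
(frame, x, y, input index).  The sort makes every result independent of
input row order; the frame key puts earlier detections first where frames
are available.

**Duplicate discounting.**  Photoactivatable dyes blink, so one receptor
can yield several localizations a few nm apart.  The discount rule is a
single greedy pass: each surviving point removes all not-yet-visited
points strictly within the dedup radius (default 20 nm).  The rule is
deliberately *not* transitive — a chain at 0, 15, 30 nm keeps the
endpoints — and survivors are actual detections, not merged centroids.
"Within r" is strict (`< r`) here, so a pair at exactly 20 nm survives.

**Complex assignment.**  The default `greedy_seed` mode implements seeded
fixed-radius aggregation: the first unassigned point in canonical order
collects every unassigned point within the search radius (default 50 nm,
inclusive `<= r`), the members are discounted from further searches, and
the scan continues.  This matches the discount-after-assignment behaviour
of neighborhood-census software and guarantees every seed–member distance
is within the radius.  `single_linkage` (connected components of the
within-radius graph) is shipped as a labelled alternative because
transitive growth is the other defensible reading of a fixed-radius rule;
it can only merge greedy complexes, never split them, so it never yields
more complexes.  Both modes are verified against independently coded
brute-force oracles in the test suite.

**Census.**  Tallies are on the receptor basis: a bin's percentage is
(receptors in complexes of that size)/(total receptors) × 100, so
percentages sum to 100 and `pct_associated = 100 − pct_monomer`.  Sizes at
or above `max_reported_size` (default 10) are pooled.  Density is total
retained receptors over the full ROI area with no edge correction;
strictly above 100 receptors/µm² classes the ROI as "high" expression.

**When to dedup.**  Duplicate discounting removes blink artifacts, but at
20 nm it also merges genuinely adjacent receptors: two receptors of a
tight dimer (cluster radius ≤ 10 nm) are always within 20 nm of each
other.  The pipeline therefore exposes dedup as an explicit step
(`run_census(..., dedup=...)`): apply it to raw single-molecule data,
skip it for inputs already discounted upstream or simulated without
blinking.  Consequently the composition-recovery checks run without
dedup, and the dedup stage is validated separately on monomer-only maps
with Poisson blinking, where the recovered count isolates discounting
performance from true intra-complex merging.

## Synthetic localization maps

Complex centers are uniform over the ROI (optionally rejection-sampled to
a minimum separation; infeasible packings fail after a bounded number of
retries).  Receptors are uniform in a disc of `cluster_radius_nm` (default
10 nm) around their center, which keeps intra-complex distances within the
50 nm search radius.  Each receptor emits one localization displaced by
isotropic Gaussian error (default SD 10 nm, consistent with sub-10 nm
PALM resolution; the true localization precision of the dye is not
published, so this default is a documented stand-in) plus
`Poisson(blink_rate)` duplicates displaced by `blink_sd_nm` (default
5 nm).  Emissions falling outside the ROI are redrawn.  All randomness
comes from a single `default_rng(seed)` per call.

What this emulates: composition, localization error, blinking multiplicity
and expression density.  What it does not: drift, frame-correlated blinking
kinetics, labelling efficiency below 1, antibody linkage error, or membrane
topography — so exact recovery in tests demonstrates correctness of the
census procedure, not expected performance on raw microscope output.

## Docking-pose post-processing

**Frame convention.**  The z-axis is the membrane normal with the membrane
center at z = 0; the fixed target protomer defines the frame and poses are
proper rotations + translations of the probe protomer, ranked by docking
score (higher better; ties broken by ascending pose id).

**Topology metrics.**  Tilt = `arccos((R·ẑ)·ẑ)` (the angle the probe's
rotated z-axis makes with the membrane normal); z-offset = z-component of
`R·c + t − c` where c is the probe's Cα geometric center.  Tilt is
invariant to spins about z and to any translation.  The filter keeps the
best 4000 poses by score, then those with tilt ≤ 0.4 rad and |z-offset| ≤
6.0 Å; the threshold applies to |z| since a protomer displaced either way
breaks membrane embedding.

**RMSD and clustering.**  Pose–pose distance is Cα RMSD between the two
placements *without* re-superposition: the target fixes the frame, so a
pure translation by d gives RMSD exactly d.  Clustering is greedy leader
clustering at 3 Å: the best-scored unclustered pose becomes a center and
absorbs everything within the cutoff.  Centers are therefore pairwise ≥
cutoff apart and ordered by score; the original workflow followed this
with visual inspection of centers, which the package replaces by ranking
centers by score and cluster size.

**Contacts and clashes.**  Interface contacts are residue pairs whose
minimum heavy-atom distance is ≤ 4.5 Å (a standard heavy-atom contact
cutoff; the source analyses name contacts without a number, so it is
configurable).  Clashes are heavy-atom pairs strictly below 2.5 Å, summed
over effector-copy pairs and copy-vs-dimer; an assembly is "clashing" when
the count exceeds 10 pairs.  Both thresholds are configurable; hydrogens
are ignored everywhere.

**Arrestin anchor filter.**  Receptor–arrestin poses are kept when the
Cα–Cα distance between the receptor's DRY arginine (residue 132) and the
arrestin finger-loop residue 71 is ≤ 12 Å.  The rule is stated in the
source workflow without a numeric cutoff; 12 Å was chosen to admit
finger-loop engagement geometries (the finger loop inserts into the
receptor's cytosolic cavity several Å below the DRY motif) and is
prominently configurable.

**Tilt/Rot indices.**  The arrestin principal axis is the dominant
principal component of its Cα cloud, sign-fixed toward the N-domain
centroid (first half of residues in sequence order).  Tilt index = angle
between that axis and the receptor main axis (+z).  Rot index = signed
angle about +z from the receptor reference vector (anchor-residue Cα
toward the receptor Cα centroid, projected in-plane) to the in-plane
projection of the arrestin axis.  These conventions make values
self-consistent within the package; they are one explicit
operationalization of the published indices, so absolute numbers need not
match other implementations.  A spherical Cα cloud (no dominant axis)
fails loudly; an axis parallel to ±z reports Tilt with Rot = NaN.

**Synthetic poses.**  Each simulated rotation is a spin about z composed
with a tilt about a random in-plane axis, so the sampled tilt round-trips
exactly through the topology computation; the translation's z-component is
chosen so the center displacement equals the sampled z-offset.  Scores
decrease monotonically with pose index by default.  The ground truth
stores the accept flag at the thresholds the filter will use, enabling
exact set comparison.  The bundled `synthetic_protomer` is an idealized
Cα helix (a geometric test body, not a model of any protein).

## BRET quantification

**Net BRET.**  Per condition, the 535/475 nm emission ratio is averaged
over repeat cycles and the donor-only mean ratio is subtracted.  Rows with
non-positive 475 nm emission are dropped with a warning.  Net acceptor
expression is the analogous fluorescence subtraction.

**Kinetics.**  Ligand-induced traces (post-agonist ratio minus basal mean,
optional vehicle-trace subtraction) are fitted to one-phase association
`y = plateau·(1 − e^(−kt))` with y0 pinned at 0 — the subtraction
construction forces it; a free-y0 variant exists for raw ratios.  Halftime
`ln 2/k` and initial rate `k·span` (span = plateau − y0, the maximum BRET
ratio) are computed exactly from the fitted parameters, never re-fitted.
Fits with fewer than 8 points or a window shorter than two halftimes warn.

**Saturation.**  `y = BRETmax·x/(BRET50 + x)` with non-negative bounds,
initialized at BRETmax₀ = max y and BRET50₀ = the x nearest half-max.
Flat data converges to BRETmax ≈ 0 and is flagged degenerate.

**Dose-response.**  Four-parameter logistic with the Hill slope fixed at 1
(the standard assumption when the slope model is unstated; a
variable-slope flag is provided), fitted on the log₁₀-concentration scale
for conditioning and reported as −log₁₀ EC50.

**Fit machinery.**  Bounded trust-region nonlinear least squares
(`scipy.optimize.curve_fit`), parameter tolerance 1e−8, max 1000 function
evaluations.  Non-convergence, k ≤ 0, or a constant response yields a
flagged result rather than an exception.  Parameters are fitted per
replicate and summarized afterwards (mean across replicates in the
pipeline report); fitting a pooled mean trace is possible but not the
default, matching the per-experiment structure of kinetic summary tables.

**Bias factor.**  Emax/EC50 per pathway and condition, expressed as fold
change versus a designated reference condition (which maps to exactly 1);
it requires converged fits for every row.

## Pipeline and reproducibility

A run config selects stages (palm, poses, bret) and their parameter
blocks.  The global seed expands through
`SeedSequence(seed).generate_state(3) % 2**31` into one child seed per
stage (and per BRET mode below that), so stages re-run in isolation
reproduce their outputs byte-identically.  All default thresholds are
logged at INFO on every run.  Validation reports every config violation,
not just the first; a stage failure aborts with the stage name, keeping
partial outputs next to a `FAILED` marker.

## Problem sizes in the shipped checks

The test suite and acceptance script use desk-scale problem sizes chosen
to make the statistical checks sharp while staying quick: 1000 random
point sets (≤ 12 points) for oracle equivalence, a 180-receptor ROI for
composition recovery, 300 monomers × 50 seeds for dedup robustness, 1000
simulated poses for the topology filter, and 100 noise seeds for each
curve-fit recovery study.  Medians over seeds are compared against truth
(10% for the kinetic halftime at σ = 0.002, 15% for saturation parameters
at σ = 0.01) — bands that reflect the estimator spread at these noise
levels, established by the simulation studies themselves.

## Known limitations

- The census has no edge correction; complexes straddling the ROI border
  are truncated, slightly biasing composition at high density.
- Greedy seeded assignment depends on the canonical order when complexes
  overlap within the search radius; the canonical sort makes this
  deterministic but it remains a modelling choice, which is why the
  single-linkage alternative ships alongside.
- RMSD clustering is O(n²) in the filtered pose count; fine for the few
  thousand poses a topology filter passes, not for raw docking decks.
- The BRET simulator adds i.i.d. Gaussian noise; real plate-reader noise
  is heteroscedastic and temporally correlated, so recovery tolerances
  here are optimistic bounds.
- Tilt/Rot index values depend on the documented axis conventions and are
  comparable within this package only.
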