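# Methods

`pcsassign` obtains sequence-specific assignments of Ile-δ1, Leu-δ1/δ2,
Met-ε and Val-γ1/γ2 methyl cross-peaks in ¹H-¹³C HMQC spectra of a protein
complex of known structure, using pseudocontact shifts (PCSs) induced by
lanthanide tags. This note describes the model, the algorithmic choices, the
synthetic-data generator used for validation, and the known limitations.

## The forward model

A paramagnetic lanthanide with anisotropic magnetic susceptibility Δχ shifts
every nearby nucleus by the pseudocontact shift. For a point metal and a
nucleus at polar coordinates (r, θ, φ) in the tensor eigenframe,

    PCS(ppm) = 1e4 / (12π r³) · [ Δχ_ax (3cos²θ − 1)
                                  + (3/2) Δχ_rh sin²θ cos 2φ ],

with r in Å and Δχ_ax, Δχ_rh in units of 10⁻³² m³. Equivalently, with the
traceless symmetric tensor χ expressed in the structure frame,

    PCS(ppm) = 1e4 / (4π r⁵) · rᵀ χ r ,

which is **linear in the five independent components of χ** once the metal
position is fixed — the property the fitting module is built around. PCSs in
ppm are nucleus-independent: the ¹H and ¹³C shifts of one methyl differ only
through the small (≤0.4 Å) difference between the proton-centroid and carbon
evaluation points. ¹H PCSs are evaluated at the centroid of the three methyl
protons (fast rotation about the threefold axis averages them there; for an
ideal tetrahedral methyl the centroid sits 1.09/3 ≈ 0.36 Å from the carbon),
¹³C PCSs at the carbon. Structures without protons are accepted with a
logged warning; ¹H PCSs then use the carbon position.

Fitted tensors are reported in the unique tensor representation (UTR):
eigenvalues ordered by increasing magnitude, which makes |Δχ_ax| maximal
among equivalent parameterizations and guarantees |Δχ_rh| ≤ (2/3)|Δχ_ax|.
Axis sign ambiguities are resolved by flipping each eigenvector so its
largest-magnitude component is positive and rebuilding the frame
right-handed.

## Measuring PCSs from peak lists

A PCS is the shift difference of the same cross-peak between the tagged
(paramagnetic) and untagged (diamagnetic, tag removed by reduction) spectrum.
Default measurement precisions are 0.008 ppm (¹H) and 0.05 ppm (¹³C); these
also set the inverse-variance weights of the tensor fit.

Automatic peak pairing exploits the nucleus-independence of the PCS: a
genuine tagged↔untagged pair moves along the spectral diagonal
(Δδ¹H ≈ Δδ¹³C in ppm). Pairing is solved as a linear assignment problem
whose cost is the squared deviation from the diagonal, normalized by the
combined tolerance plus a 6% proportional term for the proton/carbon
geometry difference; displacements more than 5σ off the diagonal are never
paired. Crossing trajectories — two peaks of one spectral region shifting by
different amounts along the same diagonal — are genuinely ambiguous from
peak lists alone, so the initial pairing *withholds* any pair whose rival
costs within a margin (default 9) of the chosen one. Withheld peaks carry no
measured value until tensor predictions arbitrate. Untagged peaks with no
plausible partner are flagged as candidates for paramagnetic blanking.

Sharp peaks that show no PCS in any dataset and coincide with a
user-supplied free-subunit reference spectrum are treated as nuisance peaks
from unassembled subunit and excluded.

## Tensor fitting

One tensor is fit per (tag site, lanthanide) group, pooling the PCSs of all
isotopically labeled subunits and assuming one metal position per group. The
objective Σ[(obs − calc)/tolerance]² is minimized by **variable projection**:
an outer 3-parameter search over the metal position
(`scipy.optimize.least_squares`, Levenberg–Marquardt) with an exact inner
weighted linear solve for the five χ components at each trial metal. This
replaces a naive 8-parameter search with orientation multi-start: because
the orientation enters linearly through χ, no orientation starts are needed,
and only the metal requires multi-starting (default: 16 positions jittered
within 5 Å of the supplied guess, typically the tagged residue's Cβ).

Two soft restraints are available and used by the assignment loop:

* a **tag-reach prior** keeping the metal within `prior_radius` (default
  12 Å) of the tagged residue's Cβ — zero inside the ball, linear outside —
  reflecting the covalent geometry of the tag arm;
* a **same-site sibling prior**: two lanthanides on one tag site occupy
  nearly the same position, so the better-determined group's fitted center
  (more records, both nuclei) anchors the weaker one (typically the ¹H-only
  Yb group) within 2 Å. The two groups are still fit independently — there
  is no hard shared-center constraint — but the weak fit is regularized
  toward the strong one. A hard shared-center mode is deliberately absent
  from the defaults.

Fit quality is summarized by Q = rms(obs − calc)/rms(obs) and the ordinary
least-squares slope m and intercept y0 of observed versus calculated PCSs.
Parameter uncertainties use a Monte-Carlo protocol: 100 refits on random
subsets with 20% of the PCSs omitted, standard deviations taken over the
UTR-reduced refits; refits start from the full-data optimum and the whole
procedure is deterministic under a seed. A leave-one-methyl-out refit is
provided as a sensitivity check; methyls carrying large PCSs perturb the
tensor more when removed than methyls with small ones.

## The assignment loop

Assignment proceeds by seed → fit → predict → match, iterated to a fixed
point.

**Seeding.** Two automatic heuristics: (a) residue-type uniqueness — a
subunit with exactly one Met (or Ile) and exactly one cross-peak compatible
only with that spectral class pins the pair; (b) distance-vs-magnitude
ranking — when the methyls surviving blanking all lie in one narrow
directional cone from the tag, the evenness of the PCS angular factor makes
their shifts share one sign and order by 1/r³, so peaks ranked by |¹H PCS|
map onto methyls ranked by distance. Heuristic (b) verifies its own
premises (single cone, uniform sign, residue-class consistency of the
ranked match) and produces nothing when they fail, e.g. for mid-structure
tags whose far field spans two cones.

**Tensor bootstrap.** The uniqueness seeds alone leave the 8-parameter
tensor under-determined (they admit an exact fit at *any* metal position),
so the initial tensor of each group is found by a grid search: candidate
metal positions on a 3 Å grid inside the tag-reach ball, χ solved linearly
from the seed records at each, each candidate scored by the cost of the best
peak↔methyl matching over all of the group's data (per-term costs capped so
single corrupt values cannot sink a true candidate). A diverse subset of
candidates (enforcing ≥4 Å metal separation, so distinct basins all
compete) is polished by match→refit alternation, and when several groups
return multiple candidate basins, the combination minimizing the *joint*
matching cost across all groups is kept — tensors that disagree about the
peak permutation are mutually incompatible, which is a strong discriminator.
Groups whose seeds are too sparse (typically Yb) join later, once
assignments made with the first tensors supply them enough records; a group
whose tensor still cannot explain the conservative measurements when the
loop stabilizes is evicted and rebuilt from the other groups' assignments.

**Matching.** Candidate costs are computed **directly against the raw
tagged spectra**: hypothesis (peak u, methyl m) predicts the tagged position
u + PCS(m) in each dataset, and its cost term is the tolerance-normalized
squared distance to the nearest tagged peak (both spectral dimensions are
always used — the cross-peak position is 2D even when only ¹H PCS values
are recorded, as for Yb). Matched terms are centred on their χ² expectation
so hypotheses with different numbers of contributing datasets compare
without bias. A missing tagged peak costs nothing when m lies inside the
lanthanide's blanking radius (default 20 Å Dy, 9 Å Yb, slack 5 Å) and a
penalty when m is far outside it. Residue-type class conflicts and
stereospecific conflicts are infinite. Stereospecific samples restrict
Leu/Val candidates both ways: presence of a peak in the (say) pro-S-labeled
sample's untagged list pins pro-S, absence pins pro-R — the untagged list
is unaffected by blanking, which is what makes the negative inference safe.
Scoring against raw spectra means no derived value can ever feed back on
itself, which proved essential: earlier designs that iterated on measured
values could lock overlapping peaks into self-consistent swapped pairs.

The minimum-cost matching is solved per subunit (`linear_sum_assignment`);
pairs with no spectral support, or costs beyond an outlier ceiling (25 per
term, ≈5σ²), are left unassigned. Tensor refits then use values re-derived
from the raw peak lists for the committed pairs only (prediction-guided
matching within a tight window, rival-margin 9 so overlapping peaks
contribute nothing), with records whose residuals exceed 3σ trimmed and the
tensor refit — robustness against the not-yet-correct fraction of the
mapping.

**Classification.** An assignment is *unambiguous* when (a) the cost gap to
the second-best methyl exceeds the margin threshold (default 9 ≈ a 3σ² gap),
(b) measured support comes from ≥2 independent datasets, and (c) the winning
cost itself is plausible (≤4 per term). The margin requirement is raised
(×3) for peaks compatible with more than one residue-type class (the Leu/Val
¹³C overlap) and further (×5) for methyls within blanking reach of any
metal, whose evidence partly consists of excused absences — empirically the
two populations where a confident-looking wrong assignment can arise.
Everything else assigned is *tentative*.

The loop terminates at a fixed point of the mapping+status signature, on
revisiting a previous state (oscillation), or after `max_iter` (20)
iterations.

## The synthetic-data generator

The generator emulates the experimental design the pipeline targets: an
elongated parallel helix bundle (default four ideal α-helices, 1.5 Å rise
and 100°/residue, 60 residues each, axes on an 8 Å circle, ≈90 Å long),
subunits labeled one at a time, lanthanide tags on engineered sites, one
pair of 2D peak lists per (labeled subunit × site × lanthanide).

Defaults and what they represent:

* sequence: Leu/Val alternating every fifth position, exactly one Ile and
  one Met per helix — echoing the sparse Ile/Met content of coiled-coil
  motifs that makes those classes natural seeds;
* tag sites `B:12` and `D:40` with Dy³⁺ at both and Yb³⁺ at the first:
  two strong-shift/strong-broadening datasets plus one weak-shift/
  weak-broadening dataset per subunit, the design that resolves near-tag
  ambiguities; the metal sits 8 Å radially outward from the tagged
  residue's Cβ (a surrogate for the tag-arm length);
* tensor magnitudes drawn per lanthanide: Δχ_ax ∈ [−30, −20] (Dy),
  [+6, +10] (Yb), rhombicity within the UTR bound, orientations uniformly
  random — Dy large and negative, Yb smaller and opposite in sign, as for
  DOTA-based tags;
* Gaussian shift noise at the stated measurement precisions, σ_H = 0.008 and
  σ_C = 0.05 ppm, applied to the tagged peaks (the untagged list is the
  reference);
* hard-radius blanking: tagged peaks removed for methyls within 20 Å (Dy)
  or 9 Å (Yb) of the metal;
* narrow per-residue-type shift windows (Ile 0.5–1.0/9–15, Leu 0.6–1.0/
  22–27, Val 0.7–1.1/19–24, Met 1.6–2.2/15–19 ppm) to mimic poor aliphatic
  dispersion, with a deliberate Leu/Val ¹³C overlap;
* 50%-labeled Leu/Val (both methyls appear) plus one stereospecific
  (pro-S) companion sample per subunit at the first Dy site, mirroring the
  use of stereospecific labeling to tell prochiral methyls apart;
* 10% nuisance peaks from unassembled subunit: sharp, PCS-free, present at
  (slightly offset) free-subunit shifts in both spectra, with a free-subunit
  reference list emitted alongside.

All randomness flows from one seed; equal configurations give byte-identical
outputs, and every dataset ships with its ground truth (true tensors,
peak→methyl map, blanked methyls, noiseless PCSs).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: lineshapes and peak overlap beyond coincidental
shift collisions, paramagnetic relaxation as a rate (blanking is a hard
radius, not a PRE model), tag-conformer ensembles and tag mobility
(averaged or site-dependent tensors), chemical-exchange broadening near
buried polar clusters, and structural error between the coordinates used
for prediction and the true solution structure. Real applications should
expect the near-tag region to be harder than the simulation suggests.

## Numerical choices

* Fit convergence: `ftol = xtol = 1e-12` (relative); noiseless synthetic
  data recovers generating parameters to <1e-4.
* Singularity guard: evaluation points must be ≥1 Å from the metal in user
  code; internal prediction paths use a tiny guard (1e-3 Å) because a
  hypothesized metal may legitimately sit on top of a methyl that would be
  blanked anyway.
* Ties in peak pairing break by intensity similarity, then lowest peak id;
  the entire pipeline is deterministic under its seed.
* Degenerate inputs: all-zero observed vectors make Q undefined (error);
  all-equal calculated values make the regression degenerate (error);
  under-determined fits (<8 records) and empty seed sets are errors with
  explicit messages.
* Problem sizes in the validation suite: bundles of 4×60 residues
  (≈96 methyls), 200 replicates for parameter-recovery coverage, 50
  replicates for assignment recovery, 100 Monte-Carlo samples per
  uncertainty estimate — sizes chosen to give stable statistics for the
  properties being checked.

## Known limitations

* Geminal Leu/Val pairs far from every tag produce near-identical
  predictions; without stereospecific data their peaks are assigned with
  small margins (tentative) and may swap. This mirrors the intrinsic
  information content of the data, not an implementation limit.
* Peaks blanked in the strong-lanthanide datasets are constrained mainly by
  the weak lanthanide; if that tensor is poorly determined the near-tag
  region degrades first.
* The bootstrap's metal grid assumes the tag-reach prior (default 12 Å);
  tags on long flexible linkers would need a wider ball and correspondingly
  more candidates.
* No treatment of residual dipolar couplings, contact shifts, or
  multi-conformer tensor averaging.
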