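# Methods

## Equilibrium occupancy model

A promoter carries an ordered set of operator sites i = 1..n (n ≤ 8), each
with a dissociation constant K<sub>d,i</sub> in µM. At free repressor
concentration c, a binding configuration S (the subset of occupied sites)
has statistical weight

w(S) = ∏<sub>i∈S</sub> (c / K<sub>d,i</sub>) · ∏<sub>i<j∈S</sub> ω<sub>ij</sub>,

and P(S) = w(S) / Σ<sub>S'</sub> w(S') over all 2<sup>n</sup>
configurations, enumerated exhaustively with weights handled in log space
so extreme c/K<sub>d</sub> ratios cannot overflow. The pairwise coupling
factors ω<sub>ij</sub> default to 1 (independent sites) — the regime that
describes the Rv2827c data — and ω > 1 reproduces AbiEi-like positive
cooperativity. ω is deliberately *not* fitted by default: on band-count
data of typical titration sizes, coupling factors and K<sub>d</sub>
rescalings are poorly separable.

Marginalizing P(S) over |S| gives the band distribution, the predicted
intensity fractions of the 0..n gel species; with ω = 1 it equals the
Poisson-binomial distribution of independent per-site occupancies
p<sub>i</sub> = c/(c + K<sub>d,i</sub>), an identity the test suite checks
to 1e-12 against an independently coded convolution oracle. Fractional
saturation is mean per-site occupancy, Y(c) = E[|S|]/n, strictly
increasing from 0 to 1.

The model treats the titrated concentration as free protein: in EMSA
conditions the probe (sub-nM in the reaction) is far below every
K<sub>d</sub> here, so ligand depletion is negligible and no correction is
applied.

### Apparent Hill coefficient

n<sub>H</sub> is the slope of log<sub>10</sub>θ vs log<sub>10</sub>c at
θ = Y/(1−Y) = 1. The half-saturation point is located by bisection on
log-concentration over [min K<sub>d</sub>/10⁴, max K<sub>d</sub>·10⁴]
(widened automatically if strong coupling pushes the midpoint outside),
to |Y − ½| < 1e-10; the slope is a central finite difference with step
1e-4 in log₁₀ space. Heterogeneous independent sites give n<sub>H</sub> < 1
— apparent negative cooperativity from affinity spread alone — and
n<sub>H</sub> falls monotonically as the K<sub>d</sub>s spread at fixed
geometric mean.

### Kd fitting

`fit_single_site` fits Y = c/(c + K<sub>d</sub>) with K<sub>d</sub>
parameterized as log₁₀K<sub>d</sub>, by deterministic multi-start local
least squares (log-spaced grid of starts, ~5 per decade of the titrated
range ±1 decade); curves that never leave Y ≈ 0 or Y ≈ 1 are rejected as
non-identifiable. `fit_multisite` fits the independent-site band
distribution to per-lane band fractions over log₁₀K<sub>d</sub> vectors,
using a deterministic ladder of center × spread starts; the recovered
K<sub>d</sub> multiset is returned sorted ascending because band counts
cannot identify which site is which. Ties across starts break by lowest
residual, then lexicographically smallest sorted K<sub>d</sub>s. Both fits
recover noiseless self-generated data to ≤ 1e-6 (single-site) and ≤ 1%
(multisite) relative error.

## EMSA Hill-plot pipeline

A quantified titration is a band table: per lane, a protein concentration
and one intensity per band species k (k proteins bound). Per lane,
fractional saturation is stoichiometrically weighted,

Y = Σ<sub>k</sub> k·I<sub>k</sub> / (n · Σ<sub>k</sub> I<sub>k</sub>),

which reduces to bound/total for a single-site probe. The alternative
"any-bound" reading Y = Σ<sub>k≥1</sub>I<sub>k</sub>/ΣI<sub>k</sub>
(fraction of probe molecules with ≥ 1 protein) is available as an option,
but on a multi-operator probe it is dominated by the tightest site and its
Hill slope stays near 1 regardless of the affinity ladder; only the
occupancy weighting exposes the negative-cooperativity signature that the
intact four-repeat promoter shows. Replicates at the same concentration
are averaged before transformation (mean ± SEM).

Hill points are (log₁₀c, log₁₀θ); lanes at c = 0 or with Y within
ε = 1e-6 of 0 or 1 have no finite Hill coordinate and are excluded (the
count of exclusions is reported, and adding fully unsaturated/saturated
endpoint lanes never changes the fit). The Hill line is ordinary least
squares over points with |log₁₀θ| ≤ 1 (≈ Y ∈ [0.09, 0.91]) — the standard
"slope at log θ = 0" practice, robust on 8–12-lane titrations — with a
fallback to the 4 points nearest log θ = 0 when the window holds fewer
than 2; the window is configurable. Then n<sub>H</sub> = slope and
K<sub>d</sub> = 10<sup>x-intercept</sup> (base-10 logarithms throughout,
as the 10<sup>x</sup> extraction requires). Classification uses a
dimensionless tolerance (default 0.10): n<sub>H</sub> < 0.9 negative,
> 1.1 positive, else non-cooperative. A non-positive slope raises a
pathological-fit error rather than returning silently.

## Inverted-repeat scanning

All (left position, spacer) placements are scanned exhaustively; a
placement is a hit when the Hamming distance between the left arm and the
reverse complement of the right arm is within the mismatch budget. The
scan is vectorized: for each spacer, all left windows are compared against
the corresponding windows of the reverse-complemented sequence in one
array operation. Coordinates are 1-based inclusive on the top strand, both
arms reported as top-strand text; an anchor at the translational start
maps position p to −(anchor − p). Defaults (arm 23 bp, spacers 0–20,
≤ 4 mismatches) admit the 13 bp intra-pair and 3–4 bp spacer architectures
of the antitoxin-controlled promoters and the degeneracy of their
consensus. IUPAC ambiguity codes in input are rejected so mismatch counts
stay unambiguous.

A palindromic locus supports shifted *registrations* — moving the left
start by ±k while changing the spacer by ∓2k pairs the same positions
about the same symmetry axis — so imperfect repeats typically produce a
small family of hits per locus. Optional overlap resolution keeps one hit
per region (lowest mismatch count, then leftmost start, then smallest
spacer), but because a registration that drops a mutated arm edge can
legitimately score fewer mismatches than the planted coordinates,
benchmarks that require exact planted coordinates evaluate the unresolved
hit list; shifted registrations and random background hits are monitored,
not asserted tightly.

Consensus matrices are plain position-frequency matrices over aligned
arms, with a majority-rule consensus string using IUPAC codes for ties,
and a mismatch score Σ<sub>pos</sub>(1 − f(base)) for ranking candidate
operators against the consensus.

## Reporter analysis

Miller units are computed exactly as mU = slope(OD420/min) × 5000 /
OD600(first time point), with the slope an OLS fit over the full kinetic
window (every 90 s for 1 h in the default design); an optional early
window handles saturating wells, and negative slopes are returned as
computed but flagged. Replicates aggregate as mean ± sd; normalized
activity divides by a named control's mean, with the ratio's sd propagated
by the delta method using each condition's SEM (validated in tests against
a 10⁵-draw Monte-Carlo oracle). The repression ratio is induced/uninduced
mean activity; values < 1 indicate negative autoregulation.

## Synthetic data

The generators emulate the study conditions rather than idealized data:

- **EMSA titrations** — 12 log-spaced lanes spanning ±2 decades around the
  K<sub>d</sub> plus the mandatory zero-protein lane, in triplicate.
  Expected band intensities are probe intensity × band distribution; each
  intensity receives an independent multiplicative lognormal factor
  (σ = 0.05 by default — intensities stay positive, matching the
  few-percent spread of triplicate gel densitometry) and an optional
  additive background. With σ = 0 the lane fractions equal the model
  exactly.
- **polyC mutant probes** — replacing a repeat by a cytosine tract ablates
  its binding event, so knockouts are modeled as site deletion; knocking
  out every site yields a probe that never shifts.
- **Planted promoters** — uniform-random background with inverted-repeat
  pairs written at known positions, the right arm carrying a stated number
  of point mutations at distinct random positions; ground-truth
  coordinates are returned with the sequence (and all generators echo
  their truth as sidecar JSON from the CLI) so tests never re-derive them.
- **Reporter kinetics** — transcription is gated on the fully unbound
  promoter: OD420 ramps at basal_slope × P(0 sites bound) per minute with
  additive Gaussian read noise; OD600 at the first time point is drawn
  uniformly near 0.5.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give bit-identical outputs.

What the generators do *not* emulate — and what passing tests therefore do
not establish about real gels — includes band-overlap and smearing in
densitometry, lane-to-lane loading correlations, competitor-lane effects,
ligand depletion at high probe loads, cell-growth and lysis variability in
reporter wells, and any structure in real promoter background sequence
(GC bias, repeats). Conclusions about those require real data.

## Problem sizes and numerical choices

Simulation-heavy checks use sizes at which the statistics are stable and
the whole suite stays interactive: 200–500 seeded noisy titrations for
robustness medians and classification rates, 100 randomized models for
the enumeration/convolution identity, 1000 planted 200-bp promoters for
scanner recovery, 10⁵ Monte-Carlo draws for the delta-method check.
Distribution normalization is asserted to 1e-12; the enumeration uses a
max-shifted softmax; optimizer tolerances are set to machine-level
(xtol = ftol = gtol = 1e-15) since the deterministic multi-start absorbs
the cost. Degenerate inputs (zero-intensity lanes, all-saturated curves,
zero-site models, anchors inside a repeat) raise typed errors rather than
producing numbers.

## Known limitations

- Coupling factors ω are representable but not fitted; the package cannot
  distinguish true site–site coupling from affinity heterogeneity using
  band counts alone.
- The band model predicts how many sites are bound, not which site a
  particular shifted species corresponds to; per-site identities come only
  from knockout-probe designs.
- Hill-plot K<sub>d</sub> extraction assumes the titration brackets
  half-saturation; entirely unsaturated or saturated curves are rejected
  rather than extrapolated.
- The scanner reports registration families for imperfect palindromes (see
  above); downstream consumers that need one interval per operator should
  use the resolved list and treat coordinates as axis-accurate rather than
  base-accurate at the arm edges.
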