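# Methods

`coedecomp` decomposes a conformational ensemble of an intrinsically
disordered protein (IDP) into radius-of-gyration (Rg) groups and
characterizes each group with the standard repertoire of
ensemble observables. This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic test
data can and cannot show.

## The decomposition

Every frame's mass-weighted radius of gyration

    Rg = sqrt( Σᵢ mᵢ ‖rᵢ − r_com‖² / Σᵢ mᵢ )

is computed over all atoms (not Cα only, matching the convention of the
common trajectory tools) and the frame is assigned to the integer-Å group
nearest its Rg. Rounding is half-away-from-zero: with group labels printed
as integers there is no canonical binning rule, and half-up is the
reproducible choice. Empty labels are omitted; groups holding fewer than
0.1 % of all frames (configurable) are flagged *low-sampling* in the
histogram output rather than dropped, since extreme-Rg groups carry large
statistical errors in every per-group average. The partition is exported in
the GROMACS `.ndx` dialect (1-based frame numbers, ≤15 per line) so external
tools can split trajectories along it.

## Scattering

Profiles are computed per frame with the Debye formula,

    I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ),

using 4-term Cromer–Mann vacuum form factors for H, C, N, O, S. No
hydration-shell or excluded-volume term is included (the
hydration-contrast-zero convention). Group and global averages are plain
arithmetic means of per-frame intensities, so group averages recombine
exactly into the global average with the occupancy weights.

Two evaluation paths exist: a direct O(A²) double sum (the reference) and a
binned path that histograms pair distances per element pair at 0.01 Å
resolution. They agree to better than 0.1 % over the default grid
(0–0.5 Å⁻¹, 101 points; a range where the small-angle approximation and the
form-factor tables are comfortable).

P(r) is a direct histogram of intra-frame atom-pair distances weighted by
fᵢ(0)·fⱼ(0), averaged over the selected frames and normalized to unit area
(default bin width 1 Å). This deliberately avoids the indirect Fourier
transform used by experimental P(r) tools: model coordinates are available,
so regularized inversion would only add machinery that cannot be verified
against them. `r_max` is reported as the largest pair distance encountered.
Self-pairs enter the r = 0 bin with weight Σfᵢ(0)², which makes
∫P(r)·sinc(qr)dr · (Σf(0))² reproduce the Debye profile at small q (within
≈2 % at q ≤ 0.3 Å⁻¹; the residual is the q-dependence of the form factors
that the q = 0 weighting ignores, plus binning error).

χ² against an experimental curve is

    χ² = (1/N) Σᵢ [(Eᵢ − c·Sᵢ)/σᵢ]²,

with the simulated profile linearly interpolated onto the experimental grid
restricted to the overlapping q window, σᵢ = 1 where no uncertainties are
given, and the scale c fitted by weighted least squares (CRYSOL-style
comparisons fit a constant; a flag pins c = 1).

## SASA

Shrake–Rupley with a deterministic golden-spiral point lattice (default 960
points, probe 1.4 Å, Bondi van der Waals radii). An isolated atom
reproduces 4π(r+probe)² to well under 2 % at 960 points; doubling the point
count changes a 24-residue chain's total by <1 %. Note the lattice is fixed
in space, so per-atom areas are rigid-motion invariant only to within the
quadrature error; totals converge much faster.

Normalized SASA is observed − expected per residue (signed Ų), with the
expected baseline the theoretical maximum-ASA scale of Tien et al. (2013),
user-overridable. The across-group variance of the normalized values is
reported per residue. The (Rg, total SASA) density uses a Gaussian product
kernel with per-dimension Scott's-rule bandwidths (σ·n^(−1/6)).

## Hydrogen bonds and contacts

Two H-bond criteria serve two purposes. The *geometric* criterion
(donor–acceptor ≤ 3.5 Å and H–donor–acceptor angle ≤ 30°, the `gmx hbond`
defaults) drives the per-group occupancy maps; donors are N/O atoms with a
covalently attached hydrogen (nearest N/O within 1.25 Å). Self and
adjacent-residue pairs are excluded from the summary maps but kept in the
raw detection. The *energetic* Kabsch–Sander criterion

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,  bond if E < −0.5

drives the secondary-structure assignment only. Contact maps are per-frame
residue-pair distances (minimum heavy-atom by default, Cα–Cα optionally)
averaged within each group.

## RMSF, clustering, tICA

RMSF per group: frames are Kabsch-superposed (proper rotations only) on
their Cα atoms onto the group mean, the mean is re-averaged, and the loop
iterates to convergence (mean shift <10⁻⁴ Å, ≤10 iterations); RMSF is the
per-residue RMS deviation from the converged mean. Clustering is the GROMOS
(Daura) neighbor-counting algorithm on pairwise Cα RMSD with a 7 Å default
cutoff; ties go to the lowest frame index, making the output deterministic.

tICA is solved as the symmetrized generalized eigenproblem
C_τ v = λ (C₀ + εI) v with C₀, C_τ estimated from the mean-centered head and
tail blocks; symmetrization keeps eigenvalues real and within [−1, 1] up to
regularization, and eigenvectors are orthonormal in the C₀ metric.
Defaults: features = all Cα–Cα distances with sequence separation ≥2
(rigid-motion invariant and defined for backbone-only chains; sin/cos
dihedral features are available), lag = 10 frames,
ε = 10⁻⁶·trace(C₀)/dim. Free-energy landscapes are −ln(occupancy) in kT over
a 60×60 grid spanning the 1st–99th percentile of the two leading
projections, shifted so the occupied minimum is zero, with empty bins
masked.

A point on timescales: for the synthetic two-state generator with symmetric
per-frame switch probability p, the slow process relaxes with autocorrelation
(1−2p)^τ, so the leading implied timescale −τ/ln λ₁ estimates the
*relaxation* time −1/ln(1−2p) ≈ 1/(2p), which is half the mean dwell time
1/p. The property tests therefore check factor-2 recovery of the relaxation
time; expecting the dwell time itself from the leading eigenvalue would sit
exactly on the factor-2 boundary and fail for purely mathematical reasons.

## Secondary structure

φ/ψ follow the IUPAC convention (φᵢ = C(i−1)–N–CA–C, ψᵢ = N–CA–C–N(i+1));
termini are masked undefined. Ramachandran integration uses four fixed
windows (degrees):

| region | φ | ψ |
|---|---|---|
| β-sheet | [−170, −120) | [120, 180) |
| PPII helix | [−90, −40) | [100, 180) |
| α-helix | [−110, −40) | [−50, 10) |
| LH helix | [30, 70) | [10, 50) |

Membership is closed-low/open-high per axis so abutting windows cannot
double-count; the windows are mutually disjoint and do not tile the plane,
so fractions need not sum to 1. Fractions are counted over raw (φ, ψ)
points; a 2° histogram (standard Ramachandran practice) is produced for
plotting.

The reduced DSSP assigns five classes with priority H > E > T > P > C:
n-turns where the carbonyl of residue i accepts the amide of i+n
(n ∈ {3, 4, 5}) under the Kabsch–Sander criterion; H for runs under two
consecutive 4-turns; E for ladders of ≥2 consecutive bridge residues
(parallel or antiparallel patterns); T for interior residues of any turn;
P for runs of ≥2 residues inside the PPII window (classic DSSP has no PPII
class; the dihedral rule approximates the modern one). Everything else is
coil.

## The synthetic generator

Real input to this workflow is a long MD trajectory; the generator emulates
the statistical features the analyses consume, for a 24-residue
histatin-5-like chain (net charge +5e with charged termini and neutral
histidines at neutral pH — the standard protonation convention for this
peptide).

Frames are grown residue-by-residue with ideal peptide geometry
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.010 Å; angles
111.2°/116.2°/121.7°; ω = 180°) from (φ, ψ) pairs sampled from the
Ramachandran windows above, plus a coil class uniform over the complement
of the four windows. Rebuilding dihedrals from the constructed chain
reproduces the inputs to 10⁻³ degrees, which ties the generator and the
analysis stack together end-to-end. Chains are backbone-only
(N, H, CA, C, O) with optional Cβ pseudo-atoms; there is no solvent, no
side-chain packing and no force field.

Default single-state occupancies are β 0.25 / PPII 0.30 / α 0.15 / LH 0.03 /
coil 0.27 — a disordered, extended-leaning mix of the kind short cationic
IDPs show, which yields a broad smooth Rg distribution (≈7–20 Å over a few
hundred frames, mean ≈12 Å) spanning the regime the decomposition is meant
to resolve.

Steric clashes (heavy-atom pairs more than two residues apart closer than
2.0 Å) are relieved by redrawing angles **within the frame's already-drawn
region labels**, up to 100 attempts, then accepted with a warning. Keeping
the labels fixed during resampling is deliberate: redrawing whole frames
would let the clash filter reject compact label combinations
preferentially, measurably biasing the region occupancies (≈+0.7 pp toward
PPII), whereas with fixed labels the occupancies remain exactly multinomial
in the configured weights — the generator's headline parameter-recovery
guarantee.

With `switch_prob` > 0 a hidden two-state Markov chain alternates between a
compact-biased regime (α 0.55 / LH 0.05 / coil 0.40) and an extended-biased
regime (β 0.30 / PPII 0.50 / coil 0.20), both overridable. This produces
the temporally correlated slow coordinate tICA is designed to find; the
chain state is returned alongside the coordinates as ground truth.

What passing tests on this input do **not** show: realism of force-field
energetics, solvation effects, side-chain H-bonding, or the specific
per-residue values a real MD ensemble would give. The synthetic ensemble
validates the *operators* (their closed forms, invariances, oracles and
parameter recovery), not the biology.

## Problem sizes and reproducibility

Test and acceptance runs use deliberately modest sizes — hundreds to a few
thousand generated frames, 24-residue chains, 120–960 SASA points —
chosen so the statistical assertions (3σ binomial recovery, 20-seed sign
tests at α = 0.01, ±0.05 on an AR(1) eigenvalue at n = 20 000) have the
power they claim while the whole suite stays quick. All randomness flows
from explicit seeds through `numpy.random.default_rng`; the pipeline writes
a manifest with SHA-256 checksums per output, and identical config + seed
reproduce identical checksums.

## Known limitations

- The Debye implementation targets the small-angle regime; no excluded-
  volume or hydration corrections, so absolute intensities are vacuum-atom
  values.
- P(r) from coordinates is not comparable bin-for-bin with regularized
  experimental P(r) inversions near r = 0 and r = r_max.
- The reduced DSSP omits the 3₁₀/π distinctions, isolated bridges and bends
  of the full 8-class scheme.
- GROMOS clustering is O(F²) in pairwise RMSD; intended for per-group frame
  counts in the thousands, not the full 300 k-frame concatenations of
  production MD studies (decompose first, then cluster per group).
- The generator's coil class is uniform over the non-window plane, which
  overweights sterically strained (φ ≈ 0) conformations relative to real
  coil libraries; the clash filter removes only hard overlaps.
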