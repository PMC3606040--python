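# Methods

## Model

The total model structure factor for reflection **s** = (h, k, l) is

    F_model(s) = k_total(s) · (F_calc(s) + k_mask(s) · F_mask(s)),
    k_total = k_overall · k_isotropic(s²) · k_anisotropic(s),

with observed amplitudes F_obs compared against |F_model|. F_calc and
F_mask are inputs (computed upstream from the atomic model and the solvent
mask); the package determines the scales. The agreement measures are the
amplitude least squares LS = Σ(F_obs − |F_model|)² and the R factor
R = Σ|F_obs − |F_model|| / ΣF_obs.

## Per-bin solvent and isotropic scales

Within one resolution bin, k_total and k_mask are treated as constants.
Writing K = k_total⁻², I = F_obs², u = |F_calc|², w = |F_mask|² and
v = Re⟨F_calc, F_mask⟩, the intensity-space residual is

    LS(K, k) = Σ [K·I − (u + 2kv + k²w)]².

Its stationary conditions in K and k = k_mask are two polynomial equations;
eliminating K via the first normal equation

    K(k) = (ΣIu + 2k·ΣIv + k²·ΣIw) / ΣI²

yields a cubic in k with coefficients

    c₃ = ΣI²·Σw² − (ΣIw)²                       (≥ 0, Cauchy–Schwarz)
    c₂ = 3[ΣI²·Σvw − ΣIv·ΣIw]
    c₁ = ΣI²·(2Σv² + Σuw) − ΣIu·ΣIw − 2(ΣIv)²
    c₀ = ΣI²·Σuv − ΣIu·ΣIv.

Roots are computed from the companion matrix (numpy.roots) after scaling;
when leading coefficients fall below 1e-12 of the largest, the equation
degrades gracefully to quadratic/linear. Candidate solutions are every real
root with k ≥ 0 whose induced K is positive, **plus always the boundary
k = 0** with K from the pure-model normal equation; the candidate with the
smallest LS wins. Including the boundary point is a deliberate superset of
the minimal "zero if no positive root" rule: when the constrained minimum
sits on the k = 0 boundary there is no interior stationary point, and the
boundary candidate guarantees the solution is never beaten by a grid
search. Bins whose observed intensities are all zero raise an error.

The per-bin k_mask curve is then smoothed with a Savitzky–Golay filter
(window 5 bins, order 2, shrunk for short inputs, polynomial edge
handling); the filter is skipped entirely when the input is already
monotone, so a monotone trend is never altered, and negative outputs are
clamped to zero. Smoothed per-bin values are assigned to reflections by
piecewise-linear interpolation in s² between bin centers (midpoint of the
bin's s² range), constant beyond the outer centers. After smoothing changes
k_mask, the per-bin isotropic scale is refreshed with the exact bin-scalar
minimiser k = Σ(F_obs·A)/ΣA², A = |F_calc + k_mask F_mask|.

Because the LS and R minima can sit at visibly different (k_mask,
k_isotropic) — heavy-tailed errors are enough to separate them — an
optional per-bin grid refinement scans k_mask over [0, 2·k_LS] (or [0, 1]
when k_LS = 0) in 41 steps, re-deriving k_isotropic at each trial, and
keeps the pair with the lowest R; the LS pair is always a candidate, so the
refinement never hurts. The factor-2 window reflects the observation that
the two minima sit within roughly a factor of two of each other.

For reporting, the classical flat-model parameters are obtained by fitting
k_sol·exp(−B_sol·s²/4) to the positive per-bin k_mask values: a closed-form
log-linearised weighted least squares (weights k_mask², which linearises
the exponential without biasing toward small values) followed by a
Levenberg–Marquardt polish on the untransformed residual. Fewer than two
positive bins means "no solvent model" (None). The same fit applied to the
per-bin K (or isotropic) values gives (k_overall, B_overall).

## Anisotropic scaling

Exponential model: k_aniso = exp(−2π² sᵗU_cryst s) with U_cryst a symmetric
tensor in the Miller-index basis. Requiring k_aniso·A = F_obs and taking
logs gives the linear problem sᵗUs = −Z, Z = (1/2π²)·ln(F_obs/A), solved by
6×6 normal equations M U = b with M = ΣV⊗V, b = −ΣZ·V and
V = (h², k², l², 2hk, 2hl, 2kl). Point-group constraints enter via the
constraint matrix C (U = Cᵗ·U_ind): the reduced system is (C M Cᵗ)U_ind = C b.
Reflections with non-positive F_obs or model amplitude are excluded from
the log fit only, and counted. A condition number above 1e12 raises a
rank-deficiency error naming the unconstrained direction.

C is derived from first principles: the null space (SVD, singular values
below 1e-9 of the largest treated as zero) of the stacked maps
U ↦ RᵗUR − U over the 6-dimensional symmetric space, for all point-group
rotations R acting on Miller indices (for a symmetry operation with
fractional-coordinate matrix W the Miller indices transform by Wᵗ).
The basis is orthonormal with signs fixed (first nonzero element positive)
and rows sorted, so it is deterministic. This reproduces the classical
independent-coefficient counts 6/4/3/2/2/2/1 for the seven crystal systems.
Because the basis is orthonormal rather than the hand-tabulated one, the
*components* of U_ind differ from textbook tables, but the spanned
subspace — the only thing that matters — is identical, and a reporting
utility converts to Cartesian B values (B = 8π²·Aᵗ U* A with A the
direct-basis matrix).

Polynomial model: k_aniso = 1 + sᵗV₀s + s²·(sᵗV₁s), the first Taylor terms
of the exponential with the constant restored so F000 keeps scale 1. Of the
two readings of the second-order term the s²-weighted quadratic form was
chosen; it is held behind a single evaluation function so the alternative
(squared first-order form) is a one-line swap. The fit is linear in the 12
coefficients, minimises the amplitude residual directly (no positivity or
log-proximity assumptions) and, following its originators, applies no
symmetry constraints; a near-singular 12×12 system falls back to the
pseudo-inverse with a warning.

A third variant polishes the constrained exponential tensor by L-BFGS-B on
the amplitude residual, starting from the analytic log-domain solution and
never returning anything worse than its start. Exponent arguments are
clamped at ±60 to survive wild trial steps. The log-domain and
amplitude-domain minima genuinely differ on noisy data (the tests assert a
strict inequality under asymmetric noise).

## Logarithmic binning

Boundaries are uniform in ln(d). Rationale: data density grows like d⁻³,
so equal-count bins starve the low-resolution region where the solvent
scale varies fastest, while the roughly exponential resolution dependence
of the scales makes their per-bin variation uniform on a log scale. The
algorithm lays a fixed grid of `max_bins` (default 30) uniform ln(d)
slices over the data range, then sweeps from low resolution to high,
greedily accumulating slices until each bin holds at least `min_count`
(default 300) reflections; a trailing under-populated remainder merges
into the previous bin. Consequences: surviving boundaries stay on the
uniform log grid; low-resolution bins hold approximately the floor while
high-resolution bins may hold thousands; and the bin count is provably
non-increasing in `min_count`. Bin i covers (b[i+1], b[i]] with closed
outer bounds; out-of-range reflections are clamped to the nearest bin and
logged. An equal-count (d⁻³) partition is provided for comparison only.

## Twinning

Observed intensities of a crystal with N twin domains are modelled as
Σ_j α_j I_j with I_j(s) = k_total²|F_calc(T_j s) + k_mask F_mask(T_j s)|²,
Σα_j = 1, operators T_j acting on Miller indices and scales shared across
domains. The constrained minimiser of Σ(I_obs − Σα_j I_j)² solves an
(N+1)×(N+1) linear system whose last row/column carry the constraint; the
Lagrange-multiplier column is multiplied by the mean over reflections of
Σ_j I_j², keeping λ on the numerical scale of the fractions. The solved
fractions are shifted by the (round-off-sized) constraint defect so
Σα = 1 holds to machine precision. Twin mates are resolved by index lookup
through the point-group rotations and the Friedel inversion; reflections
without a resolvable mate are excluded from fraction estimation but kept
for scaling.

Scale determination under twinning replaces (u, v, w) by their α-weighted
sums, after which the cubic machinery applies verbatim; with N = 1 and
α = (1.0) every operation multiplies by exact 1.0, so the twinned path is
bit-identical to the untwinned one. Fractions and scales are alternated
(cap 10 iterations, convergence when the twinned R changes by < 1e-4
absolute); a fraction outside [0, 1] suspends its operator for the current
iteration only — the reduced system is re-solved, with no explicit
renormalisation — and the full set is retried next iteration.

## Protocol

Each cycle: (1) per-bin (k_mask, k_isotropic) with the current
k_anisotropic divided out of the working amplitudes — cubic solve,
smoothing, isotropic refresh, optional grid refinement, interpolation;
(2) k_anisotropic refitted from scratch on the residual (refit rather than
incremental update: simpler, and convergence is observed in 1–5 cycles
either way). The reverse stage order is available behind an option. Cycles
stop when R improves by less than 1e-4 absolute (0.01%) or after
`max_cycles` (default 10); a cycle that increases R (possible when grid
refinement interacts with the anisotropic refit) restores the previous
state and stops. With several anisotropic methods requested ('all' or the
default 'poly+exp_anal' pairing of the two fast methods) each is evaluated
per cycle and the lowest-R result is accepted; the L-BFGS variant is
opt-in since it is much slower than the analytic paths for marginal gain.

Internally only the product k_isotropic·k_overall matters; at reporting
time the working per-bin isotropic curve is normalised by its mean and
k_overall is set to the optimal overall scalar Σ(F_obs·A)/ΣA² given the
normalised curve, so the decomposition of k_total is unique and the
equivariances hold exactly: scaling F_obs by c scales k_overall by c and
changes nothing else; scaling F_calc and F_mask jointly by c scales
k_overall by 1/c with all R factors unchanged.

R is reported over all reflections, over the low-resolution subset
(d > 8 Å, extended to at least the 500 lowest-resolution reflections if
fewer) and over the highest-resolution bin.

## Synthetic data

The generator draws F_calc and F_mask as circular complex Gaussians with
exponential envelopes exp(−B·s²/4) (B_model = 20 Å², B_mask = 150 Å²
by default), so the mask-to-model amplitude ratio decays with resolution —
the structure the flat solvent model assumes. Observed amplitudes follow
the forward model exactly (flat-solvent curve, anisotropic tensor, overall
and isotropic scales, optional twin mixture), then get multiplicative
Gaussian noise (default study condition 1%) and optional heavy-tailed
outliers (amplitude multiplied by 5^N(0,1) for a configurable fraction),
which exercise the LS-vs-R minimum separation. Indices are all lattice
points in the resolution range (one Friedel hemisphere), subsampled
uniformly at the stated seed; twin runs close the index set under the
operators first. The ground-truth record reconstructs F_obs bit-exactly.

What the generator does *not* emulate: measurement sigmas and
resolution-dependent error models, systematic absences, anomalous signal,
ice rings or completeness gaps, and any physical relationship between
F_calc and F_mask beyond their envelopes (in real data the two are
correlated at low resolution — the Babinet anticorrelation; a dedicated
stress case builds the exact degenerate limit F_mask = −p·F_calc).
Passing tests therefore demonstrate correctness of the estimators under
the stated statistical model, not performance on pathological real data.

Default study conditions used by the acceptance script: n = 20,000
reflections, 2.0–40 Å, k_sol = 0.35, B_sol = 50 Å², a tetragonal tensor
with Cartesian B of a few Å² to ~20 Å² (typical of mildly anisotropic
crystals), 1% noise; twinned companion: n = 5,000, fractions 0.7/0.3,
law k,h,−l, 1% noise. Sizes were chosen so the entire suite and the
acceptance run complete in seconds while keeping per-bin counts at
realistic levels (hundreds).

## Numerical choices and edge cases

- Cubic roots via companion-matrix eigenvalues; imaginary parts below
  1e-8 (relative) treated as real.
- Normal systems solved directly below condition 1e12, else
  pseudo-inverse (polynomial fit) or a rank-deficiency error naming the
  bad direction (exponential fit).
- Null-space tolerance for constraint derivation: 1e-9 of the largest
  singular value.
- Boundary-tie rule in binning: a d exactly on an interior boundary joins
  the bin in which it is the largest-d member (the (lo, hi] convention);
  outer bounds closed.
- Reflections with F_obs ≤ 0 or non-finite entries are rejected at model
  construction; the I/O layer drops and counts them on read.
- Degenerate unit cells (volume ≈ 0) and empty reflection sets raise
  typed errors before any computation.

## Known limitations

- F_mask is an input; mask parameters (solvent radius, shrink) are out of
  scope, as is computing F_calc/F_mask from coordinates.
- k_isotropic is represented per bin and interpolated; extremely sharp
  isotropic features inside one bin are smoothed over.
- The polynomial anisotropic model can go non-positive at extreme
  resolution for large coefficients; the protocol clamps the working
  factor at 1e-6.
- At very low resolution the Babinet degeneracy makes (k_total, k_mask)
  jointly unidentifiable; the solver completes and reports whichever
  admissible solution minimises the residual.
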