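# Methods

## Model

### Structural substrate

The model operates on a labelled structural connectome: a nonnegative
symmetric weight matrix C (arbitrary units, zero or nonzero diagonal is
accepted but degrees use row sums), and a symmetric fiber-distance matrix D
in millimetres with zero diagonal. Asymmetric inputs are symmetrized as
(M + Mᵀ)/2 with a warning — diffusion-MRI pipelines emit nominally symmetric
matrices with small numeric asymmetries, and averaging is the orthogonal
projection onto the symmetric subspace. Isolated nodes (zero-sum rows of C)
are rejected; zero off-diagonal distances are allowed and mean zero
conduction delay (warned). Weights are used as-is by default; whether to
log-transform connectome weights is left to the user (no transform is
applied internally).

### Complex Laplacian

Conduction delays D_jk / v become phase factors in the frequency domain:

    A*(ω)_jk = C_jk · exp(−i ω D_jk / v),   ω = 2πf,  D in metres, v in m/s.

The magnitude of every edge is preserved (|A*| = C); only phases rotate with
frequency. The complex Laplacian is

    L(ω) = I − α · Δ^{−1/2} A*(ω) Δ^{−1/2}    (symmetric_degree, default)
    L(ω) = I − α · Δ^{−1} A*(ω)               (row_degree, optional)

with Δ = diag(Σ_k C_jk) built from the **real** weights, so the
normalization is frequency-independent and L(0) with α=1 is the classical
symmetric normalized Laplacian (eigenvalues in [0, 2]). Which degree
normalizes the complex operator is genuinely open; symmetric_degree is the
default because it keeps L(ω) complex-symmetric and makes the ω=0 limit the
textbook operator, row_degree is retained for sensitivity analysis.

Eigenvectors are scaled to unit Hermitian norm and phase-fixed so that the
entry of largest magnitude is real and positive (ties: lowest index);
eigenvalues are sorted by ascending |λ|, ties broken by real part then
original index. The convention exists purely to make the outer products
u_k u_kᴴ bitwise reproducible; no convention is canonical for complex
eigenvectors.

### Local (mesoscopic) model

Each region hosts a linearized E–I pair driven by a common white-noise
input p(t):

    τ_e ẋ_e = −x_e + g_ee f_e⊗x_e − g_ei f_i⊗x_i + p
    τ_i ẋ_i = −x_i + g_ei f_e⊗x_e − g_ii f_i⊗x_i + p

with the unit-DC-gain Gamma kernel f(t) = (t/τ²)e^{−t/τ}, whose transform is
F(ω) = 1/(1 + iωτ)². Eliminating the inhibitory population gives the
excitatory frequency response

    Q_i(ω) = iωτ_i + 1 + g_ii F_i
    H_local(ω) = (1 − g_ei F_i / Q_i) / (iωτ_e + 1 − g_ee F_e + g_ei² F_e F_i / Q_i).

This algebra is the package's fixed default: it uses exactly the five
mesoscopic parameters of the model, takes the same noise input to both
populations, and is a proper rational low-pass with a gain-tunable
resonance. It is isolated behind a single function so alternative local
algebras can be swapped without touching the network level. The response is
excitatory-only by construction (the long-range signal is carried by
pyramidal populations); summing the E and I responses was considered and
rejected as the default because the excitatory output is what projects into
the graph term.

An independent oracle (`local_transfer_solve`) solves the 2×2 Fourier-domain
system directly and is used in tests to verify the closed form to 1e−10.

**Stability.** A parameter point is infeasible if (a) the real DC
denominator 1 − g_ee + g_ei²/(1+g_ii) is ≤ 0 — the E–I loop gain then
exceeds one and the linearized fixed point is unstable regardless of where
the evaluation grid samples; (b) |denominator| < 1e−6 anywhere on the grid;
or (c) |H_local| > 1e6 anywhere on the grid. The magnitude guards alone do
not catch (a) because the complex denominator's magnitude need not approach
zero at any sampled frequency even when its real part changes sign. Guard
thresholds are pragmatic; infeasible points are penalized inside the
optimizer, never fatal.

### Network response

The regional frequency response to unit white noise at every region is the
eigenmode sum

    T(ω) = [ Σ_k u_k u_kᴴ / (iω + λ_k(ω) F_G(ω)/τ_G) ] · F_G(ω) H_local(ω),

with F_G the Gamma response at the long-range time constant τ_G. The model
is implemented as printed — right eigenvectors with the Hermitian transpose.
For a non-Hermitian L(ω) (nonzero delay) this outer-product sum is not
exactly the resolvent, which would require the biorthogonal left
eigenvectors; the package therefore also provides `direct_solve`, the exact
dense resolvent (iωI + F_G L/τ_G)^{−1} F_G H_local. The two coincide on
zero-delay (real symmetric) Laplacians, which anchors the oracle tests; at
nonzero delay the difference is real and visible to the user through the
method flag, not hidden.

Under the default noise model (i.i.d. unit white noise per region) the
regional PSD is the row power S_j(f) = Σ_m |T_jm|²·|P|²; a `common` mode
(one shared noise realization, S_j = |Σ_m T_jm|²·|P|²) is retained because
the spatial correlation structure of the physiological input noise is not
knowable from resting data. P(ω) is flat with amplitude 1 by default (white
noise ⇒ flat spectrum); the PSD is homogeneous of degree 2 in the amplitude.
Model PSDs are not normalized before dB conversion (Pearson r is
affine-invariant, so per-region normalization would not change the spectral
objective).

dB conversion is 10·log₁₀(max(S, 1e−30)); the floor keeps exact zeros
finite (−300 dB) and the map invertible above it.

**Caching.** L(ω) = I − α·B(ω), where B(ω) = Δ^{−1/2}A*(ω)Δ^{−1/2} depends
only on the connectome, the normalization, v and the grid — not on any
fitted parameter. Hence the eigenvectors of L(ω) are exactly those of B(ω)
and λ_k(ω) = 1 − α·μ_k(ω). The eigendecomposition of B is computed once per
connectome/grid (`SpectralCache`) and reused across all objective
evaluations; each evaluation then costs only matrix multiplications. This is
an algebraic identity, not an approximation, and the cached and uncached
paths are asserted identical in tests. The α=0 point is special-cased: L is
then exactly the identity, whose canonical eigenbasis gives the decoupled
scalar response in every region; B's (non-orthonormal) eigenvectors would
not reproduce that limit because Σ u_k u_kᴴ ≠ I for a non-Hermitian matrix.

### Objective

*Spectral correlation*: Pearson r between modeled and target dB spectra,
computed per region across frequency bins, averaged over regions. Regions
with zero variance in either spectrum have undefined r and are excluded from
the mean with a warning (flat reference spectra occur in real
parcellations); their entry in the per-region vector is NaN.

*Spatial correlation*: the regional band-power profiles (trapezoidal
integral of raw power over 8–12 Hz by default — raw power, not dB) are
mean-centered and scaled to unit Euclidean norm, then compared through

    s = x̃ᵀ M ỹ,   M = rownorm(C_rownorm + w·I),

where C_rownorm is the row-degree-normalized C. The printed bilinear form is
not scale-invariant as written; centering and unit-normalizing is the
minimal reading under which the w→∞ limit is exactly the Pearson
correlation of the two profiles, making "correlation" literal. A
`normalize_profiles=False` toggle evaluates the raw bilinear form. Note the
bilinear form is not guaranteed to lie in [−1, 1] for every M at small w;
empirically it does for distance-dependent connectomes, and tests check the
limit behavior rather than assuming a bound.

*Combined objective*: the unweighted sum spectral_r + spatial_s; single-term
modes (`spectral_only`, `spatial_only`) optimize one term while still
reporting both. The default smoothing weight is w = 10, selected from the
candidate grid {0, 0.01, 0.1, 1, 10} (a `w_selection_harness` reruns that
comparison on any targets); Fisher's z = atanh(r) is provided as a building
block for group-level comparison of correlations.

## Inference

Seven free parameters with default bounds (physiologically plausible ranges
for cortical population dynamics):

| parameter | meaning | bounds | units |
|---|---|---|---|
| τ_e | excitatory time constant | 0.005 – 0.030 | s |
| τ_i | inhibitory time constant | 0.005 – 0.200 | s |
| τ_G | long-range (global) time constant | 0.005 – 0.030 | s |
| g_ee | excitatory self-gain | 0 – 2 | – |
| g_ei | E↔I cross-gain | 0 – 5 | – |
| g_ii | inhibitory self-gain | 0 – 5 | – |
| α | global coupling | 0.1 – 1.0 | – |

Conduction speed v is a fixed constant, default 5 m/s — a standard value
for myelinated cortico-cortical axons. Treating g_ee as free and v as fixed
keeps the parameter count at seven; the alternative (free v, fixed g_ee) is
reachable by constructing `SGMParameters` with a different `speed_v` and
pinning `g_ee` via the bounds.

The optimizer is `scipy.optimize.dual_annealing` — a simulated-annealing
generalization with a terminal local polish — with all randomness drawn
from a single seeded generator; identical seed and inputs give a
bitwise-identical trace and result. Infeasible points (stability failure or
a singular resolvent, min |iω + λ_k F_G/τ_G| < 1e−12) receive cost −∞
(a large penalty inside the minimizer), are counted, and never abort the
search. A bounded Nelder-Mead multistart (`multistart_local`) is available
as a cross-check. The evaluation budget is `max_evaluations` (default
2000); with the spectral cache one evaluation on a 68-region, 87-bin
problem costs ~15–20 ms on one CPU, so a default fit takes well under a
minute.

**Identifiability.** Distinct gain combinations produce near-identical
spectra, so parameter recovery is judged asymmetrically: fit quality
(objective attained, spectral correlation between the fitted model and the
noiseless truth) is the primary criterion; among the parameters, the time
constants τ_e and τ_G are the recoverable ones (they set the resonance and
roll-off frequencies directly), and the recovery harness reports all seven
relative errors without enforcing the gains. This is borne out by the
synthetic experiments: zero-noise recoveries routinely achieve >0.999
fitted-vs-truth spectral correlation with τ_e/τ_G errors of a few percent
while g_ee or g_ii sit far from truth.

## Synthetic data

The generator emulates, at the PSD level, a resting MEG study on a
68-region cortical parcellation:

* **Connectome**: n points (default 68) placed uniformly on a 70 mm-radius
  sphere (seeded); D = pairwise Euclidean distances; C = exp(−D/λ) with
  length constant λ = 50 mm and the weakest 40% of edges removed
  symmetrically (`sparsity` = 0.6). This reproduces the one structural
  property the spatial smoother exploits — weights that decay monotonically
  with distance — with head-like length scales. Resampled (bounded) if
  thresholding isolates a node.
* **Targets**: dB PSD = model output at the ground-truth parameters plus
  i.i.d. Gaussian dB noise (default sd 2 dB — multiplicative in power, a
  minimal observation-noise model for spectra); the alpha-band profile is
  computed from the noiseless raw PSD and perturbed by lognormal noise of
  matching spread (σ_ln = sd·ln10/10). Ground truth defaults to the
  mid-point of the search box.
* **Truth parameters** at mid-bounds: τ_e = 17.5 ms, τ_i = 102.5 ms,
  τ_G = 17.5 ms, g_ee = 1.0, g_ei = 2.5, g_ii = 2.5, α = 0.55.

What this does *not* emulate: tractography statistics (streamline-count
distributions, hemispheric topology), subject-level anatomical variability,
source-leakage and leadfield effects of MEG reconstruction, or non-Gaussian
spectral estimation noise. Passing the synthetic recovery experiments
demonstrates that the inference machinery can invert the model's own
forward map under its stated noise; it does not certify fit quality on
empirical MEG.

A Welch-averaged-periodogram helper (`welch_psd`, via `scipy.signal.welch`)
converts per-region time series to a `RegionalPSD` for users starting from
real exports; it is plumbing, validated by a sinusoid peak-location test
and a white-noise flatness test only.

## Numerical choices and degenerate inputs

* Frequency grid: 2–45 Hz in 0.5 Hz steps (87 bins) by default — covers the
  alpha band and the usual resting-MEG range; configurable everywhere.
* Eigendecompositions are dense (`scipy.linalg.eig`), recomputed
  independently per frequency bin; no mode tracking across ω is attempted.
  The design envelope is N up to a few hundred regions.
* Band power integrates over the grid points inside [f_lo, f_hi]
  (trapezoid); the band must lie inside the grid and contain ≥ 2 points.
* Delimiter sniffing (comma vs tab) uses the first line; decimal points
  only. Matrix round-trips are exact to 1e−12 (17 significant digits
  written).
* Zero-variance spectra, constant spatial profiles, non-monotone frequency
  headers, NaNs, isolated nodes and dimension mismatches raise immediately
  with specific messages; infeasible parameter points inside optimization
  are penalized instead.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 10–25-region synthetic graphs with a coarse 29-bin grid;
the end-to-end experiments use the full 68-region, 87-bin configuration
with budgets of 2000 evaluations (self-fit), 800 × 3 seeds (time-constant
recovery) and 400 × 5 seeds × 3 cost modes (ablation). These sizes keep a
full run in the minutes range on a single CPU while exercising the same
code paths as a full-scale fit; all of them are configurable.

## Known limitations

* The eigenmode sum with right eigenvectors is an approximation of the
  exact resolvent at nonzero delay (see above); `direct_solve` is exact and
  costs an extra dense solve per frequency.
* The linear model cannot represent amplitude-dependent phenomena
  (saturation, cross-frequency coupling, metastable switching).
* The spatial correlation's bilinear form is heuristic smoothing, not a
  proper inner-product correlation at small w.
* Only global (homogeneous) parameters are fitted; regional heterogeneity
  is out of scope.
* Sensor-space projection and source reconstruction are out of scope; the
  model predicts parcellated source-space spectra.
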