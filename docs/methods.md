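# Methods

This note records the models implemented in `qsfilter`, the defaults and the
numerical choices, in enough detail to reproduce or audit any number the
package computes.

## 1. The smoothing filter

The estimator minimizes ‖y − x‖² + η‖Dx‖² over x, where D is the
(N−n)×N banded Toeplitz matrix whose rows carry the n-th order
backward-difference kernel (−1)ʲ C(n, j). The solution is x̂ = P⁻¹y with
P = I + ηDᵀD. For the default order n = 2 the kernel is [1, −2, 1] and P is
penta-diagonal and symmetric positive definite with every eigenvalue ≥ 1
(ηDᵀD is positive semidefinite).

Two matrix modes:

* **exact** — P = I + ηDᵀD. Used for denoising. Its two outermost rows at
  each end differ from the interior band (the difference operator loses
  support at the boundary).
* **toeplitz** — the constant band (a₀, a₁, a₂) = (1+6η, −4η, η) on every
  row, the interior coefficients of the exact form, with 5N−6 nonzeros. The
  Jordan-basis identity below holds *only* for this form, which is why
  `decompose_filter` refuses exact-mode input instead of silently returning
  a wrong reconstruction.

Parameters and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| η | smoothness trade-off (dimensionless) | N/25 | tracks sharp QRS transitions; the `balanced` (N/15) and `segment` (1.2·N) presets favour progressively smoother PQ/ST segments |
| n | difference order | 2 | penta-diagonal band; the filter response 1/(1+η(2sin ω/2)^{2n}) |
| mode | exact / toeplitz | exact | exact is the actual estimator; toeplitz feeds the circuit algebra |

Solves use `scipy.linalg.solveh_banded` on the upper banded storage; the
condition number κ = λ_max/λ_min is computed by a dense symmetric
eigensolver up to N = 4096 and by banded Lanczos iteration beyond.

## 2. Jordan-basis circuit plans and gate accounting

For the Toeplitz band, P = a₀I + a₁(J + J†) + a₂(J² + J†²) exactly, with J
the N×N superdiagonal (Jordan) matrix. J is realized recursively over
n_q = log₂N qubits:

    J_2 = l_l,      J_{2^k} = σ₀ ⊗ J_{2^{k−1}} + l_l ⊗ l_u^{⊗(k−1)},

where l_u = ½(σ₁ + iσ₂) = [[0,0],[1,0]] and l_l = ½(σ₁ − iσ₂) =
[[0,1],[0,0]]. Two conventions are fixed deliberately:

* **Ladder matrices are normative.** The worked 2×2 matrices above are taken
  as ground truth and σ₂ is set to [[0, i], [−i, 0]] so the Pauli algebra
  reproduces them. (With the other common Pauli-y sign the same combinations
  evaluate to the opposite ladders.)
* **Recursion connector.** The doubling step is stated in the source
  material as "two half-size Jordan sub-circuits plus an upper-ladder
  string" without explicit wiring; σ₀ ⊗ J_{2^{k−1}} + l_l ⊗ l_u^{⊗(k−1)} is
  the unique 1-sparse completion of the superdiagonal and is what we build.

`CircuitPlan` is a tree of {leaf, tensor, sum, scale} nodes over the 2×2
gate set, evaluable to a dense matrix and serializable to JSON. Sum and
scale nodes are *accounting devices* for a linear combination of sparse
terms — no physical LCU circuit is implemented — so gate counts count
leaves. Because tensoring with σ₀ shares a sub-circuit rather than copying
it, the tree's literal leaf count (Θ(log²N)) sits well below the structured
resource model C_g = n_q·2^{n_q}, which prices each half-block realization
separately; tests assert the leaf count is dominated by C_g.

Gate-cost models (all pinned constants; unit prefactor; base-2 logarithms):

* structured count: n_q·2^{n_q}; standard unitary count: n_q³·4^{n_q};
* sparse-standard complexity: n_q·log²(T/ε)/loglog(T/ε) with
  T = d²‖P‖_max·t, d = 5, ‖P‖_max = 1;
* banded-Toeplitz complexity: √β·log₂N·log²(β‖P‖_max t/ε)/loglog(·), β = 1.

At N = 1012, t = 0.2 s, ε = 0.01 these give 253.60 vs 88.31, a 65.2%
reduction. The absolute values depend entirely on the pinned constants (no
published constants exist for these asymptotic forms); only the *reduction
ratio* is meaningful, and it exceeds 48.84% everywhere on N ∈ [16, 4096].

## 3. Hamiltonian simulation

Ũ = Σ_{l=0}^{L−1} (−iPt)ˡ/l! approximates exp(−iPt). With x = ‖Pt‖₂ the
tail bound x^L e^x / L! certifies the spectral-norm error; `taylor_order_for`
picks the smallest L meeting a target ε_P (x = 0.2, ε_P = 0.01 → L = 3).
The operator is first rescaled to unit spectral norm and the factor recorded
so downstream eigenvalue estimates can be expressed in original units.
Matrices are dense; the quantum pipeline is exercised at N ≤ 16 and nothing
in the package needs a sparse exponential. Simulation defaults t = 0.2 s,
ε_P = 0.01.

## 4. The QPE inversion pipeline

Statevector simulation throughout; shots = 0 (exact amplitudes) is the
default and the reference path, sampling mode draws seeded multinomial
histograms.

* **Evolution-time calibration.** Eigenphases must stay in [0, 1). The
  scaled spectrum lies in (0, 1], so the per-step time is set to
  t_step = 2π·⌊0.95·T⌋/T (T = 2^{n_a}): the top eigenvalue lands exactly on
  grid bin ⌊0.95T⌋, all other phases sit below it wrap-free with 5%
  headroom. A fixed t = 0.2 s cannot simultaneously satisfy wrap-freedom
  for arbitrary spectra, so the calibrated time is what the pipeline uses
  and records (t₀ = T·t_step).
* **Controlled powers** U^{2^j} are formed by repeated squaring of the dense
  step unitary. The step unitary is the adjoint of the truncated-Taylor
  approximation of exp(−i P_s t_step), built to tolerance `unitary_tol`/T
  (default 1e−8 total) so that accumulated simulation error is negligible
  against the phase-register discretization — the error source the analysis
  module actually studies. ε_P = 0.01 remains the *modeling* parameter of
  the error budget; it is not used to degrade the simulator.
* **Conditional rotation.** Branch k of the phase register carries flag
  amplitudes (√(1 − C_m²/λ̂_k²), C_m/λ̂_k) on (|0⟩, |1⟩). The printed
  source form has an unsquared λ̂ under the root, which cannot normalize a
  two-branch state; the squared form is implemented. C_m defaults to 0.99×
  the smallest representable nonzero λ̂ (bin k = 1); the κ-based choice
  O(1/κ) is a documented alternative via the `C_m` field. The k = 0 branch
  (decoded eigenvalue 0) is routed entirely to flag |0⟩: a zero mode
  contributes postselection failure, which is the Moore–Penrose
  pseudo-inverse behaviour; an error is raised only if the flag-|1⟩
  probability vanishes altogether.
* **Uncompute and decoding.** After projecting on flag |1⟩, the inverse QPE
  (forward QFT, inverse controlled powers, Hadamard projection) disentangles
  the phase register. The unnormalized system amplitudes equal
  C_m·P⁻¹ŷ up to discretization, so the decoder multiplies by ‖y‖/C_m and
  takes the real part; output norm therefore equals ‖y‖·‖P⁻¹ŷ‖ within the
  pipeline error.
* **Idealized path.** A flag reproduces the "perfect phase concentration"
  idealization (each eigencomponent assigned wholly to its nearest bin) for
  unit tests; the default path simulates the true QPE kernel including
  leakage.

Measured behaviour (N = 8, η = N/25): median fidelity against the dense
solve is ≈0.9995 at n_a = 4 and ≥0.99999 at n_a = 8, increasing monotonically
with n_a; relative ℓ₂ error at n_a = 8 is below 1%.

## 5. Error analysis

Closed forms are implemented exactly as derived, with three reconciliations
(each kept visible in the API rather than silently patched):

* The estimated eigenvalue decomposes as λ̂ = λ_tr + λ_m + λ_ε + λ_w;
  ‖λ̂ − λ_tr‖² ≤ |ε_P|² + σ_m² + σ_w², and the overall simulation variance
  is σ_e² = |ε_P|² + σ_m² + σ_h².
* The MSE bound σ_x²(1 − 2Σ E[1/λᵢ] + Σ E[1/λᵢ²]) + σ_w² Σ E[1/λᵢ²]
  subtracts *upper bounds* on its cross terms and can therefore go negative
  (e.g. λᵢ ≡ 1, N ≥ 2); it is computed as derived and a RuntimeWarning marks
  the vacuous regime. E[·] is evaluated either as a point mass (1/λ) or via
  the moment machinery below.
* The flip-count distribution over an N_q-bit eigenvalue register is the
  normalized binomial C(N_q, k)·p_b^{N_q−k}(1 − p_b)^k, with p_b the per-bit
  success probability from the product-of-cos² readout model (normalizing
  coefficients B_j default to 1/#groups). A literal unnormalized variant is
  retained as `measurement_pmf_printed` for comparison; downstream
  expectations require the proper pmf. The measurement variance averages
  squared decimal distances over all j-bit flip patterns with weights
  p_b^{N_q−j}(1−p_b)^j, normalized by (#strings)·(2^{N_q}−1)·N_q.
* The inverse-moment integrals over the observation-noise perturbation use
  the two-term Taylor truncation of the Gaussian, exp(−x²/2σ_w²) ≈ 1 −
  x²/2σ_w², integrated on [0, u_max]; the closed forms are exact
  antiderivatives of that truncated integrand (verified to 1e−8 against
  adaptive quadrature on a 100-point grid). Since 1 − y ≤ e^{−y}, the
  truncation *under*-approximates the Gaussian integrand, with gap bounded
  by the O(u⁵) truncation error. λ_m realizations enter as i·2^{−N_q}
  (one register LSB per flip count), weighted by the flip-count pmf, with
  the 1/(σ_w√2π) prefactor applied to the whole pmf-weighted sum — the only
  reading consistent with the underlying expectation.
* The perturbed filter (P + UΣ_eU†)⁻¹y is applied through the
  eigendecomposition P = UΣUᵀ, with Σ_e indexed in ascending-eigenvalue
  order; Σ_e = εI reduces to the dense inverse of P + εI.

## 6. Synthetic ECG bench

The generator integrates the standard three-ODE dynamical ECG model (limit
cycle in (x, y), five Gaussian angular events for P, Q, R, S, T pushing z)
with fixed-step RK4 at the sampling rate, plus a cheap template mode that
evaluates the closed-form beat along the phase trajectory. Defaults: 60 bpm
with 1 bpm beat-to-beat variability, 360 Hz sampling, R amplitude normalized
to 1.1 mV, event parameters at the conventional published values. Bench
record lengths are 600 and 2351 samples. Ground-truth R-peak indices are
returned (phase zero-crossing refined to the local maximum), and every noise
generator returns (noisy, noise) with noisy = clean + noise exact.

Noise classes: AWGN at a target SNR (5–25 dB bench range), powerline
interference (50 Hz default, 60 Hz configurable), and baseline wander
(0.2 Hz sinusoid plus optional band-limited random-walk drift).

What the generator does *not* emulate: electrode-motion artefacts, muscle
noise, real inter-patient morphology variation, and recording-chain
nonlinearities. Passing the bench therefore demonstrates correctness of the
algorithms under the stated noise models, not clinical performance on
arrhythmia databases; the published MSE/PSNR improvement percentages on
hospital records depend on unspecified record and baseline configurations
and are deliberately not treated as reproduction targets — the bench checks
*orderings* (filter beats noisy input at every SNR; filter at or below EMD's
median MSE at 10 dB) instead of magnitudes.

Baselines: DWT denoising (PyWavelets; db4, 4 levels, soft universal
threshold σ̂√(2 ln N) with MAD noise estimate — conventional defaults, since
no canonical configuration is published) and a from-scratch EMD (cubic-spline
envelopes on strict interior extrema mirrored about the signal ends,
Cauchy-type SD stopping at 0.3, first IMF dropped).

## 7. Problem sizes and determinism

The quantum pipeline is exercised at N ∈ {4, 8, 16} with phase registers up
to 10 bits — the regime where dense statevector simulation is exact and
fast; the classical filter and the ECG bench run at the full record lengths
(600/2351). All stochastic steps consume explicit seeds (numpy
`default_rng`); statevector mode is fully deterministic, and identical
config + seed reproduce byte-identical CSV artifacts.

## 8. Known limitations

* No transpilation to hardware gate sets, no controlled-U decomposition, no
  device noise models: the pipeline is an exact statevector reference.
* The linear-combination structure of the Jordan decomposition is accounted,
  not compiled (no LCU/block-encoding circuit).
* The gate-complexity curves are model evaluations under pinned constants,
  meaningful only as ratios.
* Run-time (wall-clock) comparisons against classical filters are out of
  scope; the package computes gate-cost models only.
* The MSE bound is loose by construction and can be vacuous (negative) for
  well-conditioned spectra.
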