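# qsfilter — a quantum smoothing filter for biomedical signal denoising

`qsfilter` implements a quantum-circuit formulation of the classical
smoothness-prior (Whittaker-style) low-pass filter, developed for ECG
denoising, together with everything needed to study it on a laptop: the
classical filter itself, the Jordan-basis circuit construction with gate-cost
accounting, a statevector quantum-phase-estimation (QPE) eigen-inversion
pipeline, a closed-form error/uncertainty analysis, a synthetic ECG
generator, and DWT/EMD baselines.

It is intended for researchers in quantum signal processing and biomedical
engineering who want a tested, reproducible reference implementation of the
method rather than access to quantum hardware.

## The method

A noisy observation y = x + w of length N is denoised by penalized least
squares

    x̂ = argmin_x ‖y − x‖² + η ‖D x‖²  ⇒  x̂ = P⁻¹ y,  P = I + η DᵀD,

where D is the n-th order difference operator (default n = 2, kernel
[1, −2, 1]) and η > 0 trades fidelity against smoothness. P is a symmetric
positive-definite **penta-diagonal** matrix with frequency response
1 / (1 + η (2 sin ω/2)^{2n}) — a low-pass smoothing filter. The default
η = N/25 tracks the QRS complex; presets N/15 and 1.2·N trade sharpness for
segment smoothness.

The quantum formulation applies P⁻¹ by HHL-style eigenvalue inversion:

1. **amplitude encoding** of y on log₂N system qubits;
2. **Hamiltonian simulation** of exp(−iPt) by truncated Taylor series with a
   certified spectral-norm error bound;
3. **QPE** writes eigenphase estimates of P into an n_a-qubit phase register;
4. a **conditional rotation** puts amplitude C_m/λ̂ on a flag qubit, and
   postselection + inverse QPE leave the system register ∝ Σ βⱼ λ̂ⱼ⁻¹ |uⱼ⟩ =
   P⁻¹|y⟩.

Because the constant-banded (Toeplitz) form of P decomposes exactly in the
Jordan basis,

    P = a₀ I + a₁ (J + J†) + a₂ (J² + J†²),   a₀ = 1+6η, a₁ = −4η, a₂ = η,

with J the superdiagonal matrix built recursively from 2×2 ladder gates, the
structured Hamiltonian needs Θ(n_q·2^{n_q}) elementary gates versus
Θ(n_q³·4^{n_q}) for an unstructured unitary — a ≥48% gate-cost reduction at
10 qubits under the corresponding complexity models.

## Worked example

```
$ qsf synth --n-samples 600 --noise awgn:10dB --seed 7 -o noisy.csv
wrote 600 samples to noisy.csv
$ qsf denoise -i noisy.csv -o clean_qsf.csv --seed 7
denoised 600 samples (classical, eta=24) -> clean_qsf.csv
```

The first command generates a 600-sample, 360 Hz synthetic ECG (one of the
two bench lengths) and adds white Gaussian noise at 10 dB SNR; the second
solves P x̂ = y with the default η = N/25 = 24. Against the clean ground
truth this run improves PSNR from 23.40 dB (noisy) to 31.22 dB (filtered).
Add `--backend quantum-statevector --ancilla-bits 8` to run the same filter
through the simulated QPE pipeline instead (identical output to within the
phase-register resolution).

Gate-cost accounting and a small phase-estimation demo:

```
$ qsf gate-count --nqubits 10 --dim 1012
kind    name            size    value
count   structured      10      10240
count   standard        10      1.04858e+09
count   reduction_%     10      99.999
model   qhs-sparse      1012    253.596
model   qhs-structured  1012    88.3057
model   reduction_%     1012    65.1785

$ qsf qpe-demo --shots 8192 --seed 7
true minimum eigenvalue : 1.000000
estimated (bin  12, 01100) : 1.040000
histogram peak: bin 01100 with 3879 / 8192 counts
```

The `count` rows evaluate the structured (n_q·2^{n_q}) and standard
(n_q³·4^{n_q}) gate-count models and their percentage reduction; the `model`
rows evaluate the sparse-standard and banded-Toeplitz gate-complexity curves
at filter dimension 1012. The demo estimates the smallest filter eigenvalue
on a 4×4 instance with a 5-bit phase register and a sampled 8192-shot
histogram; the 1/2⁵ phase resolution explains the 0.04 offset.

Other subcommands: `qsf benchmark` (tidy CSV of MSE/PSNR for
qsf/dwt/emd across an SNR grid), `qsf error-budget` (the closed-form
uncertainty table).

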