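# piezodenoise

Denoising of throat-attached piezoelectric (PVDF) vibration signals with a
Gauss–Bernoulli deep belief network.

Flexible PVDF films taped over the thyroid cartilage convert vocal-fold
vibration into a voltage trace (Q = d·F for a film with piezoelectric
coefficient d under force F). The recordings mix the laryngeal signal with
broadband high-frequency perturbation and slow baseline drift, which
ordinary spectral filtering does not remove cleanly. This package
implements a reconstruction-based denoiser for such signals, together with
the evaluation metrics used to judge it, a convolutional comparator, and a
seeded synthetic generator of vocal-fold-like vibration for training and
benchmarking.

## Method

1. **Trajectory-matrix embedding.** The signal x₁…x_T is embedded as the
   L×K Hankel matrix X with X[i,j] = x[i+j] (K = T − L + 1); each column is
   a length-L window, z-scored to zero mean and unit variance
   (x̃ⱼ = (xⱼ − μⱼ)/σⱼ).
2. **STFT stage (optional).** Hanning-windowed short-time Fourier analysis
   X[m,k] = Σₙ x[n+mH]·w[n]·e^(−j2πkn/N) with soft per-bin magnitude
   masking against a quantile noise floor, and overlap-add inverse.
3. **DBN reconstructor.** Three stacked restricted Boltzmann machines
   (Gaussian visible units in the first layer, binary above) are
   pre-trained greedily with contrastive divergence (plain SGD), then a
   linear regression head is attached and the whole stack is fine-tuned by
   backpropagation under the joint loss
   L = λ₁·MSE(x, x̂) + λ₂·‖|X_f| − |X̂_f|‖₁ with λ₁ = 0.7, λ₂ = 0.3,
   using an Adam optimizer implemented from first principles
   (m̂_t = m_t/(1−β₁ᵗ), v̂_t = v_t/(1−β₂ᵗ),
   θ_{t+1} = θ_t − α·m̂_t/(√v̂_t + ϵ)); the learning rate starts at
   5·10⁻³ and halves at epoch 90.
4. **Diagonal averaging.** Per-window reconstructions are de-scaled and
   collapsed back to a signal by averaging anti-diagonals — the exact
   inverse of the Hankel embedding.

Quality is scored by spectral flatness (geometric/arithmetic mean of the
power spectrum), Pearson correlation ρ with the reference, local noise
energy (mean per-frame variance, frames of 100 samples), the energy ratio,
and the weighted composite

    Score = 100·[W₁·ρ + W₂·(1 − min(1, Flatness/0.1)) + W₃·(1 − min(1, LNE/0.1))]

with weights (0.4, 0.3, 0.3).

## Worked example

```python
import numpy as np
from piezodenoise import (SyntheticConfig, make_benchmark,
                          make_training_set, DBNDenoiser, evaluate, ppmcc)

cfg = SyntheticConfig()                      # 2 s at 8 kHz, f0 = 120 Hz
clean, noisy = make_benchmark(cfg)           # two-channel fused pair
noisy_w, clean_w = make_training_set(cfg, 2048, L=64)

est = DBNDenoiser(pretrain_epochs=3, random_state=0)
est.fit(noisy_w, clean_w)                    # CD pre-training + Adam
denoised = est.denoise_signal(noisy)

print(f"rho(noisy, clean)    = {ppmcc(clean, noisy):.4f}")
print(f"rho(denoised, clean) = {ppmcc(clean, denoised):.4f}")
print(evaluate(clean, denoised))
```

prints (seeded run):

```
rho(noisy, clean)    = 0.9860
rho(denoised, clean) = 0.9901
spectral_flatness = 0.000023
ppmcc = 0.990110
local_noise_energy = 1.216137
energy_ratio = 0.996208
composite_score = 69.60
```

The denoised trace correlates with the clean reference better than the raw
recording does, and its spectral flatness drops by two orders of magnitude
(the white perturbation is gone). The local-noise-energy term is saturated
for this loud benchmark — intra-frame variance is dominated by the
vibration itself — so the composite score is capped near 70 here.

The same pipeline is scriptable from a shell:

```sh
piezodenoise simulate --clean-out clean.wav --noisy-out noisy.wav
piezodenoise train --checkpoint dbn.json --log losses.tsv
piezodenoise denoise --checkpoint dbn.json --input noisy.wav --output den.wav
piezodenoise evaluate --original clean.wav --denoised den.wav
piezodenoise compare --report table.tsv   # DBN vs CNN, Table-style report
```

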