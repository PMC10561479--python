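# dmfnet

Residual denoising of chest CT and X-ray images with a 26-convolution-layer
multi-level feature-fusion network — implemented entirely in NumPy (the
convolutions, batch normalisation, backpropagation and Adam are hand-written
on top of BLAS), with a synthetic chest-phantom generator so everything is
testable without downloading data.

## Who this is for

Researchers and students working on medical-image denoising who want a
self-contained, inspectable reference implementation of a dilated
residual-learning denoiser: every layer, gradient and training detail is
plain Python/NumPy, and the architecture is available as a machine-readable
layer ledger for exact structural assertions.

## The model

Noisy images follow `Y = X + eta`, `eta ~ N(0, (sigma/255)^2)` i.i.d. per
pixel (sigma quoted on the 0–255 scale).  The network predicts the noise
field and subtracts it:

```
f(L) = f(L17) + f(L18) + f(L19)          # fused multi-level noise evidence
f(N) = NFB(tanh(f(L)))                   # refined noise estimate
I_P  = PFRB(I_noisy - f(N))              # denoised image
Loss = || I - I_P ||^2  (pixel mean)
```

The backbone (layers 1–16) is a 64-filter 3x3 stack with dilation-2 layers
at positions 2, 5 and 12 to widen the receptive field without pooling;
1-filter taps (layers 17–19) read backbone layers 14–16; after the residual
subtraction, five refinement layers (22–26) produce the output.  In total:
26 conv layers — 3 dilated, 18 non-dilated conv+BN+ReLU.  Stride is 1 and
padding equals dilation everywhere, so output size always equals input size.
Training uses Adam with a staged learning rate (1e-3 / 1e-4 / 1e-5 / 1e-6
stepping after epochs 20, 40, 50), flip/rotation augmentation, blind
(sigma uniform in [0, 55]) or specific (sigma in {15, 20, 25}) noise, and a
checkpoint per epoch.  Quality is scored with PSNR and SSIM.  See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
import numpy as np
from dmfnet import (PhantomSpec, generate_phantoms, NoiseSpec, TrainConfig,
                    train, evaluate)

imgs = generate_phantoms(80, PhantomSpec(), seed=1000)      # 128x128 phantoms
cfg = TrainConfig(epochs=5, batch_size=8, seed=0,
                  noise=NoiseSpec(mode="specific", sigma=25.0))
state = train(cfg, imgs[:64])
print([round(v, 5) for v in state.loss_history])
rep = evaluate(state.model, imgs[64:], sigmas=[25.0], seed=7)[0]
print(f"PSNR noisy {rep.psnr_noisy:.2f} -> denoised {rep.psnr_denoised:.2f} dB")
print(f"SSIM noisy {rep.ssim_noisy:.4f} -> denoised {rep.ssim_denoised:.4f}")
```

Output (one CPU, ~7 minutes):

```
[0.02091, 0.00833, 0.00656, 0.00532, 0.00442]
PSNR noisy 20.56 -> denoised 24.24 dB
SSIM noisy 0.3445 -> denoised 0.7827
```

The loss falls well below the noisy-input baseline MSE of `(25/255)^2 =
0.0096`; on 16 held-out phantoms the 5-epoch model already gains ~3.7 dB
PSNR and more than doubles SSIM relative to its sigma-25 noisy input.
(Longer schedules improve this further; the reference recipe is 60 epochs.)

The same workflows are available from the shell:

```
dmfnet synth --out data --n 80 --size 128 --seed 0
dmfnet train --data data --out run --epochs 5 --batch-size 8 \
             --noise specific --sigma 25 --seed 0
dmfnet denoise --checkpoint run/checkpoints/epoch_5.ckpt --input data --out out
dmfnet evaluate --checkpoint run/checkpoints/epoch_5.ckpt --data data \
                --sigmas 15 20 25 --seed 0 --out report.csv
```

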