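# pactdiff

Restoration of subsampled volumetric photoacoustic computed tomography
(PACT) with a deterministic two-step diffusion model, plus the synthetic
hemispherical-array acquisition pipeline needed to train and evaluate it,
and downstream functional analysis (hemoglobin unmixing, sO₂/HbT, vessel
density).

High-end volumetric PACT uses dense transducer arrays (e.g., 1024
elements) that most data-acquisition hardware cannot read out at full
frame rate. Economical acquisition keeps a subset of elements and pays in
image quality: a **sparse** subset (every 4th element, the `4i+1`
indices) covers the full aperture but produces radial streak artifacts,
while a **cluster** subset (a contiguous block `1..k`) reads out fast but
acts as a small aperture and blurs. `pactdiff` is for researchers working
on sparse-view tomographic artifact removal who need a complete,
self-contained test bed: simulate the physics, train the restorer,
quantify the result.

## The model

Restoration is learned as the reverse of a deterministic ("cold")
diffusion whose forward process interpolates between the clean slice
x₀ and its degraded counterpart x_T through a Gabor-filter operator G:

    x_t = D(x₀, x_T, t) = α_t G x₀ + (1 − α_t G) x_T,
    α_t = 0.999 · (T − t)/(T − 1),   t = 1..T   (deployed T = 2)

G is an orientation- and frequency-selective linear filter
(θ = π/4, λ = 3.3, σ = 10, ψ = 0, γ = 1 by default), applied as a
pointwise spectral mask, so the forward map inverts pointwise. Sampling
runs in two network calls per slice: a U-shaped restorer R_θ (efficient
channel attention → reduced-key/value self-attention with a selective
state-space sequence refiner, sinusoidal time embedding) predicts
x̂₀ = R_θ(x_Tᶜ, T) from a 3-slice context stack; the endpoint estimate
x̂_T = (x_t − α_t G x̂₀)/(1 − α_t G) and the renoising correction
x̂_{t−1} = x_t − D(x̂₀, x̂_T, t) + D(x̂₀, x̂_T, t−1) cancel the restorer's
own error; a second pass with a feature-wise modulated time embedding
(β, γ from a shallow network on (x̂₀, x_T)) produces the final slice.
Training sums a stage-one loss ‖x̂₀ − x₀‖, a stage-two loss after
restoring the re-degraded estimate, and a consistency loss
‖x̂_{t−1} − x_{t−1}‖.

The network, its gradients and the optimizer run on a small NumPy
reverse-mode autodiff engine included in the package (`pactdiff.nn`);
gradients are verified against finite differences in the test suite.
See `docs/methods.md` for the full account.

## Worked example

Simulate paired sparse/full reconstructions at a reduced problem size,
fit the restorer, and evaluate on held-out volumes:

```python
from pactdiff import (DiffusionRestorationModel, NetworkConfig, SimConfig,
                      SubsampleScheme, TrainConfig, make_paired_dataset)

sim = SimConfig(n_elements=256, radius=24.0, grid_shape=(6, 48, 48),
                voxel_spacing=0.2, n_branches=5)
model = DiffusionRestorationModel.from_simulation(
    n_pairs=12,
    scheme=SubsampleScheme("sparse", 64),
    sim_config=sim,
    seed=0,
    network_config=NetworkConfig(base_channels=8, n_scales=2,
                                 kv_reduction=4, emb_dim=32, seed=1),
    train_config=TrainConfig(iterations=200, input_size=32, seed=0),
)
results = model.fit()
heldout = make_paired_dataset(5, SubsampleScheme("sparse", 64), sim, seed=1000)
print(results.summary(eval_dataset=heldout))
```

```
Diffusion restoration results
==============================================
scheme                                sparse64
iterations                                 200
parameters                               15447
diffusion steps T                            2
initial total loss                     0.01973
final total loss                       0.01294
final stage-one loss                   0.00481
final stage-two loss                   0.00611
final consistency loss                 0.00203
----------------------------------------------
held-out pairs                               5
PSNR degraded (dB)                       20.81
PSNR restored (dB)                       23.07
SSIM degraded                           0.6263
SSIM restored                           0.6573
==============================================
```

Even this 200-iteration fit recovers ≈2.3 dB of the quality lost to
sparse subsampling on held-out volumes (PSNR of the degraded input vs the
restored output, both against the full-array reconstruction); the three
loss components are the stage-one, stage-two and forward-consistency
terms described above. Longer training widens the gap — the acceptance
run below trains 400 iterations and gains ≈3.7 dB on 20/20 held-out
volumes. `results.restore(volume)` applies the fitted model to any
degraded volume; `results.save(path)` writes a checkpoint.

A command-line interface covers the same pipeline for shell use:

```sh
pactdiff simulate --n-pairs 50 --scheme sparse256 --seed 0 --out data/
pactdiff train --data data/ --out model.npz
pactdiff restore --ckpt model.npz --in degraded.h5 --out restored.h5
pactdiff evaluate --pred restored.h5 --ref full.h5
pactdiff unmix --volumes w730.h5 --volumes w756.h5 --volumes w796.h5 \
               --volumes w866.h5 --out maps.h5
```

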