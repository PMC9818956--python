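# penreg

Deformable registration for double-camera livestock monitoring.

Two fixed cameras over the same pen see the animals from different
angles; fusing those views — for tracking, re-identification, behaviour
analysis — requires knowing, per pixel, where content in one view lives
in the other. `penreg` implements the full alignment pipeline:

1. **Preprocessing** — radial lens undistortion
   (x_d = x(1 + k1 r² + k2 r⁴ + k3 r⁶) on normalized coordinates), pen
   masking, grayscale conversion.
2. **Projective pre-registration** — a homography per pen, estimated by
   normalized DLT from ~35 manual landmark pairs.
3. **Deformable refinement** — a U-Net-style network T_θ(I_m, I_f) = Φ
   predicting a dense displacement field, warped through a differentiable
   spatial transformer and trained by minimizing

       L = MSE(I_f, I_m∘(id+Φ)) + λ·mean‖∇Φ‖²,

   unsupervised on many unlabeled pairs; then fine-tuned
   semi-supervisedly with a landmark term μ·(1/k)Σ‖p_f − p′‖² on a small
   annotated set (weights transferred, all layers updated, early-stopped
   on an internal validation split).
4. **Evaluation** — landmark target registration error (TRE, pixels),
   split by foreground (animal) vs background landmarks, with
   Shapiro–Wilk-gated paired t / Wilcoxon comparisons between methods.

The network, spatial transformer, losses and optimizer are implemented
in NumPy with analytic backpropagation (verified against finite
differences); no deep-learning framework is required. Because the farm
recordings are not public, the package ships a synthetic paired-view
generator with exact ground-truth geometry (`penreg.simulate`) that makes
every stage trainable and testable offline. See `docs/methods.md` for
the science and the design choices.

## Worked example

```python
from penreg import (DeformableRegistration, NetworkConfig, SceneConfig,
                    TrainConfig, generate_pairs)

train = generate_pairs(200, SceneConfig(), seed=1)       # unlabeled pairs
annotated = generate_pairs(10, SceneConfig(), seed=2)    # with landmarks
test = generate_pairs(10, SceneConfig(), seed=3)

model = DeformableRegistration(train, config=NetworkConfig.desk_scale(),
                               finetune_pairs=annotated, test_pairs=test)
res = model.fit(TrainConfig(epochs=50, seed=5))          # stage 1 (~3 min, 1 CPU)
print(res.evaluate().summary())
tuned = res.fine_tune()                                  # stage 2
print(tuned.evaluate().summary())
```

Output for these seeds:

```
TRE (euclidean, 10 pairs, 60 landmarks): overall 1.410 px, background 1.665, foreground 1.155
TRE (euclidean, 10 pairs, 60 landmarks): overall 1.410 px, background 1.665, foreground 1.155
```

Read: these test pairs start at 2.92 px mean landmark error after
simulated projective pre-registration; unsupervised training alone cuts
that to 1.41 px. The second line is identical because fine-tuning's
evidence gate kept the warm-start weights — on this draw the 10
annotated pairs showed no significant validation improvement, so no
update was adopted (see `docs/methods.md`); on draws where stage 1 is
further from its floor the fine-tuned line improves instead. The
foreground/background split shows how the deformable stage handles the
animals versus the static pen structure.

The same pipeline is scriptable from the shell:

```bash
penreg simulate --out data --seed 17 --n-train 200 --n-finetune 10 --n-test 10
penreg train    --manifest data/manifest.json --checkpoint unsup.npz --seed 1
penreg finetune --manifest data/manifest.json --checkpoint unsup.npz --out tuned.npz
penreg evaluate --checkpoint tuned.npz --manifest data/manifest.json --out report.json
penreg register --checkpoint tuned.npz --fixed data/test_0000_fixed.png \
                --moving data/test_0000_moving.png --out-overlay overlay.png
```

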