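"""Desk-scale training probe: overfit a reduced model on one phantom.

Fits a reduced configuration (embed dim 16) to a single 32^3 phantom with
the full optimization recipe (Adam, hybrid dice+focal loss with label
smoothing 0.1, gradient clipping) and reports the foreground Dice overlap,
i.e. how well the network reproduces the tumor it was fitted to.  Takes
about a minute on one CPU core.
"""

from vitunet3d.data import PhantomSpec, generate_phantom
from vitunet3d.metrics import dsc
from vitunet3d.network import ModelConfig, VitUNet3D
from vitunet3d.nn import Adam
from vitunet3d.training import TrainConfig, prepare_case, train_step

case = generate_phantom(PhantomSpec(extents=(32, 32, 32),
                                    tumor_fraction=0.05, seed=1))
model = VitUNet3D(ModelConfig.tiny(), seed=0)
tc = TrainConfig()
x, y = prepare_case(case)
opt = Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)

for step in range(1, 121):
    loss = train_step(model, opt, x[None], y[None], tc.loss,
                      tc.label_smoothing, tc.grad_clip_norm)
    if step % 20 == 0:
        pred = model.predict_labels(x[None])[0]
        fg = dsc(pred != 0, y != 0)
        print(f"step {step:3d}  hybrid loss {loss:.4f}  foreground DSC {fg:.4f}")

print("\nForeground DSC near 1 means the model reproduces the phantom's")
print("tumor mask; the loss floor is set by the 0.1 label smoothing.")
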