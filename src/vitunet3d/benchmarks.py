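"""Published benchmark figures and the arithmetic used to compare to them.

Reported BraTS-2020 comparison values for this architecture family, as
printed in the literature: per-volume/per-slice FLOPs and parameter counts
of competing segmentation models, and the per-region (TC/WT/ET) evaluation
results of the reference model.  These tables serve as *inputs* to
consistency arithmetic — relative cost reductions of a configuration we
instantiate ourselves, and row averages of printed per-region entries —
not as substitutes for anything this package computes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BASELINE_COSTS",
    "REPORTED_DSC",
    "REPORTED_HD95",
    "REPORTED_NSD",
    "REPORTED_MASD",
    "REPORTED_FOLD_AVG_DSC",
    "NNFORMER_MASD",
    "relative_reduction",
    "region_average",
]

# model -> (per-volume GFLOPs, parameters in millions) at a (128,128,128) input
BASELINE_COSTS: dict[str, tuple[float, float]] = {
    "Swin-Unet": (249.61, 27.17),
    "TransBTS": (333.07, 32.99),
    "TransUnet": (361.61, 96.07),
    "UNETR": (153.52, 92.51),
    "Swin-UNETR": (394.84, 61.98),
    "nnFormer": (421.51, 149.59),
    "mmFormer": (742.32, 106.01),
    "CoTr": (659.32, 149.61),
    "UNet-Former": (159.51, 58.96),
    "CSWin-UNet": (195.84, 85.0),
}

# reference model's reported per-region results (TC, WT, ET order)
REPORTED_DSC = {"TC": 82.49, "WT": 91.03, "ET": 80.91}        # percent
REPORTED_HD95 = {"TC": 4.65, "WT": 4.23, "ET": 5.74}          # mm
REPORTED_NSD = {"TC": 40.79, "WT": 48.21, "ET": 38.10}
REPORTED_MASD = {"TC": 0.89, "WT": 0.86, "ET": 0.92}          # mm

# per-fold average DSC (percent) of the reported four-fold cross-validation
REPORTED_FOLD_AVG_DSC = (83.09, 84.94, 84.76, 83.07)

# nnFormer per-region MASD (mm), the baseline for boundary-accuracy gains
NNFORMER_MASD = {"TC": 1.41, "WT": 2.04, "ET": 1.57}


def relative_reduction(ours: float, baseline: float) -> float:
    """Percent reduction of ``ours`` relative to ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (1.0 - ours / baseline)


def region_average(values: dict[str, float] | tuple) -> float:
    """Arithmetic mean over per-region (or per-fold) entries."""
    vals = list(values.values()) if isinstance(values, dict) else list(values)
    return float(np.mean(vals))
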