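"""Two-stage inference over an image sequence.

Each image pair is min-max normalized, classified, and routed to the
matching regressor.  Two pairing modes exist, because strain can be
reported relative to the first frame or accumulated frame-to-frame:

* ``reference`` (default): pairs are (I_1, I_t); the network output is
  the cumulative strain directly.
* ``incremental``: pairs are (I_t, I_t+1); per-step strains are composed
  into cumulative strain by multiplying stretch ratios per axis
  (1 + E_xx <- (1 + E_xx)(1 + e_xx)) and adding shear — a small-strain
  approximation of composing deformation gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import normalize_pair, regressor_input, softmax
from .training import TwoStageModel
from .types import DeformationClass, ImageSequence, StrainField

__all__ = ["SequencePrediction", "predict_pair", "predict_sequence"]

REFERENCE = "reference"
INCREMENTAL = "incremental"


@dataclass
class SequencePrediction:
    """Cumulative strain fields and classes for frames 2..T."""

    fields: list[StrainField]
    classes: list[DeformationClass]
    reference_mode: str

    def __post_init__(self) -> None:
        if len(self.fields) != len(self.classes):
            raise ValueError("one class per predicted field required")


def _pad_to_multiple(x: np.ndarray, mult: int) -> tuple[np.ndarray, tuple]:
    h, w = x.shape[1:3]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return x, (0, 0)
    x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, (ph, pw)


def predict_pair(
    models: TwoStageModel,
    frame_a: np.ndarray,
    frame_b: np.ndarray,
) -> tuple[DeformationClass, StrainField]:
    """Classify one image pair and predict its dense strain field.

    Frames are reflect-padded to the regressor's resolution multiple and
    the output cropped back, so any frame size works.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share one shape")
    clf = models.classifier
    x_cls = normalize_pair(frame_a, frame_b, clf.normalization)
    cls_shape = tuple(clf.config["input_shape"])
    if frame_a.shape != cls_shape:
        from skimage.transform import resize

        x_cls = resize(x_cls, (1,) + cls_shape + (2,), order=1,
                       anti_aliasing=True, preserve_range=True)
    probs = softmax(clf.forward(x_cls, train=False))[0]
    cls = DeformationClass.from_index(int(np.argmax(probs)))

    net = models.regressors[cls.label]
    mult = 2 ** (len(net.widths) - 1)
    x_reg = regressor_input(frame_a, frame_b, net.features)
    xp, (ph, pw) = _pad_to_multiple(x_reg, mult)
    out = net.predict_field(xp)[0]
    h, w = frame_a.shape
    out = out[:h, :w, :]
    return cls, StrainField(out[..., 0], out[..., 1], out[..., 2])


def _compose(cum: StrainField, step: StrainField) -> StrainField:
    """Accumulate one incremental step onto the cumulative strain."""
    exx = (1.0 + cum.exx) * (1.0 + step.exx) - 1.0
    eyy = (1.0 + cum.eyy) * (1.0 + step.eyy) - 1.0
    exy = cum.exy + step.exy
    return StrainField(exx, exy, eyy)


def predict_sequence(
    models: TwoStageModel,
    sequence: ImageSequence,
    reference_mode: str = REFERENCE,
) -> SequencePrediction:
    """Predict cumulative strain for every frame after the first."""
    if reference_mode not in (REFERENCE, INCREMENTAL):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    frames = sequence.frames
    fields: list[StrainField] = []
    classes: list[DeformationClass] = []
    if reference_mode == REFERENCE:
        for t in range(1, len(frames)):
            cls, fld = predict_pair(models, frames[0], frames[t])
            fields.append(fld)
            classes.append(cls)
    else:
        cum = StrainField.zeros(sequence.shape)
        for t in range(1, len(frames)):
            cls, step = predict_pair(models, frames[t - 1], frames[t])
            cum = _compose(cum, step)
            fields.append(cum)
            classes.append(cls)
    return SequencePrediction(fields, classes, reference_mode)
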