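"""The two-stage strain-estimation network.

Stage one (:class:`DeformationClassifier`) labels an image pair as
tension, compression, or rigid body motion.  Stage two routes the same
pair to one of three independent UNet-style regressors (tension /
compression / rigid), each predicting the dense strain field
(exx, exy, eyy) at input resolution.

Networks are function objects on NHWC float arrays, built on
:mod:`strainkit.nn`; initialization is reproducible from a seed and
forward passes in evaluation mode are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn import (
    BatchNorm,
    Conv3x3,
    Flatten,
    Linear,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    Upsample2,
)
from .types import CLASS_NAMES, DeformationClass, StrainField

__all__ = [
    "DeformationClassifier",
    "StrainUNet",
    "build_classifier",
    "build_regressor",
    "classify_pair",
    "softmax",
    "normalize_pair",
    "correspondence_features",
    "regressor_input",
    "FEATURE_CHANNELS",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def normalize_pair(
    frame_a: np.ndarray, frame_b: np.ndarray, method: str = "minmax"
) -> np.ndarray:
    """Per-image normalize a frame pair and stack as a (1, H, W, 2) batch.

    ``minmax`` rescales each frame to [0, 1]; ``zscore`` standardizes to
    zero mean and unit variance (more robust to the heavy-tailed
    intensity outliers of multiplicative speckle noise, and used by the
    deformation classifier).
    """
    out = np.empty((1,) + frame_a.shape + (2,))
    for k, img in enumerate((frame_a, frame_b)):
        img = np.asarray(img, dtype=float)
        if not np.all(np.isfinite(img)):
            raise ValueError("frames must be finite")
        if method == "minmax":
            span = np.ptp(img)
            out[0, :, :, k] = (img - img.min()) / (span if span > 0 else 1.0)
        elif method == "zscore":
            out[0, :, :, k] = (img - img.mean()) / (img.std() or 1.0)
        else:
            raise ValueError(f"unknown normalization {method!r}")
    return out


def _conv_block(c_in: int, c_out: int, rng: np.random.Generator) -> list:
    return [Conv3x3(c_in, c_out, rng), BatchNorm(c_out), ReLU()]


#: Integer x-shifts (px) of the regressor cost volume — covers the
#: displacement range of the default deformation model at 64 px.
COST_SHIFTS_X = (-6, -4, -3, -2, -1, 0, 1, 2, 3, 4, 6)
#: Integer y-shifts of the (smaller) transverse search.
COST_SHIFTS_Y = (-3, -2, -1, 0, 1, 2, 3)
_FEATURE_SMOOTH = 2.0

#: Channel count per regressor input representation.
FEATURE_CHANNELS = {"raw": 2, "correspondence": 2 + len(COST_SHIFTS_X) + 8}


def correspondence_features(
    frame_a: np.ndarray, frame_b: np.ndarray
) -> np.ndarray:
    """Fixed correspondence featurization of a frame pair, (H, W, C).

    Small CNNs cannot learn displacement estimation from raw pixel
    pairs at a few hundred training samples — they collapse to
    predicting the mean field.  This featurization makes the
    correspondence explicit, in the spirit of the cost volumes used by
    optical-flow networks:

    * the two min-max normalized frames,
    * a smoothed-SSD cost volume over integer longitudinal shifts,
    * soft-argmin displacement maps of the longitudinal and transverse
      cost volumes,
    * Lucas-Kanade-style linearized sub-pixel displacement estimates,
    * smoothed spatial gradients of those four displacement maps
      (direct, noisy strain estimates the network refines).

    Everything is deterministic and differentiable-free (computed once
    per pair, before the network).
    """
    x = normalize_pair(frame_a, frame_b)[0]
    a, b = x[..., 0], x[..., 1]
    xs = np.array(COST_SHIFTS_X)
    ys = np.array(COST_SHIFTS_Y)
    cost_x = np.stack([
        gaussian_filter((a - np.roll(b, -s, axis=1)) ** 2, _FEATURE_SMOOTH)
        for s in xs
    ])
    cost_y = np.stack([
        gaussian_filter((a - np.roll(b, -s, axis=0)) ** 2, _FEATURE_SMOOTH)
        for s in ys
    ])

    def soft_argmin(cost: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        w = np.exp(-cost / (cost.mean() * 0.3 + 1e-6))
        return (shifts[:, None, None] * w).sum(0) / w.sum(0)

    u_cv = soft_argmin(cost_x, xs)
    v_cv = soft_argmin(cost_y, ys)

    by, bx = np.gradient(b)
    d = b - a

    def lk(grad: np.ndarray) -> np.ndarray:
        num = gaussian_filter(d * grad, _FEATURE_SMOOTH)
        den = gaussian_filter(grad * grad, _FEATURE_SMOOTH) + 1e-3
        return np.clip(num / den, -8.0, 8.0)

    u_lk, v_lk = lk(bx), lk(by)
    chans = [a, b, *cost_x, u_cv, v_cv, u_lk, v_lk]
    for disp, axis in ((u_lk, 1), (v_lk, 0), (u_cv, 1), (v_cv, 0)):
        grad = np.gradient(gaussian_filter(disp, _FEATURE_SMOOTH), axis=axis)
        chans.append(np.clip(grad, -0.5, 0.5))
    return np.stack(chans, axis=-1)


def regressor_input(
    frame_a: np.ndarray, frame_b: np.ndarray, features: str = "correspondence"
) -> np.ndarray:
    """Build the (1, H, W, C) input batch for a strain regressor."""
    if features == "raw":
        return normalize_pair(frame_a, frame_b)
    if features == "correspondence":
        return correspondence_features(frame_a, frame_b)[None]
    raise ValueError(f"unknown feature set {features!r}")


class DeformationClassifier:
    """Conv/pool feature extractor plus a fully-connected 3-way head."""

    kind = "classifier"

    def __init__(
        self,
        input_shape: tuple[int, int] = (64, 64),
        widths: tuple[int, ...] = (8, 16, 32, 64),
        fc_width: int = 64,
        seed: int = 0,
        normalization: str = "zscore",
    ):
        depth = len(widths)
        if depth < 2:
            raise ValueError("need at least 2 convolutional stages")
        h, w = input_shape
        if h % 2**depth or w % 2**depth or min(h, w) < 2**depth:
            raise ValueError(
                f"input sides must be multiples of 2^{depth} and >= 2^{depth}"
            )
        self.config = {
            "input_shape": list(input_shape),
            "widths": list(widths),
            "fc_width": fc_width,
            "seed": seed,
            "normalization": normalization,
        }
        self.normalization = normalization
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = 2
        for c_out in widths:
            layers += _conv_block(c_in, c_out, rng)
            layers.append(MaxPool2())
            c_in = c_out
        flat = (h // 2**depth) * (w // 2**depth) * widths[-1]
        layers += [
            Flatten(),
            Linear(flat, fc_width, rng),
            ReLU(),
            Linear(fc_width, len(CLASS_NAMES), rng),
        ]
        self.net = Sequential(*layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, 3) for a (N, H, W, 2) batch."""
        if x.shape[1:3] != tuple(self.config["input_shape"]):
            raise ValueError(
                f"classifier built for {self.config['input_shape']}, "
                f"got {x.shape[1:3]}"
            )
        return self.net.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))


class StrainUNet:
    """UNet-style encoder-decoder regressing a 3-channel strain field.

    Encoder stages are double conv/BN/ReLU blocks separated by 2x2 max
    pooling; the decoder mirrors them with nearest-neighbor upsampling
    and (optionally) skip concatenations; the head is a linear 3x3
    convolution so strains may be negative.
    """

    kind = "regressor"

    def __init__(
        self,
        widths: tuple[int, ...] = (8, 16, 32, 64),
        use_skips: bool = True,
        seed: int = 0,
        features: str = "correspondence",
    ):
        if len(widths) < 2:
            raise ValueError("need at least 2 resolution levels")
        if features not in FEATURE_CHANNELS:
            raise ValueError(f"unknown feature set {features!r}")
        self.config = {
            "widths": list(widths),
            "use_skips": use_skips,
            "seed": seed,
            "features": features,
        }
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.use_skips = use_skips
        self.features = features
        levels = len(widths)

        self.enc_blocks = []
        c_in = FEATURE_CHANNELS[features]
        for c_out in widths:
            self.enc_blocks.append(
                Sequential(*_conv_block(c_in, c_out, rng),
                           *_conv_block(c_out, c_out, rng))
            )
            c_in = c_out
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.ups = [Upsample2() for _ in range(levels - 1)]
        self.dec_blocks = []
        for i in reversed(range(levels - 1)):
            c_cat = widths[i + 1] + (widths[i] if use_skips else 0)
            self.dec_blocks.append(
                Sequential(*_conv_block(c_cat, widths[i], rng),
                           *_conv_block(widths[i], widths[i], rng))
            )
        self.head = Conv3x3(widths[0], 3, rng)
        # start the output head near zero: the untrained network then
        # predicts an almost-zero field and learns strain as a residual,
        # which stabilizes regression at small dataset sizes
        self.head.w.value *= 0.01

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc_blocks + self.dec_blocks:
            out += blk.params()
        out += self.head.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, H, W, 2) -> (N, H, W, 3); sides must divide 2^(levels-1)."""
        levels = len(self.widths)
        n, h, w, _ = x.shape
        if h % 2 ** (levels - 1) or w % 2 ** (levels - 1):
            raise ValueError(
                f"input sides must be divisible by {2 ** (levels - 1)}"
            )
        skips = []
        for i in range(levels - 1):
            x = self.enc_blocks[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.enc_blocks[-1].forward(x, train)
        self._skip_channels = []
        for j, i in enumerate(reversed(range(levels - 1))):
            x = self.ups[j].forward(x, train)
            if self.use_skips:
                self._skip_channels.append((x.shape[-1], skips[i].shape[-1]))
                x = np.concatenate([x, skips[i]], axis=-1)
            x = self.dec_blocks[j].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        levels = len(self.widths)
        dout = self.head.backward(dout)
        dskips: list[np.ndarray | None] = [None] * (levels - 1)
        for j in reversed(range(levels - 1)):
            i = levels - 2 - j
            dout = self.dec_blocks[j].backward(dout)
            if self.use_skips:
                c_up, _ = self._skip_channels[j]
                dskips[i] = dout[..., c_up:]
                dout = dout[..., :c_up]
            dout = self.ups[j].backward(dout)
        dout = self.enc_blocks[-1].backward(dout)
        for i in reversed(range(levels - 1)):
            dout = self.pools[i].backward(dout)
            if dskips[i] is not None:
                dout = dout + dskips[i]
            dout = self.enc_blocks[i].backward(dout)
        return dout

    def predict_field(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_classifier(
    input_shape: tuple[int, int] = (64, 64),
    widths: tuple[int, ...] = (8, 16, 32, 64),
    fc_width: int = 64,
    seed: int = 0,
    normalization: str = "zscore",
) -> DeformationClassifier:
    return DeformationClassifier(input_shape, widths, fc_width, seed,
                                 normalization)


def build_regressor(
    widths: tuple[int, ...] = (8, 16, 32, 64),
    use_skips: bool = True,
    seed: int = 0,
    features: str = "correspondence",
) -> StrainUNet:
    return StrainUNet(widths, use_skips, seed, features)


def classify_pair(
    classifier: DeformationClassifier,
    frame_a: np.ndarray,
    frame_b: np.ndarray,
) -> DeformationClass:
    """Argmax deformation class of a pair; ties go to the lowest index."""
    x = normalize_pair(frame_a, frame_b, classifier.normalization)
    probs = classifier.predict_probs(x)[0]
    return DeformationClass.from_index(int(np.argmax(probs)))


def param_count(model) -> int:
    return int(sum(p.value.size for p in model.params()))


# ---------------------------------------------------------------------------
# checkpoints


def _batchnorms(model) -> list[BatchNorm]:
    if isinstance(model, DeformationClassifier):
        seqs = [model.net]
    else:
        seqs = model.enc_blocks + model.dec_blocks
    return [l for seq in seqs for l in seq.layers if isinstance(l, BatchNorm)]


def save_checkpoint(model, path: str | Path) -> None:
    """Write a single-file checkpoint: config header + all arrays."""
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"p{i}"] = p.value
    for i, bn in enumerate(_batchnorms(model)):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    header = {"format": "strainkit-checkpoint-1", "kind": model.kind,
              "config": model.config}
    np.savez_compressed(path, header=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path, allow_pickle=False) as data:
        try:
            header = json.loads(str(data["header"]))
        except KeyError as exc:
            raise ValueError(f"{path}: not a strainkit checkpoint") from exc
        if header.get("format") != "strainkit-checkpoint-1":
            raise ValueError(f"{path}: unsupported checkpoint format")
        cfg = header["config"]
        if header["kind"] == "classifier":
            model = DeformationClassifier(
                tuple(cfg["input_shape"]), tuple(cfg["widths"]),
                cfg["fc_width"], cfg["seed"],
                cfg.get("normalization", "zscore"),
            )
        else:
            model = StrainUNet(tuple(cfg["widths"]), cfg["use_skips"],
                               cfg["seed"], cfg.get("features", "raw"))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean[...] = data[f"rm{i}"]
            bn.running_var[...] = data[f"rv{i}"]
    return model
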