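"""Synthetic speckle-image generation with exact ground-truth strain.

This module builds the training and benchmark data for the two-stage
strain-estimation network: procedurally generated ultrasound-like speckle
substrates, a prescribed tendon strain model (depth-graded longitudinal
strain with in-plane incompressibility), displacement integration, exact
inverse-map image warping, and an ultrasound-like noise model.

The deformation model encodes two observations about tendon under load:
the longitudinal strain in the superficial layer is a fixed fraction
(default 75%) of that in the deep layer, and the tissue deforms
incompressibly in-plane, coupling the transverse strain to the
longitudinal one via (1 + exx)(1 + eyy) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .types import (
    COMPRESSION,
    RIGID,
    TENSION,
    DeformationClass,
    DisplacementField,
    ImageSequence,
    LoadProtocol,
    StrainField,
    SyntheticSample,
    TendonGeometry,
    TestCase,
)

__all__ = [
    "SpeckleParams",
    "NoiseParams",
    "DeformationRanges",
    "generate_speckle_image",
    "default_geometry",
    "temporal_profile",
    "build_strain_field",
    "strain_to_displacement",
    "strain_of_displacement",
    "make_ground_truth",
    "warp_image",
    "add_noise",
    "generate_training_set",
    "generate_test_cases",
    "DEFAULT_LEVELS",
]

#: Benchmark peak deep-layer longitudinal strains: 4% .. 16%.
DEFAULT_LEVELS: tuple[float, ...] = (0.04, 0.07, 0.10, 0.13, 0.16)


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the procedural speckle substrate.

    The substrate stands in for a real B-mode frame: band-limited
    Gaussian speckle texture (autocorrelation length set by
    ``grain_sigma``) plus a brighter horizontal band emulating the
    hyperechoic tendon.
    """

    grain_sigma: float = 1.5
    base_level: float = 0.45
    contrast: float = 0.13
    band_center_frac: float = 0.5
    band_halfwidth_frac: float = 0.15
    band_gain: float = 0.35


@dataclass(frozen=True)
class NoiseParams:
    """Uniform sampling ranges for the ultrasound-like noise components.

    Each range is (low, high); the strength of every component is drawn
    uniformly from its range at application time, so a dataset spans a
    spread of noise severities.  Components, applied in order:

    * ``speckle_var`` — variance of a unit-mean gamma multiplicative
      factor (models speckle decorrelation),
    * ``additive_sigma`` — std of additive Gaussian noise (sensor noise),
    * ``gain`` / ``offset`` — global intensity jitter between frames.
    """

    speckle_var: tuple[float, float] = (0.0, 0.08)
    additive_sigma: tuple[float, float] = (0.0, 0.04)
    gain: tuple[float, float] = (0.9, 1.1)
    offset: tuple[float, float] = (-0.03, 0.03)

    def __post_init__(self) -> None:
        for name in ("speckle_var", "additive_sigma", "gain", "offset"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low > high")
        if self.speckle_var[0] < 0 or self.additive_sigma[0] < 0:
            raise ValueError("variance-like parameters must be >= 0")

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free configuration (identity transform)."""
        return cls((0.0, 0.0), (0.0, 0.0), (1.0, 1.0), (0.0, 0.0))

    def scaled(self, factor: float) -> "NoiseParams":
        """Shrink every component's range about its neutral value."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        return NoiseParams(
            speckle_var=(self.speckle_var[0] * factor, self.speckle_var[1] * factor),
            additive_sigma=(
                self.additive_sigma[0] * factor,
                self.additive_sigma[1] * factor,
            ),
            gain=(
                1.0 + (self.gain[0] - 1.0) * factor,
                1.0 + (self.gain[1] - 1.0) * factor,
            ),
            offset=(self.offset[0] * factor, self.offset[1] * factor),
        )


@dataclass(frozen=True)
class DeformationRanges:
    """Per-class sampling ranges for the training-set generator.

    ``tension`` and ``compression`` give (min, max) magnitudes of the
    deep-layer longitudinal strain; ``rigid_shift`` bounds the uniform
    per-axis translation (pixels) of the rigid class.  The lower strain
    magnitude bound keeps the classes geometrically separable at the
    image resolutions used here.
    """

    tension: tuple[float, float] = (0.02, 0.20)
    compression: tuple[float, float] = (0.02, 0.20)
    rigid_shift: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tension", "compression"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name}: need 0 <= min < max")
        if self.rigid_shift <= 0:
            raise ValueError("rigid_shift must be positive")


# ---------------------------------------------------------------------------
# speckle substrate


def generate_speckle_image(
    height: int,
    width: int,
    speckle_params: SpeckleParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Generate a reproducible ultrasound-like speckle substrate in [0, 1]."""
    if height < 32 or width < 32:
        raise ValueError("image sides must be at least 32 px")
    p = speckle_params or SpeckleParams()
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.normal(size=(height, width)), p.grain_sigma)
    tex /= tex.std()
    rows = np.arange(height)[:, None]
    center = p.band_center_frac * (height - 1)
    halfwidth = max(p.band_halfwidth_frac * height, 1.0)
    band = np.where(
        np.abs(rows - center) < halfwidth,
        0.5 * (1.0 + np.cos(np.pi * (rows - center) / halfwidth)),
        0.0,
    )
    img = p.base_level + p.contrast * tex + p.band_gain * band
    return np.clip(img, 0.0, 1.0)


def default_geometry(
    shape: tuple[int, int],
    band_center_frac: float = 0.5,
    band_halfwidth_frac: float = 0.15,
    superficial_ratio: float = 0.75,
) -> TendonGeometry:
    """Tendon geometry matching the bright band of the default substrate."""
    height, width = shape
    rows = np.arange(height)[:, None]
    center = band_center_frac * (height - 1)
    halfwidth = max(band_halfwidth_frac * height, 1.0)
    mask = np.broadcast_to(np.abs(rows - center) < halfwidth, (height, width))
    return TendonGeometry(mask.copy(), superficial_ratio=superficial_ratio)


# ---------------------------------------------------------------------------
# deformation model


def temporal_profile(t: float, protocol: LoadProtocol = LoadProtocol()) -> float:
    """Normalized load level at time ``t`` of a ramp-hold-relax cycle.

    Rises linearly to 1 over the ramp, holds, falls linearly back to 0
    over the relaxation, and stays 0 afterwards.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    r, h, x = protocol.ramp_s, protocol.hold_s, protocol.relax_s
    if t <= r:
        return t / r
    if t <= r + h:
        return 1.0
    if t <= r + h + x:
        return (r + h + x - t) / x
    return 0.0


def build_strain_field(
    eps_deep: float,
    geometry: TendonGeometry,
    margin_frac: float = 0.1,
) -> StrainField:
    """Prescribe the tendon strain field for a deep-layer strain ``eps_deep``.

    Longitudinal strain exx ramps linearly across the tendon thickness
    from ``superficial_ratio * eps_deep`` at the superficial edge to
    ``eps_deep`` at the deep edge, is constant along the tendon, and
    decays to zero with a raised-cosine taper over ``margin_frac`` of the
    image height outside the tendon.  Transverse strain follows in-plane
    incompressibility, eyy = 1/(1 + exx) - 1, and the prescribed shear is
    zero.
    """
    if abs(eps_deep) >= 0.5:
        raise ValueError("|eps_deep| must be < 0.5")
    mask = geometry.tendon_mask
    if geometry.depth_axis == 1:
        mask = mask.T
    height, width = mask.shape
    r0, r1 = TendonGeometry(mask).depth_extent
    ratio = geometry.superficial_ratio
    rows = np.arange(height, dtype=float)

    depth_profile = np.empty(height)
    inside = (rows >= r0) & (rows <= r1)
    frac = (rows - r0) / max(r1 - r0, 1)
    depth_profile[inside] = ratio + (1.0 - ratio) * frac[inside]
    margin = max(margin_frac * height, 1.0)

    def taper(d: np.ndarray) -> np.ndarray:
        w = np.clip(d / margin, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * w))

    above = rows < r0
    depth_profile[above] = ratio * taper(r0 - rows[above])
    below = rows > r1
    depth_profile[below] = taper(rows[below] - r1)

    exx = np.tile((eps_deep * depth_profile)[:, None], (1, width))
    eyy = 1.0 / (1.0 + exx) - 1.0
    fld = StrainField(exx, np.zeros_like(exx), eyy)
    if geometry.depth_axis == 1:
        fld = StrainField(fld.exx.T, fld.exy.T, fld.eyy.T)
    return fld


def strain_to_displacement(
    field: StrainField, anchor: tuple[int, int] | None = None
) -> DisplacementField:
    """Integrate a strain field into a displacement field.

    ``u`` is the cumulative trapezoidal integral of exx along the
    longitudinal axis from the anchor column, ``v`` the integral of eyy
    along depth from the anchor row; both vanish at the anchor (default:
    image center).
    """
    if not field.valid_mask.all():
        raise ValueError("strain field must be valid everywhere")
    h, w = field.shape
    if anchor is None:
        anchor = (h // 2, w // 2)
    ar, ac = anchor
    if not (0 <= ar < h and 0 <= ac < w):
        raise ValueError("anchor outside the image")
    u = cumulative_trapezoid(field.exx, axis=1, dx=1.0, initial=0.0)
    u -= u[:, ac][:, None]
    v = cumulative_trapezoid(field.eyy, axis=0, dx=1.0, initial=0.0)
    v -= v[ar, :][None, :]
    return DisplacementField(u, v)


def strain_of_displacement(disp: DisplacementField) -> StrainField:
    """Small-strain tensor of a displacement field by central differences."""
    dudy, dudx = np.gradient(disp.u)
    dvdy, dvdx = np.gradient(disp.v)
    return StrainField(dudx, 0.5 * (dudy + dvdx), dvdy)


def make_ground_truth(
    eps_deep: float,
    geometry: TendonGeometry,
    margin_frac: float = 0.1,
    anchor: tuple[int, int] | None = None,
) -> tuple[StrainField, DisplacementField]:
    """Prescribed field plus the shear its displacement actually induces.

    A depth-graded exx cannot coexist with exactly zero shear: the
    integrated u varies with depth, so the warped image carries
    exy = (1/2) du/dy.  The returned truth keeps the closed-form exx and
    eyy (preserving the superficial/deep ratio and incompressibility
    exactly) and stores that induced shear, making the truth kinematically
    consistent with the displacement used for warping.
    """
    prescribed = build_strain_field(eps_deep, geometry, margin_frac)
    disp = strain_to_displacement(prescribed, anchor)
    dudy = np.gradient(disp.u, axis=0)
    dvdx = np.gradient(disp.v, axis=1)
    truth = StrainField(prescribed.exx, 0.5 * (dudy + dvdx), prescribed.eyy)
    return truth, disp


# ---------------------------------------------------------------------------
# warping and noise


def warp_image(
    image: np.ndarray,
    disp: DisplacementField,
    interpolation: str = "bicubic",
    inversion_iters: int = 12,
) -> np.ndarray:
    """Apply a reference-frame displacement field to an image.

    ``disp`` gives the motion of material points of ``image``: the point
    at reference position X lands at X + (u, v)(X).  The warp is realized
    backwards — for every output pixel x the reference position is found
    by fixed-point inversion of X + u(X) = x — so the deformation of the
    output matches the prescribed field to interpolation accuracy even at
    large strains.  Out-of-domain samples replicate the nearest edge.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != disp.shape:
        raise ValueError("image and displacement shapes differ")
    order = {"bicubic": 3, "bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if np.ptp(disp.u) < 1e-15 and np.ptp(disp.v) < 1e-15:
        # uniform translation: the inverse map is exact in one step
        xs, ys = xx - disp.u.flat[0], yy - disp.v.flat[0]
    else:
        xs, ys = xx - disp.u, yy - disp.v
        for _ in range(inversion_iters):
            us = ndimage.map_coordinates(disp.u, [ys, xs], order=1, mode="nearest")
            vs = ndimage.map_coordinates(disp.v, [ys, xs], order=1, mode="nearest")
            xs, ys = xx - us, yy - vs
    warped = ndimage.map_coordinates(image, [ys, xs], order=order, mode="nearest")
    return warped


def add_noise(
    image: np.ndarray,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    return_record: bool = False,
):
    """Corrupt an image with ultrasound-like noise, reproducibly.

    Component strengths are drawn uniformly from the ranges in
    ``noise_params`` (see :class:`NoiseParams`); the result is clipped to
    [0, 1].  With ``return_record`` the sampled strengths are returned
    alongside the image.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("input image must lie in [0, 1]")
    p = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)
    var = rng.uniform(*p.speckle_var)
    sigma = rng.uniform(*p.additive_sigma)
    gain = rng.uniform(*p.gain)
    offset = rng.uniform(*p.offset)

    out = image
    if var > 0:
        out = out * rng.gamma(shape=1.0 / var, scale=var, size=image.shape)
    if sigma > 0:
        out = out + rng.normal(scale=sigma, size=image.shape)
    out = gain * out + offset
    out = np.clip(out, 0.0, 1.0)
    if return_record:
        return out, {"speckle_var": var, "additive_sigma": sigma,
                     "gain": gain, "offset": offset}
    return out


# ---------------------------------------------------------------------------
# dataset assembly


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _rigid_truth_and_disp(
    shape: tuple[int, int], shift: tuple[float, float]
) -> tuple[StrainField, DisplacementField]:
    u = np.full(shape, shift[0])
    v = np.full(shape, shift[1])
    return StrainField.zeros(shape), DisplacementField(u, v)


def generate_training_set(
    n_pairs: int = 3750,
    class_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    deformation_ranges: DeformationRanges | None = None,
    noise_ranges: NoiseParams | None = None,
    seed: int = 0,
    image_shape: tuple[int, int] = (64, 64),
    geometry: TendonGeometry | None = None,
    speckle_params: SpeckleParams | None = None,
) -> list[SyntheticSample]:
    """Draw a seeded training set of image pairs with exact ground truth.

    Each sample: draw a class from ``class_mix``; for tension and
    compression draw the deep-layer strain magnitude uniformly from its
    range, build the tendon field, and warp a fresh speckle substrate;
    for the rigid class apply a uniform subpixel translation.  Both
    frames then receive independent noise.
    """
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 3 nonnegative proportions summing to 1")
    ranges = deformation_ranges or DeformationRanges()
    noise = noise_ranges if noise_ranges is not None else NoiseParams()
    geometry = geometry or default_geometry(image_shape)

    master = np.random.default_rng(seed)
    labels = master.choice(3, size=n_pairs, p=mix)
    children = np.random.SeedSequence(seed).spawn(n_pairs)

    samples: list[SyntheticSample] = []
    for i in range(n_pairs):
        ss = children[i]
        s_speckle, s_eps, s_noise_a, s_noise_b = (_seed_of(c) for c in ss.spawn(4))
        rng = np.random.default_rng(s_eps)
        cls = DeformationClass.from_index(int(labels[i]))
        substrate = generate_speckle_image(
            *image_shape, speckle_params, seed=s_speckle
        )
        params: dict = {"class": cls.label}
        if cls == RIGID:
            shift = tuple(rng.uniform(-ranges.rigid_shift, ranges.rigid_shift, 2))
            truth, disp = _rigid_truth_and_disp(image_shape, shift)
            params["shift_px"] = shift
        else:
            lo, hi = ranges.tension if cls == TENSION else ranges.compression
            eps = rng.uniform(lo, hi)
            if cls == COMPRESSION:
                eps = -eps
            truth, disp = make_ground_truth(eps, geometry)
            params["eps_deep"] = eps
        # bicubic interpolation can overshoot the [0, 1] intensity range
        warped = np.clip(warp_image(substrate, disp), 0.0, 1.0)
        ref, rec_a = add_noise(substrate, noise, seed=s_noise_a, return_record=True)
        deformed, rec_b = add_noise(warped, noise, seed=s_noise_b, return_record=True)
        params["noise_ref"], params["noise_def"] = rec_a, rec_b
        samples.append(
            SyntheticSample(ref, deformed, truth, cls, params, seed=_seed_of(ss))
        )
    return samples


def generate_test_cases(
    levels: Sequence[float] = DEFAULT_LEVELS,
    protocol: LoadProtocol = LoadProtocol(),
    fps: float = 2.0,
    seed: int = 0,
    noise_ranges: NoiseParams | None = None,
    image_shape: tuple[int, int] = (64, 64),
    geometry: TendonGeometry | None = None,
    speckle_params: SpeckleParams | None = None,
    pixel_spacing: float = 0.1,
) -> list[TestCase]:
    """Build one benchmark sequence per peak-strain level.

    The frame at time t carries a deep-layer strain of
    ``level * temporal_profile(t)``; ground truth is stored per frame
    relative to the first frame, before noise is applied.
    """
    if len(levels) == 0:
        raise ValueError("levels must be non-empty")
    for lv in levels:
        if not 0.0 < lv < 0.5:
            raise ValueError(f"level {lv} outside (0, 0.5)")
    noise = noise_ranges if noise_ranges is not None else NoiseParams()
    geometry = geometry or default_geometry(image_shape)
    children = np.random.SeedSequence(seed).spawn(len(levels))

    cases: list[TestCase] = []
    n_frames = int(round(protocol.duration * fps)) + 1
    times = np.arange(n_frames) / fps
    for level, ss in zip(levels, children):
        s_speckle, *frame_seeds = (_seed_of(c) for c in ss.spawn(n_frames + 1))
        substrate = generate_speckle_image(*image_shape, speckle_params, seed=s_speckle)
        frames, truths = [], []
        for k, t in enumerate(times):
            eps = level * temporal_profile(float(t), protocol)
            if eps == 0.0:
                warped = substrate
                truth = StrainField.zeros(image_shape)
            else:
                truth, disp = make_ground_truth(eps, geometry)
                warped = np.clip(warp_image(substrate, disp), 0.0, 1.0)
            frames.append(add_noise(warped, noise, seed=frame_seeds[k]))
            if k > 0:
                truths.append(truth)
        seq = ImageSequence(frames, pixel_spacing=pixel_spacing,
                            frame_interval=1.0 / fps)
        cases.append(TestCase(seq, truths, eps_long_max=float(level),
                              protocol=protocol))
    return cases
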