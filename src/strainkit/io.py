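"""Readers and writers shared by the CLI and the library.

Conventions: grayscale float frames in [0, 1] (integer images are
rescaled by their dtype maximum; RGB collapses to luminance), natural
sort of frame file names, 16-bit TIFF for written frames, and a
compressed ``.npz`` multi-array container with an embedded JSON manifest
for strain fields.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import ImageSequence, StrainField

__all__ = [
    "natural_sort_key",
    "to_grayscale",
    "read_image_stack",
    "write_image_stack",
    "write_strain_container",
    "read_strain_container",
]

#: Rec. 601 luminance weights for RGB -> grayscale conversion.
LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


def natural_sort_key(name: str):
    """Sort key treating digit runs numerically: frame2 < frame10."""
    return [int(s) if s.isdigit() else s.lower()
            for s in re.split(r"(\d+)", name)]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Any loaded image -> float grayscale in [0, 1]."""
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3] @ LUMA
    if img.ndim != 2:
        raise ValueError(f"cannot interpret image of shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = img.astype(float)
    return img


def read_image_stack(
    path: str | Path,
    pixel_spacing: float | None = None,
    frame_interval: float | None = None,
) -> ImageSequence:
    """Load a directory of TIFF/PNG frames (or one multi-page TIFF).

    Frames are natural-sorted by file name.  Pixel spacing and frame
    interval come from a ``metadata.json`` sidecar when present; explicit
    arguments override it.
    """
    path = Path(path)
    meta: dict = {}
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in _FRAME_SUFFIXES),
            key=lambda f: natural_sort_key(f.name),
        )
        if not files:
            raise ValueError(f"{path}: no TIFF/PNG frames found")
        frames = [to_grayscale(iio.imread(f)) for f in files]
        sidecar = path / "metadata.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            offenders = [
                f"{fl.name}: {fr.shape}" for fl, fr in zip(files, frames)
            ]
            raise ValueError("mixed frame shapes: " + "; ".join(offenders))
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [to_grayscale(fr) for fr in stack]
    return ImageSequence(
        frames,
        pixel_spacing=pixel_spacing or meta.get("pixel_spacing_mm", 1.0),
        frame_interval=frame_interval or meta.get("frame_interval_s", 1.0),
    )


def write_image_stack(sequence: ImageSequence, path: str | Path) -> None:
    """Write frames as 16-bit grayscale TIFFs plus a metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    digits = len(str(len(sequence) - 1))
    for i, frame in enumerate(sequence.frames):
        data = np.round(np.clip(frame, 0, 1) * 65535).astype(np.uint16)
        tifffile.imwrite(path / f"frame{i:0{digits}d}.tif", data)
    (path / "metadata.json").write_text(json.dumps({
        "pixel_spacing_mm": sequence.pixel_spacing,
        "frame_interval_s": sequence.frame_interval,
        "n_frames": len(sequence),
    }, indent=2))


def write_strain_container(
    fields: Sequence[StrainField],
    manifest: dict,
    path: str | Path,
    overwrite: bool = False,
) -> None:
    """Write strain fields to a compressed multi-array container.

    Arrays ``exx<i>/exy<i>/eyy<i>/mask<i>`` per frame plus a JSON
    manifest (shape, frame count, and caller-provided entries such as
    reference mode and seed).  Read-back is lossless.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    arrays = {}
    for i, f in enumerate(fields):
        for comp in ("exx", "exy", "eyy"):
            if not np.all(np.isfinite(getattr(f, comp)[f.valid_mask])):
                raise ValueError(f"frame {i}: non-finite strain values")
        arrays[f"exx{i}"] = f.exx
        arrays[f"exy{i}"] = f.exy
        arrays[f"eyy{i}"] = f.eyy
        arrays[f"mask{i}"] = f.valid_mask
    full = {
        "format": "strainkit-fields-1",
        "n_fields": len(fields),
        "shape": list(fields[0].shape) if fields else None,
        **manifest,
    }
    np.savez_compressed(path, manifest=json.dumps(full), **arrays)


def read_strain_container(
    path: str | Path,
) -> tuple[list[StrainField], dict]:
    """Inverse of :func:`write_strain_container`."""
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:
        raise ValueError(f"{path}: not a strainkit field container "
                         f"({exc})") from exc
    with data:
        try:
            manifest = json.loads(str(data["manifest"]))
            fields = [
                StrainField(
                    data[f"exx{i}"], data[f"exy{i}"], data[f"eyy{i}"],
                    data[f"mask{i}"],
                )
                for i in range(manifest.get("n_fields", 0))
            ]
        except KeyError as exc:
            raise ValueError(f"{path}: not a strainkit field container "
                             f"(missing {exc})") from exc
        if manifest.get("format") != "strainkit-fields-1":
            raise ValueError(f"{path}: unsupported container format")
    return fields, manifest
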