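"""Image and batch I/O.

Images travel as 8- or 16-bit grayscale PNG/TIFF; pixel intensities are
real-valued throughout the pipeline and quantised only here, at export.
The on-disk orientation stores the lateral axis as the first dimension
(L x D), i.e. one row per beamline.  Batches go into NPZ archives that
keep the acquired-line masks and the declared value range alongside the
pixel tensor.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import USImage

__all__ = ["read_image", "write_image", "save_batch", "load_batch", "write_video_frames"]


def read_image(path: str | Path, district_tag: str = "") -> USImage:
    """Read a grayscale PNG/TIFF into a normalised USImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) grayscale image
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        pix = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        pix = arr.astype(float) / 65535.0
    else:
        pix = np.clip(arr.astype(float), 0.0, 1.0)
    return USImage(pixels=pix, value_range=(0.0, 1.0), district_tag=district_tag)


def write_image(img: USImage, path: str | Path, bitdepth: int = 8) -> None:
    """Quantise to 8 or 16 bits and write PNG/TIFF (suffix decides)."""
    if bitdepth not in (8, 16):
        raise ValueError("bitdepth must be 8 or 16")
    norm = img.to_normalised().pixels
    peak = 255 if bitdepth == 8 else 65535
    arr = np.round(norm * peak).astype(np.uint8 if bitdepth == 8 else np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def save_batch(images: Sequence[USImage], path: str | Path) -> None:
    """Lossless NPZ archive of same-shaped images plus their metadata."""
    images = list(images)
    if not images:
        raise ValueError("empty batch")
    shape = images[0].pixels.shape
    for im in images:
        if im.pixels.shape != shape:
            raise ValueError("all images in a batch must share dimensions")
    np.savez_compressed(
        path,
        pixels=np.stack([im.pixels for im in images]),
        acquired_mask=np.stack([im.acquired_mask for im in images]),
        value_range=np.array(images[0].value_range),
        district_tags=np.array([im.district_tag for im in images]),
    )


def load_batch(path: str | Path) -> List[USImage]:
    with np.load(path, allow_pickle=False) as data:
        vr = tuple(float(v) for v in data["value_range"])
        tags = [str(t) for t in data["district_tags"]]
        return [
            USImage(pixels=data["pixels"][i], value_range=vr,
                    acquired_mask=data["acquired_mask"][i], district_tag=tags[i])
            for i in range(data["pixels"].shape[0])
        ]


def write_video_frames(frames: Sequence[USImage], out_dir: str | Path,
                       bitdepth: int = 8, fmt: str = "png") -> List[Path]:
    """Write an ordered frame stack as numbered images in a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, f in enumerate(frames):
        p = out_dir / f"frame_{t:04d}.{fmt}"
        write_image(f, p, bitdepth=bitdepth)
        paths.append(p)
    return paths
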