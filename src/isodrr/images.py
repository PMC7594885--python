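"""8-bit grayscale DRR images and their on-disk formats (PNG / PGM).

Pixel pitch (and any window/level used) travels with the image: in a PNG
text chunk, or in comment lines of a binary PGM header.  Both formats
round-trip pixels losslessly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo


@dataclass
class DRRImage:
    """Rendered radiograph: 8-bit pixels plus geometry/display provenance.

    ``pixels[row, col]`` with row along the detector v axis and col along
    u.  ``integral`` optionally keeps the un-windowed line-integral map
    (code-integral units); it is not serialised.
    """

    pixels: np.ndarray
    pitch_mm: float
    metadata: dict = field(default_factory=dict)
    integral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be a 2-D uint8 array")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def pixel_to_mm(self, col: float, row: float) -> tuple[float, float]:
        """Detector (u, v) mm coordinates of a (fractional) pixel centre."""
        n_v, n_u = self.pixels.shape
        return (
            (col - (n_u - 1) / 2.0) * self.pitch_mm,
            (row - (n_v - 1) / 2.0) * self.pitch_mm,
        )


def _float_metadata(img: DRRImage) -> dict[str, str]:
    meta = {"pitch_mm": f"{img.pitch_mm:.9g}"}
    for key in ("window", "level"):
        if key in img.metadata and img.metadata[key] is not None:
            meta[key] = f"{float(img.metadata[key]):.9g}"
    return meta


def write_image(img: DRRImage, path: str | Path) -> Path:
    """Write an 8-bit grayscale image as PNG (default) or binary PGM."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        n_v, n_u = img.pixels.shape
        comments = "".join(f"# {k}={v}\n" for k, v in _float_metadata(img).items())
        with open(path, "wb") as fh:
            fh.write(f"P5\n{comments}{n_u} {n_v}\n255\n".encode("ascii"))
            fh.write(np.ascontiguousarray(img.pixels).tobytes())
    elif path.suffix.lower() == ".png":
        info = PngInfo()
        for k, v in _float_metadata(img).items():
            info.add_text(k, v)
        Image.fromarray(img.pixels, mode="L").save(path, pnginfo=info)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r} (use .png or .pgm)")
    return path


def read_image(path: str | Path) -> DRRImage:
    """Read a PNG/PGM written by :func:`write_image`, recovering the pitch."""
    path = Path(path)
    meta: dict[str, float] = {}
    if path.suffix.lower() == ".pgm":
        head = path.read_bytes()[:4096]
        for m in re.finditer(rb"#\s*(\w+)=([-+0-9.eE]+)", head):
            meta[m.group(1).decode()] = float(m.group(2))
    with Image.open(path) as im:
        if path.suffix.lower() == ".png":
            for k in ("pitch_mm", "window", "level"):
                if k in im.info:
                    meta[k] = float(im.info[k])
        pixels = np.asarray(im.convert("L"), dtype=np.uint8)
    pitch = meta.pop("pitch_mm", None)
    if pitch is None:
        raise ValueError(f"{path}: no pitch_mm metadata found")
    return DRRImage(pixels=pixels, pitch_mm=pitch, metadata=meta)
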