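"""Multi-channel image container and TIFF/JSON round-trip.

A :class:`MultiChannelImage` holds co-registered 2D intensity planes keyed by
channel role ("dna", "tubulin", "phh3", "gamma_tubulin", "cep215", "actin")
together with the physical pixel size in micrometres.  Images are written as
one multi-page TIFF per well (page order = channel order) with a JSON sidecar
naming the channel roles and the pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: channel roles for the two screen configurations
CHANNEL_SETS: dict[str, tuple[str, ...]] = {
    "screenA": ("dna", "tubulin", "cep215", "actin"),
    "screenB": ("dna", "tubulin", "phh3", "gamma_tubulin"),
}


@dataclass
class MultiChannelImage:
    planes: dict[str, np.ndarray]
    pixel_size_um: float
    channel_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("image needs at least one channel plane")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel planes differ in shape: {shapes}")
        if not self.channel_order:
            self.channel_order = tuple(self.planes)
        for role, plane in self.planes.items():
            if not np.all(np.isfinite(plane)):
                raise ValueError(f"non-finite intensities in channel {role!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.planes[role]

    def __contains__(self, role: str) -> bool:
        return role in self.planes

    def scale(self, role: str, factor: float) -> "MultiChannelImage":
        """Return a copy with one channel multiplied by ``factor``."""
        planes = {r: (p * factor if r == role else p.copy()) for r, p in self.planes.items()}
        return MultiChannelImage(planes, self.pixel_size_um, self.channel_order)

    # ------------------------------------------------------------------ IO
    def save(self, tiff_path: str | Path, meta_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        stack = np.stack([self.planes[r] for r in self.channel_order]).astype(np.float32)
        tifffile.imwrite(tiff_path, stack)
        if meta_path is None:
            meta_path = tiff_path.with_suffix(".json")
        meta = {"channels": list(self.channel_order), "pixel_size_um": self.pixel_size_um}
        Path(meta_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, tiff_path: str | Path, meta_path: str | Path | None = None) -> "MultiChannelImage":
        tiff_path = Path(tiff_path)
        if meta_path is None:
            meta_path = tiff_path.with_suffix(".json")
        meta = json.loads(Path(meta_path).read_text())
        stack = tifffile.imread(tiff_path)
        if stack.ndim == 2:
            stack = stack[None]
        planes = {role: np.asarray(stack[i], dtype=np.float32)
                  for i, role in enumerate(meta["channels"])}
        return cls(planes, float(meta["pixel_size_um"]), tuple(meta["channels"]))
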