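"""The in-memory particle-image container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def disk_mask(L: int) -> np.ndarray:
    """Boolean mask of the inscribed unit disk on the L x L pixel grid."""
    c = L // 2
    t = (np.arange(L) - c) * (2.0 / L)
    return np.hypot(t[None, :], t[:, None]) <= 1.0


@dataclass
class ImageStack:
    """A stack of N square real images with physical pixel size.

    ``group_ids`` optionally assigns each image to a defocus group.
    """

    data: np.ndarray                  # (N, L, L) float
    pixel_size_A: float = 1.0
    group_ids: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[-1] != self.data.shape[-2]:
            raise ValueError("images must form an (N, L, L) stack of squares")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("images contain non-finite values")

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[-1]
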