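"""Core in-memory container for multi-channel microscopy images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HPA_CHANNELS = ("nucleus", "microtubules", "er", "protein")
CELLPAINTING_CHANNELS = ("dna", "er", "rna", "agp", "mito")


@dataclass
class MultiChannelImage:
    """C-channel raster with channel-role labels.

    ``data`` has shape (C, H, W), float values; generated scenes live in
    [0, 1], normalized views may take any real value.
    """

    data: np.ndarray
    channels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("image data must be (C, H, W)")
        if not self.channels:
            self.channels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "MultiChannelImage":
        return MultiChannelImage(self.data.copy(), self.channels)
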