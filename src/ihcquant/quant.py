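"""Pixel-tally container shared by the ROI, whole-block and TMA paths."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StainQuant"]


@dataclass(frozen=True)
class StainQuant:
    """Pixel tallies for one analyzed region.

    Invariants (enforced on construction):
    ``background_pixels + sample_pixels == total_pixels`` and
    ``stained_pixels + unstained_pixels == sample_pixels``.

    ``stain_fraction`` is ``stained / sample`` when the region contains
    any sample tissue and ``None`` otherwise — never silently 0, so that
    downstream ratios fail loudly on empty regions.
    """

    total_pixels: int
    background_pixels: int
    sample_pixels: int
    stained_pixels: int
    unstained_pixels: int

    def __post_init__(self) -> None:
        counts = (
            self.total_pixels,
            self.background_pixels,
            self.sample_pixels,
            self.stained_pixels,
            self.unstained_pixels,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"negative pixel count in {counts}")
        if self.background_pixels + self.sample_pixels != self.total_pixels:
            raise ValueError(
                "background + sample != total "
                f"({self.background_pixels} + {self.sample_pixels} != {self.total_pixels})"
            )
        if self.stained_pixels + self.unstained_pixels != self.sample_pixels:
            raise ValueError(
                "stained + unstained != sample "
                f"({self.stained_pixels} + {self.unstained_pixels} != {self.sample_pixels})"
            )

    @property
    def stain_fraction(self) -> float | None:
        """Stained sample pixels over all sample pixels; None if no sample."""
        if self.sample_pixels == 0:
            return None
        return self.stained_pixels / self.sample_pixels

    def __add__(self, other: "StainQuant") -> "StainQuant":
        return StainQuant(
            total_pixels=self.total_pixels + other.total_pixels,
            background_pixels=self.background_pixels + other.background_pixels,
            sample_pixels=self.sample_pixels + other.sample_pixels,
            stained_pixels=self.stained_pixels + other.stained_pixels,
            unstained_pixels=self.unstained_pixels + other.unstained_pixels,
        )

    @classmethod
    def zero(cls) -> "StainQuant":
        return cls(0, 0, 0, 0, 0)
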