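"""Serial-crystallography count accounting.

A serial run collects a fixed number of detector images; a *hit* is an
image containing diffraction, and an *indexed* image is a hit whose pattern
was assigned a lattice.  The two headline rates are

    hit rate      = 100 · hits / images      (%)
    indexing rate = 100 · indexed / hits     (%)

Percentages are reported unrounded; round to one decimal for display to
match the field's table conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SSXCounts", "SSXRates", "ssx_rates"]


@dataclass(frozen=True)
class SSXCounts:
    """Image/hit/indexed counts for one dataset; 0 ≤ indexed ≤ hits ≤ images."""

    images: int
    hits: int
    indexed: int

    def __post_init__(self) -> None:
        for name in ("images", "hits", "indexed"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if not self.indexed <= self.hits <= self.images:
            raise ValueError(
                f"counts must satisfy indexed <= hits <= images, got "
                f"{self.indexed} <= {self.hits} <= {self.images}"
            )


@dataclass(frozen=True)
class SSXRates:
    """Hit and indexing percentages; ``indexing_rate`` is ``None`` when there
    were no hits (undefined, not zero)."""

    hit_rate: float
    indexing_rate: float | None


def ssx_rates(counts: SSXCounts) -> SSXRates:
    """Compute hit and indexing rates (%) from raw counts."""
    if counts.images == 0:
        raise ValueError("images must be > 0 to define a hit rate")
    hit_rate = 100.0 * counts.hits / counts.images
    indexing_rate = (
        100.0 * counts.indexed / counts.hits if counts.hits > 0 else None
    )
    return SSXRates(hit_rate=hit_rate, indexing_rate=indexing_rate)
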