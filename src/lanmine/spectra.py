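"""Peak and spectrum containers shared by MS1 matching and MS/MS annotation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = ["Peak", "Spectrum"]


@dataclass(frozen=True)
class Peak:
    """One peak; charge is optional (None = try all configured states)."""

    mz: float
    intensity: float = 0.0
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be > 0, got {self.mz}")
        if self.charge is not None and self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS (or MS1) peak list with optional precursor metadata."""

    peaks: Tuple[Peak, ...]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    title: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> Tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)
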