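"""Acquisition-protocol presets for the five benchmark experiments.

These record the protocol bookkeeping of the study conditions the package
emulates: interleave/spoke counts of the fully sampled phyllotaxis
acquisitions, and the RF phase-cycling schemes of the mapping protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["StudyProtocol", "PROTOCOLS", "phase_increments"]


def phase_increments(start: float, stop: float, step: float) -> Tuple[float, ...]:
    """Inclusive arithmetic RF-phase-increment ladder in degrees."""
    return tuple(np.arange(start, stop + step / 2.0, step, dtype=float))


@dataclass(frozen=True)
class StudyProtocol:
    """Bookkeeping of one acquisition protocol."""

    name: str
    sequence: str
    n_interleaves: int
    spokes_per_interleave: int
    tr_ms: float
    te_ms: float
    flip_deg: float
    rf_phase_increments_deg: Optional[Tuple[float, ...]] = None

    @property
    def n_spokes(self) -> int:
        """Spokes of a single trajectory repetition."""
        return self.n_interleaves * self.spokes_per_interleave

    @property
    def n_phase_cycles(self) -> int:
        if self.rf_phase_increments_deg is None:
            return 1
        return len(self.rf_phase_increments_deg)

    @property
    def total_readouts(self) -> int:
        """Total spokes over the whole phase-cycled series."""
        return self.n_spokes * self.n_phase_cycles


PROTOCOLS = {
    "scanner_comparison": StudyProtocol(
        name="scanner_comparison", sequence="bssfp",
        n_interleaves=89, spokes_per_interleave=200,
        tr_ms=3.6, te_ms=1.8, flip_deg=20.0,
        rf_phase_increments_deg=(180.0,),
    ),
    "salt_water_phantom": StudyProtocol(
        name="salt_water_phantom", sequence="bssfp",
        n_interleaves=89, spokes_per_interleave=200,
        tr_ms=3.6, te_ms=1.8, flip_deg=20.0,
        rf_phase_increments_deg=(180.0,),
    ),
    "t1_t2_phantom": StudyProtocol(
        name="t1_t2_phantom", sequence="phase_cycled_bssfp",
        n_interleaves=89, spokes_per_interleave=200,
        tr_ms=5.0, te_ms=2.5, flip_deg=20.0,
        rf_phase_increments_deg=phase_increments(0.0, 340.0, 20.0),
    ),
    "in_vivo_brain": StudyProtocol(
        name="in_vivo_brain", sequence="phase_cycled_bssfp",
        n_interleaves=89, spokes_per_interleave=200,
        tr_ms=5.0, te_ms=2.5, flip_deg=20.0,
        rf_phase_increments_deg=phase_increments(0.0, 330.0, 30.0),
    ),
    "in_vivo_heart": StudyProtocol(
        name="in_vivo_heart", sequence="gre",
        n_interleaves=547, spokes_per_interleave=18,
        tr_ms=5.5, te_ms=2.6, flip_deg=10.0,
        rf_phase_increments_deg=None,
    ),
}
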