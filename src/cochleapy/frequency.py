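"""Tonotopic frequency-place maps.

The organ-of-Corti characteristic frequency follows the Greenwood
frequency-place function

    f(x) = A * (10**(a * x) - k),

with x the fractional distance from the apex along the organ of Corti.  The
standard human constants (A = 165.4 Hz, a = 2.1, k = 0.88) are exposed as
configuration: they are calibration values from the psychoacoustic
literature, not quantities this package re-estimates.

Spiral-ganglion characteristic frequencies use the same functional form
evaluated at the ganglion's own fractional place; because Rosenthal's canal
spans fewer turns than the organ of Corti, a configurable linear place
compression maps ganglion place onto organ-of-Corti place (identity by
default, i.e. both paths are normalised by their own full length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GreenwoodMap:
    """Greenwood-form frequency-place map."""

    A: float = 165.4   # Hz
    a: float = 2.1     # decades over the full place range
    k: float = 0.88    # low-frequency correction

    def frequency(self, x_from_apex):
        """CF in Hz at fractional distance ``x_from_apex`` in [0, 1] from the apex."""
        x = np.clip(np.asarray(x_from_apex, dtype=float), 0.0, 1.0)
        out = self.A * (10.0 ** (self.a * x) - self.k)
        return float(out) if out.ndim == 0 else out

    def frequency_from_base(self, fraction_from_base):
        return self.frequency(1.0 - np.asarray(fraction_from_base, dtype=float))


@dataclass
class SpiralGanglionMap:
    """Frequency-place map along the spiral ganglion (Rosenthal's canal)."""

    greenwood: GreenwoodMap = None
    place_scale: float = 1.0   # ganglion place -> organ-of-Corti place
    place_offset: float = 0.0

    def __post_init__(self):
        if self.greenwood is None:
            self.greenwood = GreenwoodMap()

    def frequency_from_base(self, fraction_from_base):
        x = np.clip(self.place_scale * np.asarray(fraction_from_base, dtype=float)
                    + self.place_offset, 0.0, 1.0)
        return self.greenwood.frequency_from_base(x)
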