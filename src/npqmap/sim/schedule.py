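"""Measurement schedule of the fluorescence imaging routine.

The assay applies 10 min of 2000 umol m-2 s-1 actinic light followed by
12 min of darkness.  During the light (NPQ induction) period parameters are
sampled every 20 s for the first minute, then every minute; during the dark
(relaxation) period every 20 s for the first minute, every minute up to
4 min, then every 3 min, with the final sample pinned at 12 min because NPQf
and the photoprotection index are defined at the final dark time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LIGHT_DEFAULT = (1 / 3, 2 / 3, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
_DARK_DEFAULT = (1 / 3, 2 / 3, 1, 2, 3, 4, 7, 10, 12)

LIGHT_DURATION_MIN = 10.0
DARK_DURATION_MIN = 12.0


@dataclass(frozen=True)
class MeasurementSchedule:
    """Sampling times (minutes) for the light and dark phases.

    ``light_times`` are offsets from lights-on within [0, 10]; ``dark_times``
    are offsets from lights-off within (0, 12].
    """

    light_times: tuple[float, ...] = _LIGHT_DEFAULT
    dark_times: tuple[float, ...] = _DARK_DEFAULT

    def __post_init__(self) -> None:
        lt = np.asarray(self.light_times, dtype=float)
        dt = np.asarray(self.dark_times, dtype=float)
        if lt.size < 4 or dt.size < 4:
            raise ValueError("need at least 4 samples per phase for the fits")
        if np.any(np.diff(lt) <= 0) or np.any(np.diff(dt) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if lt[0] <= 0 or lt[-1] != LIGHT_DURATION_MIN:
            raise ValueError("light phase must span (0, 10] min and end at 10")
        if dt[0] <= 0 or dt[-1] != DARK_DURATION_MIN:
            raise ValueError("dark phase must span (0, 12] min and end at 12")
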