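"""Core in-memory containers shared by all analysis stages.

A :class:`SpikeTrain` is the unit of all correlation analysis: a sorted
array of event times (seconds) over a known recording duration.  A
:class:`FluorescenceMatrix` holds cells x frames fluorescence, either raw
or background-corrected (dF/F).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

EPOCHS = ("baseline", "during", "after")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) over a recording of known duration.

    Parameters
    ----------
    times_s
        Event times in seconds; sorted nondecreasing, all within
        ``[0, duration_s]``.
    duration_s
        Recording length in seconds; must be positive.
    """

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self):
        times = np.asarray(self.times_s, dtype=float).ravel()
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise InvalidParameterError("spike times must be sorted")
            if times[0] < 0 or times[-1] > self.duration_s:
                raise InvalidParameterError(
                    "spike times must lie in [0, duration_s]"
                )
        object.__setattr__(self, "times_s", times)

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    @property
    def rate_hz(self) -> float:
        """Spike count divided by total recording time."""
        return self.n_spikes / self.duration_s

    def shifted(self, offset_s: float) -> "SpikeTrain":
        """Return a copy with all times shifted by ``offset_s`` (must stay
        inside the recording)."""
        return SpikeTrain(self.times_s + offset_s, self.duration_s)


@dataclass
class FluorescenceMatrix:
    """Cells x frames fluorescence at a fixed frame rate.

    ``kind`` distinguishes raw extracted traces from background-corrected
    (dF/F) traces; ``epoch`` tags which recording epoch the matrix covers.
    """

    values: np.ndarray
    frame_rate_hz: float = 5.0
    epoch: str = "baseline"
    kind: str = "raw"
    roi_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("values must be 2-D (cells x frames)")
        if self.values.shape[1] < 2:
            raise InvalidParameterError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("fluorescence contains non-finite values")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be positive")
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.values.shape[0])
        else:
            self.roi_ids = np.asarray(self.roi_ids)
            if self.roi_ids.size != self.values.shape[0]:
                raise InvalidParameterError("roi_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz
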