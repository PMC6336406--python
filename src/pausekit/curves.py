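"""Time-course containers shared across the package.

A :class:`ProgressCurve` is the basic observable of a gel-based pause assay:
the fraction of RNA of a designated species (e.g. the C17 pause RNA) as a
function of time, optionally with a per-point standard deviation, for a
single replicate.  Fluorescence traces from stopped-flow experiments use the
lighter :class:`FluorescenceTrace`, whose signal is normalized but not
constrained to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProgressCurve", "FluorescenceTrace"]

# Fractions from gel quantification may stray slightly outside [0, 1]
# because of background subtraction; tolerate a small excursion.
_FRACTION_SLACK = 0.25


@dataclass
class ProgressCurve:
    """Fraction of a designated RNA species versus time for one replicate.

    Parameters
    ----------
    times:
        Time points in seconds, nonnegative and strictly increasing.
    fractions:
        Dimensionless fractions in [0, 1] (small excursions from
        quantification noise are tolerated).
    sd:
        Optional per-point standard deviation (same length as ``times``).
    replicate:
        Replicate identifier.
    species:
        Label of the measured species or species aggregate
        (e.g. ``"pause_rna"``, ``"prepause"``, ``"C17plus"``).
    """

    times: np.ndarray
    fractions: np.ndarray
    sd: np.ndarray | None = None
    replicate: int = 0
    species: str = "pause_rna"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, y = self.times, self.fractions
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValueError("times must be nonnegative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"times must be strictly increasing within replicate {self.replicate}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("fractions must be finite")
        if np.any(y < -_FRACTION_SLACK) or np.any(y > 1 + _FRACTION_SLACK):
            bad = int(np.argmax((y < -_FRACTION_SLACK) | (y > 1 + _FRACTION_SLACK)))
            raise ValueError(
                f"fraction {y[bad]:g} at row {bad} of replicate "
                f"{self.replicate} is outside [0, 1]"
            )
        if self.sd is not None:
            if self.sd.shape != t.shape:
                raise ValueError("sd must match times in length")
            if np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "replicate": self.replicate,
                "time_s": self.times,
                f"fraction_{self.species}": self.fractions,
            }
        )
        if self.sd is not None:
            out["sd"] = self.sd
        return out


@dataclass
class FluorescenceTrace:
    """Normalized stopped-flow fluorescence signal versus time."""

    times: np.ndarray
    signal: np.ndarray
    sd: np.ndarray | None = None
    label: str = "6MI"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.times.ndim != 1 or self.signal.shape != self.times.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace time grid must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_s": self.times, "signal": self.signal})
        if self.sd is not None:
            out["sd"] = self.sd
        return out
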