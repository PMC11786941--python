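"""Discrete joint choice set of weekly work and informal-care hours.

A potential carer allocates a weekly time endowment ``T`` (112 hours: a
7-day week minus 8 hours of sleep per day) between market work ``hw``,
informal caregiving ``hc`` and leisure ``l``, where leisure is the
residual ``l = T - hw - hc``.  The default choice set crosses three work
categories (0 / 30 / 40 hours: no work, part time, full time) with three
care categories (0 / 7 / 14 hours: no care, one hour per day, two hours
per day), giving nine discrete alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Weekly time endowment in hours (7 days minus 8 hours of sleep a day).
DEFAULT_T = 112.0

DEFAULT_WORK_LEVELS = (0.0, 30.0, 40.0)
DEFAULT_CARE_LEVELS = (0.0, 7.0, 14.0)

#: Snapping thresholds mapping observed continuous hours onto the grid.
#: Work: <15 -> 0, 15-35 -> 30, >35 -> 40.  Care: <1 -> 0, 1-10.5 -> 7,
#: >10.5 -> 14.  A convention; the survey mapping is not documented.
DEFAULT_WORK_CUTS = (15.0, 35.0)
DEFAULT_CARE_CUTS = (1.0, 10.5)


def leisure(hw: float, hc: float, T: float = DEFAULT_T) -> float:
    """Leisure residual ``T - hw - hc``.

    Raises ``ValueError`` if hours are negative or exceed the endowment.
    """
    if hw < 0 or hc < 0:
        raise ValueError("work and care hours must be non-negative")
    res = T - hw - hc
    if res < 0:
        raise ValueError(
            f"negative leisure: hw={hw} + hc={hc} exceeds endowment T={T}"
        )
    return res


@dataclass(frozen=True)
class Alternative:
    """One cell of the joint (work, care) choice grid."""

    index: int
    work_hours: float
    care_hours: float
    leisure: float

    @property
    def cares(self) -> bool:
        return self.care_hours > 0

    @property
    def works(self) -> bool:
        return self.work_hours > 0


@dataclass(frozen=True)
class ChoiceSet:
    """Ordered collection of alternatives (work outer, care inner).

    The ordering is fixed so that every downstream matrix (income,
    utilities, calibrated error terms) indexes alternatives identically:
    the no-work block comes first with care hours ascending within each
    work block.
    """

    alternatives: tuple[Alternative, ...]
    T: float = DEFAULT_T

    def __len__(self) -> int:
        return len(self.alternatives)

    def __iter__(self):
        return iter(self.alternatives)

    def __getitem__(self, j: int) -> Alternative:
        return self.alternatives[j]

    @property
    def work_hours(self) -> np.ndarray:
        return np.array([a.work_hours for a in self.alternatives])

    @property
    def care_hours(self) -> np.ndarray:
        return np.array([a.care_hours for a in self.alternatives])

    @property
    def leisure_hours(self) -> np.ndarray:
        return np.array([a.leisure for a in self.alternatives])

    @property
    def care_mask(self) -> np.ndarray:
        """Boolean mask of alternatives with positive care hours."""
        return self.care_hours > 0

    @property
    def work_mask(self) -> np.ndarray:
        return self.work_hours > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [a.index for a in self.alternatives],
                "hw": self.work_hours,
                "hc": self.care_hours,
                "l": self.leisure_hours,
            }
        )

    def to_csv(self, path) -> None:
        """Serialize the grid to a small audit CSV (index, hw, hc, l)."""
        self.to_frame().to_csv(path, index=False)


def build_choice_set(
    work_levels=DEFAULT_WORK_LEVELS,
    care_levels=DEFAULT_CARE_LEVELS,
    T: float = DEFAULT_T,
) -> ChoiceSet:
    """Build the Cartesian product of work and care hour categories.

    Alternatives are ordered work-outer / care-inner.  Levels must be
    non-negative and duplicate-free, and every combination must leave
    non-negative leisure (the default grid leaves l > 0 everywhere).
    """
    work_levels = [float(w) for w in work_levels]
    care_levels = [float(c) for c in care_levels]
    if len(set(work_levels)) != len(work_levels):
        raise ValueError("duplicate work levels")
    if len(set(care_levels)) != len(care_levels):
        raise ValueError("duplicate care levels")
    if any(w < 0 for w in work_levels) or any(c < 0 for c in care_levels):
        raise ValueError("hour levels must be non-negative")
    alts = []
    j = 0
    for hw in work_levels:
        for hc in care_levels:
            alts.append(Alternative(j, hw, hc, leisure(hw, hc, T)))
            j += 1
    return ChoiceSet(tuple(alts), T=T)


def snap_to_grid(
    hw_obs,
    hc_obs,
    choice_set: ChoiceSet,
    work_cuts=DEFAULT_WORK_CUTS,
    care_cuts=DEFAULT_CARE_CUTS,
) -> np.ndarray:
    """Map observed continuous weekly hours onto alternative indices.

    Observed (hw, hc) pairs are discretized by the threshold rule and the
    resulting grid cell is looked up in the choice set.  Works on scalars
    or arrays; returns an integer index array.
    """
    hw_obs = np.atleast_1d(np.asarray(hw_obs, dtype=float))
    hc_obs = np.atleast_1d(np.asarray(hc_obs, dtype=float))
    work_levels = sorted(set(choice_set.work_hours))
    care_levels = sorted(set(choice_set.care_hours))
    if len(work_levels) != len(work_cuts) + 1 or len(care_levels) != len(care_cuts) + 1:
        raise ValueError("cut lists must have one fewer entry than grid levels")
    hw_cat = np.digitize(hw_obs, work_cuts)
    hc_cat = np.digitize(hc_obs, care_cuts)
    hw_snap = np.array(work_levels)[hw_cat]
    hc_snap = np.array(care_levels)[hc_cat]
    lookup = {
        (a.work_hours, a.care_hours): a.index for a in choice_set
    }
    return np.array([lookup[(w, c)] for w, c in zip(hw_snap, hc_snap)])
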