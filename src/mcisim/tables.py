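"""Vital-sign coding and survival-deterioration lookup tables.

Both tables ship as delimiter-separated fixtures under ``mcisim/data`` and are
loaded once at import of the modules that need them.  The deterioration grid
gives the survival probability (in percent) of a casualty as a function of the
RPM injury-severity score (columns, 0 worst .. 12 best) and the time elapsed
since injury (rows, 30-minute bins).  Lookups are a left-continuous step
function: the row for the largest tabulated time not exceeding ``t`` applies,
and times beyond the last row reuse the last row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

RPM_MIN, RPM_MAX = 0, 12


def _data_path(name: str):
    return resources.files("mcisim.data").joinpath(name)


def load_rpm_coding() -> dict:
    """Load the vital-sign coding table.

    Returns a dict with keys ``rr``, ``pr`` (lists of ``(lo, hi, code)`` with
    ``hi`` possibly ``inf``) and ``motor`` (label -> code).
    """
    rr, pr, motor = [], [], {}
    with _data_path("rpm_coding.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header[0] == "code"
        for line in fh:
            code, rr_lo, rr_hi, pr_lo, pr_hi, m = line.rstrip("\n").split("\t")
            code = int(code)
            rr.append((int(rr_lo), math.inf if rr_hi == "inf" else int(rr_hi), code))
            pr.append((int(pr_lo), math.inf if pr_hi == "inf" else int(pr_hi), code))
            motor[m] = code
    return {"rr": rr, "pr": pr, "motor": motor}


RPM_CODING = load_rpm_coding()
MOTOR_LEVELS = tuple(RPM_CODING["motor"])  # ordered worst -> best


@dataclass(frozen=True)
class DeteriorationTable:
    """Survival probability (%) indexed by (elapsed-time bin, RPM score)."""

    times: tuple  # row times in minutes, ascending, starting at 0
    grid: np.ndarray = field(repr=False)  # shape (len(times), 13)
    bin_width: int = 30

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.shape != (len(self.times), RPM_MAX + 1):
            raise ValueError("grid shape does not match times x 13 RPM columns")
        self.validate()

    def validate(self) -> None:
        g = self.grid
        if (g < 0).any() or (g > 100).any():
            raise ValueError("survival probabilities must lie in [0, 100]")
        if (np.diff(g, axis=0) > 0).any():
            raise ValueError("survival must be non-increasing in time for fixed RPM")
        if (np.diff(g, axis=1) < 0).any():
            raise ValueError("survival must be non-decreasing in RPM for fixed time")
        if list(self.times) != sorted(self.times) or self.times[0] != 0:
            raise ValueError("times must be ascending and start at 0")

    def row_index(self, t: float) -> int:
        """Index of the largest tabulated time <= t (last row beyond the end)."""
        if t < 0:
            raise ValueError("elapsed time must be >= 0")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return idx

    def lookup(self, rpm: int, t: float) -> float:
        if not (RPM_MIN <= rpm <= RPM_MAX):
            raise ValueError(f"RPM score {rpm!r} outside [0, 12]")
        return float(self.grid[self.row_index(t), rpm])

    def first_zero_time(self, rpm_at) -> float:
        """First tabulated bin time at which survival reaches 0.

        ``rpm_at`` maps a bin time (minutes) to the RPM score the victim holds
        at that time.  Returns ``math.inf`` if survival never reaches zero on
        the tabulated horizon.
        """
        for t in self.times:
            if self.lookup(rpm_at(t), t) == 0:
                return float(t)
        return math.inf

    @classmethod
    def default(cls) -> "DeteriorationTable":
        times, rows = [], []
        with _data_path("deterioration.tsv").open() as fh:
            fh.readline()
            for line in fh:
                parts = line.split()
                times.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
        return cls(times=tuple(times), grid=np.array(rows))
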