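"""Domain containers and delimited-text I/O for two-level energy and work data.

The on-disk dialect is deliberately plain: tab- or comma-delimited UTF-8
text with a header row, ``#`` comment lines allowed, decimal points only.
Energy series hold per-frame potential energies evaluated at both levels
of theory (the cheap "low" level used for sampling, and the expensive
"high" level providing accurate energetics); work sets hold per-switch
nonequilibrium work values for one switching direction.

Sign convention: every stored ΔA, ΔU and W is in the low→high direction
for forward data and in the native high→low direction for backward data;
negation happens only where an estimator requires it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "Direction",
    "EnergySeries",
    "WorkSet",
    "FormatError",
    "ValidationError",
    "wrap_angle",
    "read_energy_series",
    "write_energy_series",
    "read_work_set",
    "write_work_set",
    "apply_offset",
]


class FormatError(ValueError):
    """Raised when a file lacks the expected columns or structure."""


class ValidationError(ValueError):
    """Raised when parsed content violates a container invariant."""


class Level(str, enum.Enum):
    """Which level of theory generated the sampling."""

    LOW = "low"
    HIGH = "high"


class Direction(str, enum.Enum):
    """Switching direction: forward is low→high, backward is high→low."""

    FORWARD = "forward"
    BACKWARD = "backward"


def wrap_angle(angle):
    """Wrap angles (degrees) into [-180, 180).

    Works on scalars and arrays; 185 maps to -175, -180 stays -180.
    """
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class EnergySeries:
    """Per-frame energies at both levels from one equilibrium run.

    Attributes
    ----------
    sampling_level : Level
        Level of theory whose canonical ensemble the frames sample.
    frame_index : ndarray of int
        Strictly increasing frame numbers.
    u_low, u_high : ndarray of float
        Potential energy of each frame at the two levels (kcal/mol).
    dihedrals : DataFrame or None
        Optional per-frame dihedral angles (degrees, wrapped to
        [-180, 180)), one named column per rotatable bond.
    coords : ndarray or None
        Optional in-memory coordinates (n_frames, n_coords) so that
        switching runs can be launched from the saved frames.  Not
        serialized by :func:`write_energy_series`.
    """

    sampling_level: Level
    frame_index: np.ndarray
    u_low: np.ndarray
    u_high: np.ndarray
    dihedrals: Optional[pd.DataFrame] = None
    coords: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sampling_level = Level(self.sampling_level)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.u_low = np.asarray(self.u_low, dtype=float)
        self.u_high = np.asarray(self.u_high, dtype=float)
        n = len(self.frame_index)
        if n == 0:
            raise ValidationError("energy series is empty")
        if len(self.u_low) != n or len(self.u_high) != n:
            raise ValidationError("frame/energy column lengths differ")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValidationError("frame_index must be strictly increasing")
        for name, u in (("u_low", self.u_low), ("u_high", self.u_high)):
            bad = np.flatnonzero(~np.isfinite(u))
            if bad.size:
                raise ValidationError(f"non-finite {name} at row {bad[0]}")
        if self.dihedrals is not None:
            if len(self.dihedrals) != n:
                raise ValidationError("dihedral rows do not match frame count")
            self.dihedrals = _wrap_dihedral_frame(pd.DataFrame(self.dihedrals))
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape[0] != n:
                raise ValidationError("coords rows do not match frame count")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def delta_u(self) -> np.ndarray:
        """Instantaneous low→high energy gap, u_high - u_low, per frame."""
        return self.u_high - self.u_low


def _wrap_dihedral_frame(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(wrap_angle(df.to_numpy()), columns=df.columns, index=df.index)


@dataclass
class WorkSet:
    """Nonequilibrium work values for one direction and switch length.

    ``works`` are in kcal/mol with the direction's native sign: a
    backward set holds W(high→low) as produced by the switches, not its
    negation.
    """

    direction: Direction
    switch_steps: int
    timestep_fs: float
    switch_id: np.ndarray
    works: np.ndarray
    end_dihedrals: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.switch_id = np.asarray(self.switch_id, dtype=int)
        self.works = np.asarray(self.works, dtype=float)
        if self.works.size == 0:
            raise ValidationError("work set is empty")
        if len(self.switch_id) != len(self.works):
            raise ValidationError("switch_id/works lengths differ")
        if self.switch_steps < 1:
            raise ValidationError("switch_steps must be >= 1")
        if len(np.unique(self.switch_id)) != len(self.switch_id):
            raise ValidationError("duplicate switch_id values")
        bad = np.flatnonzero(~np.isfinite(self.works))
        if bad.size:
            raise ValidationError(f"non-finite work at row {bad[0]}")
        if self.end_dihedrals is not None:
            if len(self.end_dihedrals) != len(self.works):
                raise ValidationError("end_dihedrals rows do not match work count")
            self.end_dihedrals = _wrap_dihedral_frame(pd.DataFrame(self.end_dihedrals))

    def __len__(self) -> int:
        return len(self.works)


_RESERVED_ENERGY_COLS = {"frame", "u_low", "u_high"}


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValidationError(f"{path}: empty file")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        # round_trip parsing keeps write→read of full-precision decimal
        # text bit-exact
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_energy_series(path, level: Level | str) -> EnergySeries:
    """Read a per-frame two-level energy table.

    The file must have columns ``frame``, ``u_low`` and ``u_high``; any
    further numeric columns are taken as dihedral angles in degrees and
    wrapped to [-180, 180).
    """
    df = _read_table(path)
    missing = _RESERVED_ENERGY_COLS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in _RESERVED_ENERGY_COLS]
    dihedrals = df[extra] if extra else None
    return EnergySeries(
        sampling_level=Level(level),
        frame_index=df["frame"].to_numpy(),
        u_low=df["u_low"].to_numpy(dtype=float),
        u_high=df["u_high"].to_numpy(dtype=float),
        dihedrals=dihedrals,
    )


def write_energy_series(series: EnergySeries, path, sep: str = "\t") -> None:
    """Write an energy series as delimited text (17 significant digits,
    enough for a bit-exact float round trip)."""
    df = pd.DataFrame(
        {
            "frame": series.frame_index,
            "u_low": series.u_low,
            "u_high": series.u_high,
        }
    )
    if series.dihedrals is not None:
        for col in series.dihedrals.columns:
            df[col] = series.dihedrals[col].to_numpy()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_work_set(
    path,
    direction: Direction | str,
    switch_steps: int = 1000,
    timestep_fs: float = 1.0,
) -> WorkSet:
    """Read a per-switch work table with columns ``switch_id`` and ``w``."""
    df = _read_table(path)
    missing = {"switch_id", "w"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c not in {"switch_id", "w"}]
    return WorkSet(
        direction=Direction(direction),
        switch_steps=switch_steps,
        timestep_fs=timestep_fs,
        switch_id=df["switch_id"].to_numpy(),
        works=df["w"].to_numpy(dtype=float),
        end_dihedrals=df[extra] if extra else None,
    )


def write_work_set(work: WorkSet, path, sep: str = "\t") -> None:
    df = pd.DataFrame({"switch_id": work.switch_id, "w": work.works})
    if work.end_dihedrals is not None:
        for col in work.end_dihedrals.columns:
            df[col] = work.end_dihedrals[col].to_numpy()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def apply_offset(delta_a_reported: float, offset: float) -> float:
    """Restore the full free-energy difference from a tabulated value.

    Connection-leg ΔA values between an MM and an SQM level carry a huge
    constant part (the tabulated per-molecule "offset", ~10^4 kcal/mol)
    that is split off so the interesting digits stay visible.  The
    convention moves the value away from zero: the offset is added to
    positive tabulated values and subtracted from negative ones; zero
    maps to zero.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if delta_a_reported > 0:
        return delta_a_reported + offset
    if delta_a_reported < 0:
        return delta_a_reported - offset
    return 0.0
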