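"""Shared domain types, calibrated-image and trace I/O, configuration and validation.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major (``(row, col)`` = ``(y, x)``);
* physical lengths are micrometres, forces piconewtons (optical tweezers)
  or nanonewtons (AFM), elastic moduli pascals;
* calibrated quantities carry their unit in the column name
  (``area_um2``, ``E_pa``, ``Dp_um2_per_s``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Image2D",
    "LabeledMask",
    "ForceTrace",
    "IndentationProtocol",
    "MechResult",
    "GROUP_TABLE_COLUMNS",
    "make_group_table",
    "validate_group_table",
    "read_image",
    "write_image",
    "load_trace",
    "write_trace",
    "write_results",
    "read_results",
    "load_protocol",
    "save_protocol",
]


@dataclass(frozen=True)
class Image2D:
    """A single-channel intensity image with physical pixel calibration.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Non-negative intensities, stored as float64.
    pixel_size_um : float
        Physical size of one pixel in micrometres (> 0).
    channel_name : str
        Free-text channel label, e.g. ``"DAPI"``, ``"laminB1"``, ``"gH2AX"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D grid, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D intensities must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabeledMask:
    """Integer label grid: 0 = background, k = nucleus (object) k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("LabeledMask requires a 2-D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, lab.astype(np.int64)):
                raise ValueError("labels must be integers")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def n_objects(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of a single labelled object."""
        return self.labels == label


@dataclass(frozen=True)
class ForceTrace:
    """A sampled force–time series from one indentation experiment.

    ``flags`` collects quality warnings attached at load time (e.g.
    ``"truncated"`` when the trace is shorter than its protocol implies).
    """

    time_s: np.ndarray
    force_pN: np.ndarray
    sample_rate_hz: float
    position_um: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=np.float64)
        f = np.asarray(self.force_pN, dtype=np.float64)
        if t.ndim != 1 or f.ndim != 1 or len(t) != len(f):
            raise ValueError("time_s and force_pN must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        # sample rate must agree with the median time step within 1 %
        med_dt = float(np.median(dt))
        if abs(med_dt * self.sample_rate_hz - 1.0) > 0.01:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} inconsistent with "
                f"median time step {med_dt:.6g} s (>1% off)"
            )
        pos = self.position_um
        if pos is not None:
            pos = np.asarray(pos, dtype=np.float64)
            if pos.shape != t.shape:
                raise ValueError("position_um length mismatch")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_pN", f)
        object.__setattr__(self, "position_um", pos)
        object.__setattr__(self, "flags", tuple(self.flags))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class IndentationProtocol:
    """Square-wave amplitude-sweep indentation schedule.

    Defaults follow the standard optical-tweezers routine for nuclear
    indentation: square oscillation at 0.5 Hz (slow enough for complete
    poroelastic relaxation between cycles), 100 % offset (bead pushes for
    half of each period and fully retracts for the other half), amplitudes
    swept over 0.6–1.6 µm in 0.05 or 0.10 µm steps, 45 s of data per
    amplitude, 3 µm nominal indenter bead.
    """

    amplitudes_um: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.6, 1.6001, 0.10), 10))
    )
    frequency_hz: float = 0.5
    dwell_per_amplitude_s: float = 45.0
    offset_fraction: float = 1.0
    bead_diameter_um: float = 3.0
    trap_stiffness_pN_per_um: float = 200.0
    waveform: str = "square"

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes_um)
        if len(amps) == 0:
            raise ValueError("at least one amplitude required")
        if any(a <= 0 for a in amps):
            raise ValueError("amplitudes must be positive")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitudes must be strictly ascending")
        if self.waveform != "square":
            raise ValueError("only square waveform is supported")
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be > 0")
        if not self.dwell_per_amplitude_s > 1.0 / self.frequency_hz:
            raise ValueError("dwell must exceed one oscillation period")
        if not self.bead_diameter_um > 0:
            raise ValueError("bead_diameter_um must be > 0")
        if not self.trap_stiffness_pN_per_um > 0:
            raise ValueError("trap_stiffness_pN_per_um must be > 0")
        object.__setattr__(self, "amplitudes_um", amps)

    @classmethod
    def from_sweep(
        cls,
        start_um: float = 0.6,
        stop_um: float = 1.6,
        step_um: float = 0.10,
        **kwargs,
    ) -> "IndentationProtocol":
        """Build a protocol from an amplitude sweep (inclusive endpoints)."""
        n = int(round((stop_um - start_um) / step_um)) + 1
        amps = tuple(np.round(start_um + step_um * np.arange(n), 10))
        return cls(amplitudes_um=amps, **kwargs)

    @property
    def bead_radius_um(self) -> float:
        return self.bead_diameter_um / 2.0

    @property
    def n_amplitudes(self) -> int:
        return len(self.amplitudes_um)

    @property
    def total_duration_s(self) -> float:
        return self.dwell_per_amplitude_s * self.n_amplitudes


@dataclass
class MechResult:
    """Per-nucleus mechanical estimates from the optical-tweezers pipeline.

    ``E_pa`` is the stiffness fitted from instantaneous peak indentation
    forces; ``E_equilibrium_pa`` the secondary modulus fitted from plateau
    forces; ``Dp_um2_per_s`` the poroelastic diffusion coefficient
    (median over identifiable relaxation segments).
    """

    E_pa: float
    Dp_um2_per_s: float
    n_cycles_used: int
    fit_rss: float
    E_equilibrium_pa: float = float("nan")
    depth_bins: dict | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.flags = tuple(self.flags)
        if not self.flags:
            if not (self.E_pa > 0 and self.Dp_um2_per_s > 0):
                raise ValueError("unflagged MechResult requires positive E and Dp")


# ---------------------------------------------------------------------------
# GroupTable: long-format per-sample metric table shared by all stages
# ---------------------------------------------------------------------------

GROUP_TABLE_COLUMNS = ["sample_id", "condition", "metric_name", "value"]


def make_group_table(rows) -> pd.DataFrame:
    """Build a validated long-format group table.

    ``rows`` is an iterable of ``(sample_id, condition, metric_name, value)``.
    """
    df = pd.DataFrame(list(rows), columns=GROUP_TABLE_COLUMNS)
    validate_group_table(df)
    return df


def validate_group_table(table: pd.DataFrame, conditions: set[str] | None = None) -> None:
    missing = [c for c in GROUP_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns: {missing}")
    if len(table) and not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("group table values must be finite")
    if conditions is not None:
        bad = set(table["condition"]) - set(conditions)
        if bad:
            raise ValueError(f"undeclared conditions: {sorted(bad)}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path: str | os.PathLike, pixel_size_um: float, channel_name: str = "") -> Image2D:
    """Read a single-plane grayscale TIFF as a calibrated :class:`Image2D`.

    Pixel calibration is a required user input: microscopy TIFFs rarely
    carry trustworthy physical metadata, so it is never inferred.
    """
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: multi-channel/multi-page TIFF (shape {arr.shape}); "
            "split channels upstream or pass a single-plane grayscale file"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return Image2D(arr.astype(np.float64), pixel_size_um, channel_name)


def write_image(image: Image2D, path: str | os.PathLike) -> None:
    """Write an :class:`Image2D` as a float32 single-plane TIFF."""
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def load_trace(path: str | os.PathLike, protocol: IndentationProtocol | None = None) -> ForceTrace:
    """Load a delimited force trace with header ``time_s,force_pN[,position_um]``.

    If a protocol is given and the trace is shorter than the protocol's
    total duration, the trace is returned with a ``"truncated"`` flag
    rather than rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_s", "force_pN"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    rate = 1.0 / float(np.median(np.diff(t)))
    pos = df["position_um"].to_numpy(dtype=float) if "position_um" in df.columns else None
    flags: list[str] = []
    if protocol is not None:
        # a sampled trace of the full protocol ends one sample short of the
        # nominal duration; only a larger shortfall means truncation
        med_dt = float(np.median(np.diff(t)))
        if protocol.total_duration_s - (t[-1] - t[0]) > 1.5 * med_dt:
            flags.append("truncated")
    return ForceTrace(
        time_s=t,
        force_pN=df["force_pN"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        position_um=pos,
        flags=tuple(flags),
    )


def write_trace(trace: ForceTrace, path: str | os.PathLike) -> None:
    cols = {"time_s": trace.time_s, "force_pN": trace.force_pN}
    if trace.position_um is not None:
        cols["position_um"] = trace.position_um
    pd.DataFrame(cols).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a group table as CSV with fixed column order."""
    validate_group_table(table)
    table[GROUP_TABLE_COLUMNS].to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_group_table(df)
    return df[GROUP_TABLE_COLUMNS]


def load_protocol(path: str | os.PathLike) -> IndentationProtocol:
    """Load an indentation protocol from a YAML file with a ``protocol:`` block."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("protocol", doc) if isinstance(doc, dict) else None
    if not isinstance(block, dict):
        raise ValueError(f"{path}: expected a mapping with a 'protocol:' block")
    if "amplitudes_um" in block:
        block["amplitudes_um"] = tuple(float(a) for a in block["amplitudes_um"])
    return IndentationProtocol(**block)


def save_protocol(protocol: IndentationProtocol, path: str | os.PathLike) -> None:
    block = {
        "waveform": protocol.waveform,
        "frequency_hz": protocol.frequency_hz,
        "amplitudes_um": [float(a) for a in protocol.amplitudes_um],
        "dwell_per_amplitude_s": protocol.dwell_per_amplitude_s,
        "offset_fraction": protocol.offset_fraction,
        "bead_diameter_um": protocol.bead_diameter_um,
        "trap_stiffness_pN_per_um": protocol.trap_stiffness_pN_per_um,
    }
    with open(path, "w") as fh:
        yaml.safe_dump({"protocol": block}, fh, sort_keys=False)
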