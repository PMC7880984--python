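"""Gaze-trace I/O, pixel-to-angle conversion and decimation.

Traces are delimited text (comma or tab, autodetected) with a header row
naming columns ``time``, ``x``, ``y`` and optionally ``eye``. Positions may
be screen pixels (requires a :class:`ScreenGeometry`) or visual angles in
degrees. Internally everything is degrees of azimuth/elevation relative to
straight-ahead: rightward and upward positive, screen center at (0, 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "ScreenGeometry",
    "GazeTrace",
    "pixels_to_degrees",
    "read_trace",
    "write_trace",
    "downsample",
]

_MIN_SAMPLES = 10


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical geometry of a flat screen viewed fronto-parallel.

    Defaults correspond to a 125 x 77 cm HD (1920 x 1080) display viewed
    from 100 cm, a typical large-format oculomotor lab setup.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 125.0
    height_cm: float = 77.0
    viewing_distance_cm: float = 100.0
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"ScreenGeometry.{name} must be strictly positive")
        if self.center_px is None:
            object.__setattr__(
                self, "center_px", ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)
            )

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenGeometry":
        """Load geometry from a YAML / flat key=value file."""
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:  # pragma: no cover - malformed config
            raise FormatError(f"cannot parse geometry file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            # fall back to key=value lines
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = line.split("=", 1)
                raw[key.strip()] = yaml.safe_load(val.strip())
        kwargs = {}
        mapping = {
            "width_px": "width_px",
            "height_px": "height_px",
            "width_cm": "width_cm",
            "height_cm": "height_cm",
            "distance_cm": "viewing_distance_cm",
            "viewing_distance_cm": "viewing_distance_cm",
            "center_px": "center_px",
        }
        for key, attr in mapping.items():
            if key in raw:
                val = raw[key]
                if attr == "center_px" and val is not None:
                    val = tuple(float(v) for v in val)
                kwargs[attr] = val
        return cls(**kwargs)


@dataclass
class GazeTrace:
    """Uniformly sampled monocular gaze time series in degrees.

    ``validity_mask`` marks tracked samples; lost or out-of-screen samples
    stay in place (so indices and timing are preserved) but are flagged
    invalid rather than dropped.
    """

    timestamps: np.ndarray  # seconds, strictly increasing, uniform
    azimuth: np.ndarray  # degrees
    elevation: np.ndarray  # degrees
    sampling_frequency: float  # Hz
    eye_label: str = "unknown"
    validity_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.azimuth = np.asarray(self.azimuth, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.validity_mask is None:
            self.validity_mask = np.isfinite(self.azimuth) & np.isfinite(self.elevation)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.azimuth) == len(self.elevation) == len(self.validity_mask) == n):
            raise DataError("GazeTrace arrays must share one length")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        """Nominal sampling period in seconds."""
        return 1.0 / self.sampling_frequency

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.timestamps,
                "x": self.azimuth,
                "y": self.elevation,
                "valid": self.validity_mask,
            }
        )


def pixels_to_degrees(
    x_px: np.ndarray | float, y_px: np.ndarray | float, geometry: ScreenGeometry
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Convert screen-pixel coordinates to (azimuth, elevation) in degrees.

    Each axis is converted independently: the metric offset from screen
    center is divided by the viewing distance and passed through atan.
    Rightward azimuth and upward elevation are positive; screen pixel rows
    grow downward, hence the sign flip on y.
    """
    cx, cy = geometry.center_px  # type: ignore[misc]
    dx_cm = (np.asarray(x_px, dtype=float) - cx) * geometry.cm_per_px_x
    dy_cm = (cy - np.asarray(y_px, dtype=float)) * geometry.cm_per_px_y
    az = np.degrees(np.arctan2(dx_cm, geometry.viewing_distance_cm))
    el = np.degrees(np.arctan2(dy_cm, geometry.viewing_distance_cm))
    if np.isscalar(x_px) and np.isscalar(y_px):
        return float(az), float(el)
    return az, el


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_trace(
    path: str | Path,
    dialect: str = "degrees",
    geometry: ScreenGeometry | None = None,
) -> GazeTrace:
    """Read one gaze trace from a delimited text file.

    Parameters
    ----------
    path
        File with header columns ``time``, ``x``, ``y`` (optional ``eye``).
    dialect
        ``"degrees"`` if x/y already are visual angles, ``"pixels"`` if
        they are screen pixels (then *geometry* is required).
    geometry
        Screen geometry for the pixel dialect.

    The sampling frequency is inferred from the median timestamp spacing.
    Non-finite samples, and pixel samples outside the screen, are flagged
    invalid in ``validity_mask`` — never dropped.
    """
    import pandas as pd

    if dialect not in ("degrees", "pixels"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    if dialect == "pixels" and geometry is None:
        raise ParameterError("pixels dialect requires a ScreenGeometry")

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        head = fh.readline()
    delim = _sniff_delimiter(head)
    df = pd.read_csv(path, sep=delim)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"time", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {sorted(missing)}")
    if len(df) < _MIN_SAMPLES:
        raise DataError(f"{path.name}: need at least {_MIN_SAMPLES} samples, got {len(df)}")

    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path.name}: timestamps are not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))

    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    valid = np.isfinite(x) & np.isfinite(y)
    if dialect == "pixels":
        assert geometry is not None
        on_screen = (
            (x >= 0) & (x <= geometry.width_px - 1) & (y >= 0) & (y <= geometry.height_px - 1)
        )
        valid &= on_screen
        az, el = pixels_to_degrees(np.where(np.isfinite(x), x, 0.0),
                                   np.where(np.isfinite(y), y, 0.0), geometry)
        az = np.where(valid, az, np.nan)
        el = np.where(valid, el, np.nan)
    else:
        az, el = x, y

    eye = "unknown"
    if "eye" in df.columns:
        labels = {str(v).strip().lower() for v in df["eye"].dropna().unique()}
        if labels <= {"left", "l"}:
            eye = "left"
        elif labels <= {"right", "r"}:
            eye = "right"
    return GazeTrace(t, az, el, sampling_frequency=fs, eye_label=eye, validity_mask=valid)


def write_trace(trace: GazeTrace, path: str | Path, delimiter: str = ",") -> None:
    """Write a trace in the degrees dialect (full float precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["time", "x", "y", "eye"])
        for t, az, el in zip(trace.timestamps, trace.azimuth, trace.elevation):
            writer.writerow([repr(float(t)), repr(float(az)), repr(float(el)), trace.eye_label])


def downsample(trace: GazeTrace, factor: int) -> GazeTrace:
    """Decimate a trace, keeping every *factor*-th sample starting at 0.

    Pure decimation without anti-alias filtering — this emulates what a
    genuinely slower eye tracker would record, which is the point of the
    sampling-frequency robustness study.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"decimation factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(
            trace,
            timestamps=trace.timestamps.copy(),
            azimuth=trace.azimuth.copy(),
            elevation=trace.elevation.copy(),
            validity_mask=trace.validity_mask.copy(),
        )
    sl = slice(None, None, factor)
    return GazeTrace(
        timestamps=trace.timestamps[sl].copy(),
        azimuth=trace.azimuth[sl].copy(),
        elevation=trace.elevation[sl].copy(),
        sampling_frequency=trace.sampling_frequency / factor,
        eye_label=trace.eye_label,
        validity_mask=trace.validity_mask[sl].copy(),
    )
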