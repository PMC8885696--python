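"""Complex permittivity spectra: containers, unit conversions and CSV I/O.

A spectrum is the complex relative permittivity eps* = eps' - j eps'' sampled
on a frequency grid.  The real part eps' (dielectric constant) stores energy;
the imaginary part eps'' (dielectric loss) dissipates it and is equivalent to
a dielectric conductivity sigma = eps'' * eps0 * 2*pi*f.  Loss is always
stored as eps''; sigma is derived on demand so the two never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Vacuum permittivity, F/m (CODATA 2018).
EPS0 = 8.8541878128e-12

#: Measurement band of the coaxial-probe setup, Hz.
DEFAULT_F_MIN = 200e6
DEFAULT_F_MAX = 14e9
#: Number of grid points in the default acquisition grid.
DEFAULT_N_POINTS = 167

PHASES = ("control", "ischemia", "reperfusion")


class SpectrumError(ValueError):
    """Invalid spectrum data or operation."""


class GridMismatchError(SpectrumError):
    """Two spectra do not share an identical frequency grid."""


class BandError(SpectrumError):
    """Requested frequency band does not intersect the spectrum."""


class SpectraParseError(SpectrumError):
    """Malformed spectra CSV."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing frequency sample points in Hz."""

    points: np.ndarray
    band: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise SpectrumError("frequency grid needs at least 2 points")
        if not np.all(np.diff(pts) > 0):
            raise SpectrumError("frequency grid must be strictly increasing")
        if pts[0] <= 0:
            raise SpectrumError("frequencies must be positive")
        band = self.band if self.band is not None else (float(pts[0]), float(pts[-1]))
        band = (float(band[0]), float(band[1]))
        if pts[0] < band[0] or pts[-1] > band[1]:
            raise SpectrumError("grid points fall outside the declared band")
        object.__setattr__(self, "band", band)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency 2*pi*f, rad/s."""
        return 2.0 * np.pi * self.points

    def __len__(self) -> int:
        return self.points.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyGrid)
            and len(self) == len(other)
            and np.array_equal(self.points, other.points)
        )

    def __hash__(self):
        return hash((self.points.tobytes(), self.band))


def default_grid(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    n_points: int = DEFAULT_N_POINTS,
) -> FrequencyGrid:
    """Linearly spaced acquisition grid (default: 167 points, 200 MHz-14 GHz)."""
    return FrequencyGrid(np.linspace(f_min, f_max, n_points))


@dataclass(frozen=True)
class SpecimenMeta:
    """Provenance of one measurement.

    ``case_id`` follows the four-arm protocol: 1 control, 2 ischemia,
    3 = 3 h ischemia + reperfusion, 4 = 4 h ischemia + reperfusion.
    ``ischemia_h``/``reperfusion_h`` are elapsed hours at measurement time.
    """

    subject_id: str
    case_id: int
    phase: str
    ischemia_h: float = 0.0
    reperfusion_h: float = 0.0
    replicate: int = 1

    def __post_init__(self):
        object.__setattr__(self, "subject_id", str(self.subject_id))
        object.__setattr__(self, "case_id", int(self.case_id))
        object.__setattr__(self, "ischemia_h", float(self.ischemia_h))
        object.__setattr__(self, "reperfusion_h", float(self.reperfusion_h))
        object.__setattr__(self, "replicate", int(self.replicate))
        if self.phase not in PHASES:
            raise SpectrumError(f"unknown phase {self.phase!r}")
        if self.case_id not in (1, 2, 3, 4):
            raise SpectrumError(f"case_id must be 1-4, got {self.case_id}")
        if self.ischemia_h < 0 or self.reperfusion_h < 0:
            raise SpectrumError("elapsed hours must be non-negative")
        if self.replicate < 1:
            raise SpectrumError("replicate must be a positive integer")
        if self.phase == "control" and (self.ischemia_h or self.reperfusion_h):
            raise SpectrumError("control specimens have zero elapsed injury time")
        if self.phase == "ischemia" and self.reperfusion_h:
            raise SpectrumError("ischemia-phase specimens have zero reperfusion time")
        if self.phase == "reperfusion" and self.ischemia_h <= 0:
            raise SpectrumError("reperfusion requires a positive ischemic duration")


@dataclass(frozen=True)
class PermittivitySpectrum:
    """One measured (or simulated) permittivity spectrum."""

    grid: FrequencyGrid
    eps_real: np.ndarray
    eps_imag: np.ndarray
    meta: SpecimenMeta | None = None

    def __post_init__(self):
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_imag", ei)
        n = len(self.grid)
        if er.shape != (n,) or ei.shape != (n,):
            raise SpectrumError("eps_real/eps_imag must match the grid length")
        if not (np.all(np.isfinite(er)) and np.all(np.isfinite(ei))):
            raise SpectrumError("non-finite permittivity values")
        if np.any(er <= 0):
            raise SpectrumError("eps_real must be strictly positive")
        if np.any(ei < 0):
            raise SpectrumError("eps_imag must be non-negative")

    @property
    def complex_permittivity(self) -> np.ndarray:
        """eps* = eps' - j eps''."""
        return self.eps_real - 1j * self.eps_imag

    @property
    def conductivity(self) -> np.ndarray:
        """Dielectric conductivity sigma = eps'' eps0 2*pi*f, S/m."""
        return loss_to_conductivity(self.eps_imag, self.grid.points)


def loss_to_conductivity(eps_imag, f):
    """Convert dielectric loss eps'' to conductivity sigma = eps'' eps0 2*pi*f (S/m)."""
    eps_imag = np.asarray(eps_imag, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise SpectrumError("frequency must be positive")
    if np.any(eps_imag < 0):
        raise SpectrumError("eps_imag must be non-negative")
    return eps_imag * EPS0 * 2.0 * np.pi * f


def conductivity_to_loss(sigma, f):
    """Inverse of :func:`loss_to_conductivity`."""
    sigma = np.asarray(sigma, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise SpectrumError("frequency must be positive")
    if np.any(sigma < 0):
        raise SpectrumError("conductivity must be non-negative")
    return sigma / (EPS0 * 2.0 * np.pi * f)


def relative_change(
    test: PermittivitySpectrum, control: PermittivitySpectrum
) -> pd.DataFrame:
    """Per-frequency percentage change of eps' and sigma against a control.

    Returns a DataFrame with columns ``frequency_hz``, ``delta_eps_real_pct``
    (100*(eps' - eps'_c)/eps'_c) and ``delta_sigma_pct`` (analogous on the
    derived conductivities).
    """
    if test.grid != control.grid:
        raise GridMismatchError("test and control spectra are on different grids")
    if np.any(control.eps_real == 0):
        raise SpectrumError("control eps_real contains zeros")
    sig_c = control.conductivity
    if np.any(sig_c == 0):
        raise SpectrumError("control conductivity contains zeros")
    d_eps = 100.0 * (test.eps_real - control.eps_real) / control.eps_real
    d_sig = 100.0 * (test.conductivity - sig_c) / sig_c
    return pd.DataFrame(
        {
            "frequency_hz": test.grid.points,
            "delta_eps_real_pct": d_eps,
            "delta_sigma_pct": d_sig,
        }
    )


def restrict_band(
    s: PermittivitySpectrum, f_min: float, f_max: float
) -> PermittivitySpectrum:
    """Sub-spectrum on grid points with f_min <= f <= f_max (metadata kept)."""
    if f_min >= f_max:
        raise BandError("f_min must be below f_max")
    mask = (s.grid.points >= f_min) & (s.grid.points <= f_max)
    if mask.sum() < 2:
        raise BandError(
            f"band [{f_min:g}, {f_max:g}] Hz keeps {int(mask.sum())} grid point(s); "
            "need at least 2"
        )
    pts = s.grid.points[mask]
    grid = FrequencyGrid(pts, band=(max(f_min, s.grid.band[0]), min(f_max, s.grid.band[1])))
    return PermittivitySpectrum(grid, s.eps_real[mask], s.eps_imag[mask], s.meta)


# ---------------------------------------------------------------------------
# CSV I/O (long format, one row per frequency point)

CSV_COLUMNS = [
    "subject_id",
    "case_id",
    "phase",
    "ischemia_h",
    "reperfusion_h",
    "replicate",
    "frequency_hz",
    "eps_real",
    "eps_imag",
]

_GROUP_KEYS = CSV_COLUMNS[:6]


def write_spectra_csv(spectra: Iterable[PermittivitySpectrum], path) -> None:
    """Write spectra to a long-format CSV (full float precision)."""
    frames = []
    for s in spectra:
        if s.meta is None:
            raise SpectrumError("cannot write a spectrum without metadata")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.meta.subject_id,
                    "case_id": s.meta.case_id,
                    "phase": s.meta.phase,
                    "ischemia_h": s.meta.ischemia_h,
                    "reperfusion_h": s.meta.reperfusion_h,
                    "replicate": s.meta.replicate,
                    "frequency_hz": s.grid.points,
                    "eps_real": s.eps_real,
                    "eps_imag": s.eps_imag,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path) -> list[PermittivitySpectrum]:
    """Read a long-format spectra CSV back into a list of spectra.

    Rows are grouped into one spectrum per (subject, case, phase, hours,
    replicate).  Frequencies must be strictly increasing within each group.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(f"missing columns: {missing}")
    for col in ("frequency_hz", "eps_real", "eps_imag"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SpectraParseError(f"NaN in column {col!r} at row {row}")
    spectra = []
    for key, g in df.groupby(_GROUP_KEYS, sort=False):
        f = g["frequency_hz"].to_numpy(dtype=float)
        if not np.all(np.diff(f) > 0):
            first_bad = int(g.index[np.flatnonzero(np.diff(f) <= 0)[0] + 1])
            raise SpectraParseError(
                f"non-monotone frequency at row {first_bad} in group {key}"
            )
        meta = SpecimenMeta(
            subject_id=str(key[0]),
            case_id=int(key[1]),
            phase=str(key[2]),
            ischemia_h=float(key[3]),
            reperfusion_h=float(key[4]),
            replicate=int(key[5]),
        )
        spectra.append(
            PermittivitySpectrum(
                FrequencyGrid(f),
                g["eps_real"].to_numpy(dtype=float),
                g["eps_imag"].to_numpy(dtype=float),
                meta,
            )
        )
    return spectra
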