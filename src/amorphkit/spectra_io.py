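"""Data model and delimited-text I/O for dielectric spectra, relaxation maps,
dissolution profiles and run configuration.

Units are fixed throughout the package: temperature in K, frequency in Hz,
dielectric loss dimensionless, time in minutes, volume in mL, disc area in
cm^2, concentration in mg mL^-1.  No unit inference is performed.

Spectrum files are long-format delimited text (comma or tab, auto-detected)
with columns ``temperature_K``, ``frequency_Hz``, ``eps_loss`` and an optional
``eps_storage`` pass-through.  Dissolution files have ``time_min`` plus one
``conc_rep<i>`` column per replicate; disc geometry travels in ``# key: value``
header comments or is supplied by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: Minimum number of frequency points for a spectrum to be fit-eligible.
MIN_POINTS = 8
#: Minimum frequency span (decades) for fit eligibility.
MIN_DECADES = 2.0


class RelaxationSource(str, Enum):
    """Provenance of a relaxation-map point."""

    HN_FIT = "hn_fit"
    MASTER_SHIFT = "master_shift"


@dataclass(frozen=True)
class LossSpectrum:
    """One temperature's dielectric loss spectrum, the pipeline's atomic input.

    Parameters
    ----------
    temperature : float
        Measurement temperature in kelvin.
    frequencies : ndarray
        Strictly increasing, positive frequencies in Hz.
    loss : ndarray
        Dielectric loss ``eps''`` at each frequency (dimensionless).
    label : str
        Free-text sample descriptor, e.g. ``"vitrified"`` or ``"cryomilled"``.
    storage : ndarray or None
        Optional real-permittivity pass-through; unused by the fits.
    """

    temperature: float
    frequencies: np.ndarray
    loss: np.ndarray
    label: str = ""
    storage: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        e = np.asarray(self.loss, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "loss", e)
        if f.ndim != 1 or e.shape != f.shape:
            raise ValueError("frequencies and loss must be 1-D and equal length")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValueError("frequencies must be finite and positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(e)):
            raise ValueError("loss values must be finite")
        if not np.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError("temperature must be positive and finite")
        if self.storage is not None:
            s = np.asarray(self.storage, dtype=float)
            if s.shape != f.shape:
                raise ValueError("storage must match frequency grid")
            object.__setattr__(self, "storage", s)

    @property
    def n_points(self) -> int:
        return self.frequencies.size

    @property
    def decades(self) -> float:
        """Frequency span in decades."""
        return float(np.log10(self.frequencies[-1] / self.frequencies[0]))

    def is_fit_eligible(self) -> bool:
        """At least ``MIN_POINTS`` points spanning at least ``MIN_DECADES``."""
        return self.n_points >= MIN_POINTS and self.decades >= MIN_DECADES


@dataclass
class SpectrumSet:
    """Ordered collection of spectra, sorted ascending in temperature."""

    spectra: list[LossSpectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = sorted(self.spectra, key=lambda s: s.temperature)
        temps = [s.temperature for s in self.spectra]
        if len(set(temps)) != len(temps):
            raise ValueError("temperatures must be unique within a SpectrumSet")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.spectra])

    def at(self, temperature: float, atol: float = 1e-6) -> LossSpectrum:
        for s in self.spectra:
            if abs(s.temperature - temperature) <= atol:
                return s
        raise KeyError(f"no spectrum at T = {temperature} K")


@dataclass(frozen=True)
class RelaxationPoint:
    """One (T, log10 tau_alpha) point of the relaxation map."""

    temperature: float
    log10_tau_alpha: float
    source: RelaxationSource
    uncertainty: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "source", RelaxationSource(self.source))
        if not np.isfinite(self.uncertainty) or self.uncertainty < 0:
            raise ValueError("uncertainty must be finite and >= 0")
        if not np.isfinite(self.log10_tau_alpha):
            raise ValueError("log10_tau_alpha must be finite")


@dataclass
class RelaxationMap:
    """Collection of relaxation points, measured (HN fit) or predicted."""

    points: list[RelaxationPoint]

    def __post_init__(self):
        self.points = sorted(self.points, key=lambda p: p.temperature)

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def subset(self, source: RelaxationSource | str) -> "RelaxationMap":
        source = RelaxationSource(source)
        return RelaxationMap([p for p in self.points if p.source == source])

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature for p in self.points])

    @property
    def log10_tau(self) -> np.ndarray:
        return np.array([p.log10_tau_alpha for p in self.points])


@dataclass
class DissolutionProfile:
    """Replicate concentration-time curves from a stationary-disc test.

    ``concentrations`` has shape (n_replicates, n_times); all replicates share
    the time grid.  ``volume`` in mL, ``disc_area`` in cm^2.
    """

    times: np.ndarray
    concentrations: np.ndarray
    volume: float
    disc_area: float
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise FormatError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if c.shape[1] != t.size:
            raise ValueError("replicates must share the time grid")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and >= 0")
        if self.volume <= 0 or self.disc_area <= 0:
            raise ValueError("volume and disc_area must be positive")
        self.times = t
        self.concentrations = c

    @property
    def n_replicates(self) -> int:
        return self.concentrations.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SPECTRUM_COLUMNS = ("temperature_K", "frequency_Hz", "eps_loss")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    body = "".join(
        line for line in path.read_text().splitlines(keepends=True)
        if not line.startswith("#")
    )
    if not body.strip():
        raise EmptyInputError(f"{path} contains no data")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} contains no data")
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")
    return df


def read_spectrum_set(path: str | Path, label: str = "") -> SpectrumSet:
    """Read a long-format spectrum table into a validated :class:`SpectrumSet`.

    Rows with non-positive frequency or non-finite loss are dropped with a
    logged count; missing columns raise :class:`FormatError`.
    """
    df = _read_table(path)
    for col in _SPECTRUM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    n0 = len(df)
    df = df[np.isfinite(df["frequency_Hz"]) & (df["frequency_Hz"] > 0)]
    df = df[np.isfinite(df["eps_loss"])]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("read_spectrum_set: dropped %d invalid row(s) from %s", dropped, path)
    if df.empty:
        raise EmptyInputError(f"{path}: all rows invalid")
    spectra = []
    for temp, grp in df.groupby("temperature_K", sort=True):
        grp = grp.sort_values("frequency_Hz")
        storage = grp["eps_storage"].to_numpy() if "eps_storage" in grp.columns else None
        spectra.append(
            LossSpectrum(
                temperature=float(temp),
                frequencies=grp["frequency_Hz"].to_numpy(),
                loss=grp["eps_loss"].to_numpy(),
                label=label,
                storage=storage,
            )
        )
    return SpectrumSet(spectra, metadata={"path": str(path), "dropped_rows": dropped})


def write_spectrum_set(sset: SpectrumSet, path: str | Path) -> None:
    """Write a spectrum set as long-format CSV with 17 significant digits."""
    frames = []
    for s in sset:
        d = {
            "temperature_K": np.full(s.n_points, s.temperature),
            "frequency_Hz": s.frequencies,
            "eps_loss": s.loss,
        }
        if s.storage is not None:
            d["eps_storage"] = s.storage
        frames.append(pd.DataFrame(d))
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_dissolution(
    path: str | Path,
    volume: float | None = None,
    disc_area: float | None = None,
    label: str = "",
) -> DissolutionProfile:
    """Read a dissolution profile (``time_min``, ``conc_rep*`` columns).

    ``volume`` (mL) and ``disc_area`` (cm^2) may come from ``# volume_mL:`` /
    ``# disc_area_cm2:`` header comments or the keyword arguments; keyword
    arguments win.
    """
    path = Path(path)
    header = _parse_header_metadata(path)
    volume = volume if volume is not None else header.get("volume_mL")
    disc_area = disc_area if disc_area is not None else header.get("disc_area_cm2")
    if volume is None or disc_area is None:
        raise FormatError(f"{path}: volume and disc_area must be in header or arguments")
    df = _read_table(path)
    if "time_min" not in df.columns:
        raise FormatError(f"missing required column 'time_min' in {path}")
    rep_cols = [c for c in df.columns if c.startswith("conc_rep")]
    if not rep_cols:
        raise FormatError(f"no 'conc_rep*' columns in {path}")
    df = df.sort_values("time_min")
    times = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: non-monotone times")
    conc = df[rep_cols].to_numpy(dtype=float).T
    logger.info("read_dissolution: %d replicate(s), %d time points", len(rep_cols), times.size)
    return DissolutionProfile(times, conc, float(volume), float(disc_area), label=label)


def write_dissolution(profile: DissolutionProfile, path: str | Path) -> None:
    path = Path(path)
    cols = {"time_min": profile.times}
    for i in range(profile.n_replicates):
        cols[f"conc_rep{i + 1}"] = profile.concentrations[i]
    with open(path, "w") as fh:
        fh.write(f"# volume_mL: {profile.volume:.17g}\n")
        fh.write(f"# disc_area_cm2: {profile.disc_area:.17g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def _parse_header_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val.strip()
    return meta


def read_relaxation_map(path: str | Path) -> RelaxationMap:
    df = _read_table(path)
    for col in ("temperature_K", "log10_tau_alpha_s", "source"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    unc = df["uncertainty"] if "uncertainty" in df.columns else np.zeros(len(df))
    points = [
        RelaxationPoint(float(t), float(lt), RelaxationSource(src), float(u))
        for t, lt, src, u in zip(df["temperature_K"], df["log10_tau_alpha_s"], df["source"], unc)
    ]
    return RelaxationMap(points)


def write_relaxation_map(rmap: RelaxationMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "temperature_K": [p.temperature for p in rmap],
            "log10_tau_alpha_s": [p.log10_tau_alpha for p in rmap],
            "source": [p.source.value for p in rmap],
            "uncertainty": [p.uncertainty for p in rmap],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_config(path: str | Path) -> dict:
    """Read a nested key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        raise EmptyInputError(f"{path} is empty")
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return cfg
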