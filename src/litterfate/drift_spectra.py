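"""Litter-quality compound ratios from mid-infrared (DRIFT) spectra.

Ratios are ratios of *maximum* absorbance inside fixed diagnostic
wavenumber windows (aliphatic C-H, aromatic C=C/COO-, amide I-III, lignin
C=C, polysaccharide C-O). They are invariant under positive scaling of
the absorbance, so they can be computed on raw or max-normalised spectra.
No baseline correction is applied before ratio computation (instrument-
side corrections are assumed to have happened upstream); a hook exists
but defaults to off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandSet",
    "DEFAULT_BANDS",
    "normalize_max",
    "band_max",
    "compound_ratios",
    "average_replicates",
    "read_spectrum_csv",
    "read_jcamp",
]

#: Ratio name -> (numerator band, denominator band)
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "Aliphatic:Aromatic": ("Aliphatic", "Aromatic"),
    "Polysaccharide:Lignin": ("Polysaccharides", "Lignin"),
    "Aliphatic:AmideI": ("Aliphatic", "AmideI"),
    "Aliphatic:AmideII": ("Aliphatic", "AmideII"),
    "Aliphatic:AmideIII": ("Aliphatic", "AmideIII"),
}


@dataclass
class Spectrum:
    """A wavenumber/absorbance pair on a strictly monotone grid.

    Grids are accepted ascending or descending and canonicalised to
    descending wavenumber (instrument convention, 4000 -> 400 cm-1).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.shape != ab.shape:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        d = np.diff(wn)
        if np.all(d > 0):
            wn, ab = wn[::-1], ab[::-1]
        elif not np.all(d < 0):
            raise ValueError("wavenumber grid must be strictly monotone")
        self.wavenumbers, self.absorbance = wn, ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.absorbance * factor)


@dataclass(frozen=True)
class BandSet:
    """Named diagnostic wavenumber windows [low, high] in cm-1."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        for name, (low, high) in self.bands.items():
            if not low < high:
                raise ValueError(f"band {name!r}: low must be < high")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "Aliphatic": (2915.0, 2990.0),
    "Aromatic": (1600.0, 1660.0),
    "AmideI": (1652.0, 1658.0),
    "AmideII": (1540.0, 1548.0),
    "Lignin": (1504.0, 1512.0),
    "AmideIII": (1230.0, 1320.0),
    "Polysaccharides": (1140.0, 1180.0),
}


def normalize_max(spectrum: Spectrum) -> Spectrum:
    """Divide by the maximum absorbance (idempotent; max becomes 1)."""
    peak = float(np.max(spectrum.absorbance))
    if peak <= 0:
        raise ValueError("cannot normalise a spectrum with non-positive maximum")
    return Spectrum(spectrum.wavenumbers.copy(), spectrum.absorbance / peak,
                    normalised=True)


def band_max(spectrum: Spectrum, band: tuple[float, float], *,
             name: str | None = None) -> float:
    """Maximum absorbance over grid points inside [low, high], inclusive.

    Ties are broken toward the lower wavenumber (irrelevant for the value
    itself, but fixes which grid point a reported peak position refers to).
    """
    low, high = band
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not mask.any():
        label = f" {name!r}" if name else ""
        raise ValueError(
            f"band{label} [{low}, {high}] cm-1 contains no grid points")
    return float(np.max(spectrum.absorbance[mask]))


def band_argmax(spectrum: Spectrum, band: tuple[float, float]) -> float:
    """Wavenumber of the in-band maximum (lowest wavenumber on ties)."""
    low, high = band
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not mask.any():
        raise ValueError(f"band [{low}, {high}] cm-1 contains no grid points")
    wn, ab = spectrum.wavenumbers[mask], spectrum.absorbance[mask]
    peak = ab.max()
    return float(wn[np.isclose(ab, peak)].min())


def compound_ratios(spectrum: Spectrum, bands: BandSet | None = None,
                    *, subtract_min_baseline: bool = False) -> dict[str, float]:
    """All compound ratios (numerator band max / denominator band max)."""
    bands = bands or BandSet()
    spec = spectrum
    if subtract_min_baseline:
        spec = Spectrum(spectrum.wavenumbers.copy(),
                        spectrum.absorbance - spectrum.absorbance.min())
    out = {}
    for ratio, (num, den) in RATIO_DEFINITIONS.items():
        denom = band_max(spec, bands[den], name=den)
        if denom <= 0:
            raise ValueError(f"denominator band {den!r} has non-positive maximum")
        out[ratio] = band_max(spec, bands[num], name=num) / denom
    return out


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra on a common grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("replicate spectra are not on a common grid")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(grid.copy(), mean)


def read_spectrum_csv(path) -> Spectrum:
    """Read a wavenumber_cm1/absorbance CSV."""
    df = pd.read_csv(path)
    return Spectrum(df["wavenumber_cm1"].to_numpy(),
                    df["absorbance"].to_numpy())


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader for single-block (X++(Y..Y)) AFFN data.

    Supports the tabular XYDATA form with XFACTOR/YFACTOR scaling; enough
    for plain exported IR spectra. Compressed (SQZ/DIF/DUP) encodings are
    not supported.
    """
    xfactor = yfactor = 1.0
    deltax: float | None = None
    lines: list[tuple[float, list[float]]] = []
    in_data = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.replace(" ", "").upper()
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "XYDATA":
                    if "(X++(Y..Y))" not in value.replace(" ", ""):
                        raise ValueError(f"unsupported XYDATA form: {value!r}")
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data:
                parts = line.replace(",", " ").split()
                try:
                    nums = [float(p) for p in parts]
                except ValueError as exc:
                    raise ValueError(
                        f"non-AFFN data line in {path}: {line!r}") from exc
                if len(nums) < 2:
                    raise ValueError(f"data line with no Y values: {line!r}")
                lines.append((nums[0] * xfactor,
                              [n * yfactor for n in nums[1:]]))
    if not lines or sum(len(y) for _, y in lines) < 2:
        raise ValueError(f"no XYDATA found in {path}")
    if deltax is None:
        if len(lines) < 2:
            raise ValueError(
                f"{path}: cannot infer X spacing (single data line, no ##DELTAX=)")
        x0_first, y_first = lines[0]
        deltax = (lines[1][0] - x0_first) / len(y_first)
    xs: list[float] = []
    ys: list[float] = []
    for x0, yvals in lines:
        xs.extend(x0 + j * deltax for j in range(len(yvals)))
        ys.extend(yvals)
    return Spectrum(np.asarray(xs), np.asarray(ys))
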