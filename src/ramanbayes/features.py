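"""Diagnostic band fluxes and variance-based band inspection.

Nine bands carry the diagnostic signal: six in the fingerprint region
(600-1800 cm^-1) covering DNA|RNA ring breathing and O-P-O backbone (796),
proline/hydroxyproline/tyrosine and saccharides (828), hydroxyapatite
phosphate and glycogen (1048), lipids/collagen/amide III (1300), lipids and
fatty acids (1437), amide I / lipid C=C (1654); and the high-wavenumber
C-H stretch triplet at 2853, 2896, 2937 cm^-1 (2800-3000 cm^-1). Tumor
tissue shows a relative rise of 796 against 828 and a collapse of the HW
triplet.

The band flux is the preprocessed intensity at the channel nearest the
band center. Feature sets: FP (6 bands), HW (3 bands), FPHW (all 9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError
from .io import RamanSpectrum, SpectrumSet

FEATURE_SETS = ("FPHW", "FP", "HW")

DEFAULT_BAND_CENTERS = (
    796.0,
    828.0,
    1048.0,
    1300.0,
    1437.0,
    1654.0,
    2853.0,
    2896.0,
    2937.0,
)

DEFAULT_BAND_LABELS = (
    "796 DNA|RNA ring breathing / O-P-O backbone",
    "828 proline, tyrosine, saccharides",
    "1048 hydroxyapatite phosphate, glycogen",
    "1300 lipids, collagen, amide III",
    "1437 lipids, fatty acids, collagen",
    "1654 amide I, lipid C=C",
    "2853 lipid CH2 symmetric stretch",
    "2896 protein/lipid CH asymmetric stretch",
    "2937 C-H lipids, proteins, glycogen, DNA|RNA",
)

FINGERPRINT_RANGE = (600.0, 1800.0)
HIGH_WAVENUMBER_RANGE = (2800.0, 3000.0)
DEAD_ZONE = (1800.0, 2800.0)


@dataclass
class BandSet:
    """Ordered diagnostic band centers and the FP/HW/FPHW index groups."""

    bands: list[tuple[float, str]] = field(
        default_factory=lambda: list(zip(DEFAULT_BAND_CENTERS, DEFAULT_BAND_LABELS))
    )
    groups: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if self.groups is None:
            fp = [
                i
                for i, (c, _) in enumerate(self.bands)
                if FINGERPRINT_RANGE[0] <= c <= FINGERPRINT_RANGE[1]
            ]
            hw = [
                i
                for i, (c, _) in enumerate(self.bands)
                if HIGH_WAVENUMBER_RANGE[0] <= c <= HIGH_WAVENUMBER_RANGE[1]
            ]
            self.groups = {"FP": fp, "HW": hw, "FPHW": fp + hw}
        for name, idx in self.groups.items():
            for i in idx:
                if not 0 <= i < len(self.bands):
                    raise ValidationError(f"group {name}: band index {i} out of range")

    @property
    def centers(self) -> np.ndarray:
        return np.array([c for c, _ in self.bands])

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.bands]

    def group_centers(self, feature_set: str) -> np.ndarray:
        return self.centers[self.group_indices(feature_set)]

    def group_indices(self, feature_set: str) -> list[int]:
        if feature_set not in self.groups:
            raise ValidationError(
                f"unknown feature set {feature_set!r}; expected one of "
                f"{sorted(self.groups)}"
            )
        return self.groups[feature_set]


def default_band_set() -> BandSet:
    return BandSet()


@dataclass
class FeatureMatrix:
    """Targets x band-flux matrix for one feature-set tag."""

    target_ids: list[str]
    feature_set: str
    values: np.ndarray
    band_labels: list[str]
    band_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D")
        if self.values.shape[0] != len(self.target_ids):
            raise ValidationError("row count must match number of targets")
        if self.values.shape[1] != len(self.band_labels):
            raise ValidationError("column count must match number of band labels")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.band_labels)
        df.insert(0, "target_id", self.target_ids)
        return df


def variance_spectrum(sset: SpectrumSet) -> np.ndarray:
    """Channel-wise sample variance (ddof=1) across a spectrum set.

    High-variance channels are the information-rich regions from which
    diagnostic bands were chosen.
    """
    if len(sset) < 2:
        raise ValidationError("variance_spectrum needs at least 2 spectra")
    return np.var(sset.intensity_matrix(), axis=0, ddof=1)


def suggest_bands(
    variance: np.ndarray,
    axis: np.ndarray,
    n: int,
    exclusions: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Return the wavenumbers of the ``n`` tallest local variance maxima.

    Exclusion ranges (inclusive, in cm^-1) drop candidate peaks, e.g.
    regions at risk of surgical-ink contamination. This is an analyst aid
    only; the default :class:`BandSet` is never altered by it.
    """
    variance = np.asarray(variance, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if len(variance) != len(axis):
        raise ValidationError("variance and axis lengths differ")
    peaks, _ = find_peaks(variance)
    centers = axis[peaks]
    heights = variance[peaks]
    if exclusions:
        keep = np.ones(len(peaks), dtype=bool)
        for lo, hi in exclusions:
            keep &= ~((centers >= lo) & (centers <= hi))
        centers, heights = centers[keep], heights[keep]
    order = np.argsort(heights)[::-1]
    centers = centers[order]
    if len(centers) < n:
        warnings.warn(
            f"only {len(centers)} local maxima found (requested {n})",
            stacklevel=2,
        )
        return centers
    return centers[:n]


def extract_band_flux(spectrum: RamanSpectrum, center: float) -> float:
    """Intensity at the channel nearest ``center``.

    Equidistant neighbours resolve to the lower wavenumber.
    """
    w = spectrum.wavenumbers
    if center < w[0] or center > w[-1]:
        raise ValidationError(
            f"band center {center} cm^-1 outside axis range "
            f"[{w[0]}, {w[-1]}]"
        )
    idx = int(np.argmin(np.abs(w - center)))  # argmin picks the lower index on ties
    return float(spectrum.intensities[idx])


def band_flux_window(
    spectrum: RamanSpectrum, center: float, half_width: float = 6.0
) -> float:
    """Mean intensity over center +/- half_width cm^-1 (optional variant)."""
    w = spectrum.wavenumbers
    if center < w[0] or center > w[-1]:
        raise ValidationError(f"band center {center} cm^-1 outside axis range")
    mask = np.abs(w - center) <= half_width
    if not mask.any():
        return extract_band_flux(spectrum, center)
    return float(spectrum.intensities[mask].mean())


def build_feature_matrix(
    sset: SpectrumSet,
    bands: BandSet | None = None,
    feature_set: str = "FPHW",
) -> FeatureMatrix:
    """Band-flux matrix for the requested feature group, columns in band order."""
    bands = bands or default_band_set()
    idx = bands.group_indices(feature_set)
    centers = [bands.bands[i][0] for i in idx]
    labels = [bands.bands[i][1] for i in idx]
    w = sset.axis
    for c, lab in zip(centers, labels):
        if c < w[0] or c > w[-1]:
            raise ValidationError(
                f"band '{lab}' at {c} cm^-1 lies outside the spectral axis"
            )
    cols = [int(np.argmin(np.abs(w - c))) for c in centers]
    values = sset.intensity_matrix()[:, cols]
    return FeatureMatrix(
        target_ids=sset.target_ids,
        feature_set=feature_set,
        values=values,
        band_labels=labels,
        band_centers=np.array(centers),
    )
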