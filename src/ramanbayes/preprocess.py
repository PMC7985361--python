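"""Spectral preprocessing: crop, arPLS baseline removal, smoothing, normalization.

The pipeline applied to every spectrum, in order:

1. crop to the analysis window (default 600-3350 cm^-1, dropping the
   low-shift region contaminated by fiber fluorescence and laser bleed),
2. subtract an arPLS fluorescence baseline,
3. Savitzky-Golay smoothing (window 7 channels),
4. mean-center,
5. divide by the Euclidean norm.

After step 5 every spectrum is a unit vector with zero mean; band fluxes
read off these vectors are therefore relative, not absolute, intensities.
The silent detector region near 1800-2800 cm^-1 is retained in the data
(it is removed only by plotting helpers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import ConvergenceWarning, ValidationError
from .io import RamanSpectrum, SpectrumSet


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    crop_min/crop_max : analysis window in cm^-1 (inclusive both ends).
    arpls_lambda : smoothness penalty of the baseline estimator; larger
        values give stiffer baselines. Default 1e5.
    arpls_ratio : relative-change-of-weights termination threshold, 1e-3.
    savgol_window : odd channel count of the smoothing window, default 7.
    savgol_order : polynomial order of the smoother, default 3.
    """

    crop_min: float = 600.0
    crop_max: float = 3350.0
    arpls_lambda: float = 1e5
    arpls_ratio: float = 1e-3
    arpls_max_iter: int = 100
    savgol_window: int = 7
    savgol_order: int = 3

    def __post_init__(self) -> None:
        if not self.crop_min < self.crop_max:
            raise ValidationError("crop_min must be < crop_max")
        if self.arpls_lambda <= 0:
            raise ValidationError("arpls_lambda must be positive")
        if not 0 < self.arpls_ratio < 1:
            raise ValidationError("arpls_ratio must be in (0, 1)")
        if self.arpls_max_iter < 1:
            raise ValidationError("arpls_max_iter must be >= 1")
        if self.savgol_window < 3 or self.savgol_window % 2 == 0:
            raise ValidationError("savgol_window must be odd and >= 3")
        if not 0 <= self.savgol_order < self.savgol_window:
            raise ValidationError("savgol_order must be < savgol_window")


def crop_spectrum(
    spectrum: RamanSpectrum, lo: float, hi: float
) -> RamanSpectrum:
    """Keep only channels with lo <= wavenumber <= hi (inclusive)."""
    if not lo < hi:
        raise ValidationError("crop bounds must satisfy lo < hi")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"{spectrum.target_id}: fewer than 2 channels survive crop "
            f"[{lo}, {hi}]"
        )
    return spectrum.with_values(
        spectrum.wavenumbers[mask], spectrum.intensities[mask]
    )


@dataclass
class ArplsResult:
    """Baseline plus solver diagnostics (and the per-iteration trace).

    ``iterates[k]`` is the baseline solved at iteration k from the weight
    vector ``weights[k]``, so external solvers can replay every step.
    """

    baseline: np.ndarray
    n_iter: int
    converged: bool
    iterates: list[np.ndarray] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)


def _second_difference(n: int) -> sparse.csc_matrix:
    return sparse.diags(
        [1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc"
    )


def arpls_baseline(
    intensities: Sequence[float],
    lam: float = 1e5,
    ratio: float = 1e-3,
    max_iter: int = 100,
    full_output: bool = False,
) -> np.ndarray | ArplsResult:
    """Asymmetrically reweighted penalized least-squares baseline.

    Each iteration solves the weighted penalized system

        (W + lam * D' D) z = W y

    where D is the second-difference operator, then reweights the residual
    d = y - z asymmetrically: channels well above the baseline (Raman
    peaks) get weights near 0 through a logistic function of the residual
    scaled by the mean m and standard deviation s of the negative
    residuals, w = 1 / (1 + exp(2 (d - (2s - m)) / s)). Iteration stops
    when the relative change of the weight vector drops below ``ratio``
    or after ``max_iter`` iterations (the last iterate is then returned
    with a :class:`ConvergenceWarning`).
    """
    y = np.asarray(intensities, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValidationError("arpls_baseline needs a 1-D signal with >= 5 channels")
    if lam <= 0:
        raise ValidationError("lam must be positive")
    if not 0 < ratio < 1:
        raise ValidationError("ratio must be in (0, 1)")
    n = len(y)
    D = _second_difference(n)
    H = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    converged = False
    iterates: list[np.ndarray] = []
    weight_trace: list[np.ndarray] = []
    it = 0
    for it in range(1, max_iter + 1):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + H, w * y)
        if full_output:
            iterates.append(z.copy())
            weight_trace.append(w.copy())
        d = y - z
        if np.linalg.norm(d) <= 1e-10 * max(np.linalg.norm(y), 1.0):
            # baseline reproduces the signal to rounding error (peak-free
            # input); further reweighting would only chase float noise
            converged = True
            break
        dn = d[d < 0]
        if dn.size == 0:
            # baseline everywhere at or below the signal; weights stable
            converged = True
            break
        m = dn.mean()
        s = dn.std()
        if s <= np.finfo(float).tiny:
            converged = True
            break
        expo = np.clip(2.0 * (d - (2.0 * s - m)) / s, -500.0, 500.0)
        wt = 1.0 / (1.0 + np.exp(expo))
        crit = np.linalg.norm(w - wt) / np.linalg.norm(w)
        w = wt
        if crit < ratio:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"arPLS did not converge within {max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    if full_output:
        return ArplsResult(z, it, converged, iterates, weight_trace)
    return z


def subtract_baseline(
    spectrum: RamanSpectrum, baseline: Sequence[float]
) -> RamanSpectrum:
    """Replace intensities with intensities - baseline (negatives allowed)."""
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) != spectrum.n_channels:
        raise ValidationError(
            f"{spectrum.target_id}: baseline length {len(baseline)} != "
            f"{spectrum.n_channels} channels"
        )
    return spectrum.with_values(intensities=spectrum.intensities - baseline)


def savgol_smooth(
    spectrum: RamanSpectrum, window: int = 7, order: int = 3
) -> RamanSpectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    Edges use a polynomial fit on the truncated window (scipy's ``interp``
    mode), so no mirrored samples are invented. Polynomials of degree
    <= ``order`` pass through unchanged.
    """
    if window % 2 == 0 or window < order + 1:
        raise ValidationError("window must be odd and >= order + 1")
    if window > spectrum.n_channels:
        raise ValidationError(
            f"{spectrum.target_id}: window {window} exceeds "
            f"{spectrum.n_channels} channels"
        )
    smoothed = savgol_filter(
        spectrum.intensities, window_length=window, polyorder=order, mode="interp"
    )
    return spectrum.with_values(intensities=smoothed)


def normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Mean-center, then scale to unit Euclidean norm."""
    centered = spectrum.intensities - spectrum.intensities.mean()
    nrm = np.linalg.norm(centered)
    if nrm < 1e-300 or not np.isfinite(nrm):
        raise ValidationError(
            f"{spectrum.target_id}: constant spectrum cannot be normalized"
        )
    return spectrum.with_values(intensities=centered / nrm)


def preprocess_spectrum(
    spectrum: RamanSpectrum, config: PreprocessConfig | None = None
) -> RamanSpectrum:
    """crop -> arPLS subtract -> Savitzky-Golay -> mean-center + unit norm."""
    config = config or PreprocessConfig()
    s = crop_spectrum(spectrum, config.crop_min, config.crop_max)
    baseline = arpls_baseline(
        s.intensities,
        lam=config.arpls_lambda,
        ratio=config.arpls_ratio,
        max_iter=config.arpls_max_iter,
    )
    s = subtract_baseline(s, baseline)
    s = savgol_smooth(s, config.savgol_window, config.savgol_order)
    return normalize(s)


def preprocess_all(
    sset: SpectrumSet, config: PreprocessConfig | None = None
) -> SpectrumSet:
    """Apply the full preprocessing chain to every spectrum of a set."""
    config = config or PreprocessConfig()
    out = []
    for s in sset:
        try:
            out.append(preprocess_spectrum(s, config))
        except ValidationError as exc:
            raise ValidationError(
                f"preprocessing failed for target {s.target_id}: {exc}"
            ) from exc
    return SpectrumSet(out)
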