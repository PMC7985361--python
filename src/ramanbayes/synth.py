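"""Seeded generator of synthetic tissue Raman spectra.

The patient spectra behind this kind of study are never public, so the
generator provides test fixtures with the statistical structure the
pipeline assumes:

* healthy template — strong high-wavenumber C-H triplet (2853/2896/2937
  cm^-1), strong fingerprint lipid bands, and a DNA|RNA band at 796 cm^-1
  weaker than the neighbouring 828 cm^-1 band;
* tumor template — collapsed high-wavenumber signal (amplitudes scaled by
  ``hw_collapse_factor``), weaker lipids, and an inverted 796:828 ratio;
* boundary targets — convex mixtures m*tumor + (1-m)*healthy;
* a broad fluorescence baseline (decaying exponential plus a quadratic),
  additive Gaussian noise, and optional narrow surgical-ink contaminant
  peaks placed away from every diagnostic band.

Peaks are pseudo-Voigt profiles. Everything is deterministic given
(config, m, seed). Amplitudes are synthetic design choices reproducing the
qualitative healthy/tumor contrasts, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import DEFAULT_BAND_CENTERS
from .io import RamanSpectrum, SpectrumSet

HEALTHY = "healthy"
TUMOR = "tumor"

# Relative peak amplitudes at each center (diagnostic bands + filler bands).
# Healthy: weak 796 vs 828, strong lipids, strong HW triplet.
HEALTHY_AMPLITUDES = {
    700.0: 0.25,
    796.0: 0.30,
    828.0: 0.60,
    937.0: 0.30,
    1004.0: 0.45,
    1048.0: 0.50,
    1126.0: 0.35,
    1260.0: 0.50,
    1300.0: 1.20,
    1437.0: 1.50,
    1654.0: 1.00,
    1745.0: 0.40,
    2853.0: 2.00,
    2896.0: 1.80,
    2937.0: 2.20,
}

# Tumor: 796 > 828 (DNA|RNA rise), lipid loss; HW filled in from the
# healthy triplet scaled by hw_collapse_factor in GeneratorConfig.
TUMOR_FP_AMPLITUDES = {
    700.0: 0.25,
    796.0: 0.90,
    828.0: 0.55,
    937.0: 0.35,
    1004.0: 0.55,
    1048.0: 0.60,
    1126.0: 0.35,
    1260.0: 0.45,
    1300.0: 0.70,
    1437.0: 0.60,
    1654.0: 0.90,
    1745.0: 0.20,
}

HW_CENTERS = (2853.0, 2896.0, 2937.0)

MIN_INK_BAND_DISTANCE = 15.0  # cm^-1


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, eta: float = 0.5
) -> np.ndarray:
    """Linear blend of a Lorentzian (eta) and a Gaussian (1-eta), unit peak."""
    hwhm = fwhm / 2.0
    lor = hwhm**2 / ((x - center) ** 2 + hwhm**2)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gau = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return eta * lor + (1.0 - eta) * gau


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-spectrum generator.

    Defaults emulate the instrument axis (2 cm^-1 steps over 600-3000
    cm^-1, oversampling the ~4.5 cm^-1 resolution; widen to 147-3350 to
    exercise cropping), ~20 cm^-1 FWHM tissue bands, a fluorescence
    baseline a few times taller than the Raman peaks, and detector noise
    ~1% of the strongest band.
    """

    axis_min: float = 600.0
    axis_max: float = 3000.0
    axis_step: float = 2.0
    peak_width: float = 20.0
    healthy_amplitudes: dict[float, float] = field(
        default_factory=lambda: dict(HEALTHY_AMPLITUDES)
    )
    tumor_amplitudes: dict[float, float] | None = None
    hw_collapse_factor: float = 0.3
    baseline_scale: float = 5.0
    noise_sd: float = 0.02
    poisson_like_noise: bool = False
    ink_peak_positions: tuple[float, ...] = (700.0, 950.0, 1510.0, 2200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_min >= self.axis_max or self.axis_step <= 0:
            raise ValidationError("invalid axis specification")
        if self.tumor_amplitudes is None:
            t = dict(TUMOR_FP_AMPLITUDES)
            for c in HW_CENTERS:
                t[c] = self.healthy_amplitudes[c] * self.hw_collapse_factor
            self.tumor_amplitudes = t
        h, t = self.healthy_amplitudes, self.tumor_amplitudes
        if not t[796.0] / t[828.0] > 1.0:
            raise ValidationError("tumor 796:828 amplitude ratio must exceed 1")
        if not h[796.0] / h[828.0] < 1.0:
            raise ValidationError("healthy 796:828 amplitude ratio must be < 1")
        if not np.mean([t[c] for c in HW_CENTERS]) < np.mean(
            [h[c] for c in HW_CENTERS]
        ):
            raise ValidationError("tumor HW amplitudes must be depleted vs healthy")
        for pos in self.ink_peak_positions:
            if min(abs(pos - c) for c in DEFAULT_BAND_CENTERS) < MIN_INK_BAND_DISTANCE:
                raise ValidationError(
                    f"ink position {pos} within {MIN_INK_BAND_DISTANCE} cm^-1 "
                    "of a diagnostic band"
                )

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_max - self.axis_min) / self.axis_step)) + 1
        return self.axis_min + self.axis_step * np.arange(n)


@dataclass
class SyntheticTarget:
    """A generated spectrum plus its ground truth."""

    spectrum: RamanSpectrum
    truth_class: str
    mix_fraction: float
    histology_quintile: int

    def __post_init__(self) -> None:
        expected = TUMOR if self.mix_fraction >= 0.5 else HEALTHY
        if self.truth_class != expected:
            raise ValidationError("truth_class inconsistent with mix fraction")


def _template(
    axis: np.ndarray,
    amplitudes: dict[float, float],
    width: float,
    jitter: dict[float, float] | None = None,
) -> np.ndarray:
    y = np.zeros_like(axis)
    for center, amp in amplitudes.items():
        if jitter:
            amp = amp * jitter.get(center, 1.0)
        y += amp * pseudo_voigt(axis, center, width)
    return y


def _fluorescence_baseline(axis: np.ndarray, scale: float) -> np.ndarray:
    u = axis - axis[0]
    return scale * (1.3 * np.exp(-u / 1000.0) + 0.4 + 1.0e-4 * u - 4.0e-8 * u**2)


def _quintile_from_m(m: float) -> int:
    return int(min((0, 25, 50, 75, 100), key=lambda q: abs(q - 100.0 * m)))


def generate_spectrum(
    config: GeneratorConfig,
    m: float,
    seed: int,
    target_id: str | None = None,
    patient_id: str = "sim-patient",
    amplitude_jitter: float = 0.0,
    region_label: str | None = None,
) -> SyntheticTarget:
    """One synthetic target at healthy->tumor mixture fraction ``m``.

    intensity = (1-m) healthy + m tumor + fluorescence baseline + noise.
    ``amplitude_jitter`` (e.g. 0.1 for +/-10%) draws one multiplicative
    factor per band, mimicking biological variation between targets.
    """
    if not 0.0 <= m <= 1.0:
        raise ValidationError(f"mix fraction {m} outside [0, 1]")
    rng = np.random.default_rng(seed)
    axis = config.axis()
    jitter_h = jitter_t = None
    if amplitude_jitter > 0:
        jitter_h = {
            c: rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter)
            for c in config.healthy_amplitudes
        }
        jitter_t = {
            c: rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter)
            for c in config.tumor_amplitudes
        }
    healthy = _template(axis, config.healthy_amplitudes, config.peak_width, jitter_h)
    tumor = _template(axis, config.tumor_amplitudes, config.peak_width, jitter_t)
    signal = (1.0 - m) * healthy + m * tumor
    y = signal + _fluorescence_baseline(axis, config.baseline_scale)
    if config.noise_sd > 0:
        if config.poisson_like_noise:
            y = y + rng.normal(0.0, config.noise_sd, len(axis)) * np.sqrt(
                np.clip(y, 0.0, None) / max(y.max(), 1e-12)
            )
        else:
            y = y + rng.normal(0.0, config.noise_sd, len(axis))
    quintile = _quintile_from_m(m)
    cls = TUMOR if m >= 0.5 else HEALTHY
    if target_id is None:
        target_id = f"sim-m{m:g}-s{seed}"
    spectrum = RamanSpectrum(
        target_id=target_id,
        patient_id=patient_id,
        wavenumbers=axis,
        intensities=y,
        histology_quintile=quintile,
        region_label=region_label,
    )
    return SyntheticTarget(spectrum, cls, m, quintile)


def generate_dataset(
    config: GeneratorConfig,
    n_healthy: int,
    n_tumor: int,
    n_boundary: int = 0,
    seed: int | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """A full synthetic dataset plus its ground-truth manifest.

    Healthy targets at m=0, tumor at m=1, boundary targets uniformly at
    m in {0.25, 0.5, 0.75}. Each target gets +/-10% per-band amplitude
    jitter and a fresh noise realization. The manifest carries target_id,
    patient_id, true class, m, derived histology quintile and region label.
    """
    if min(n_healthy, n_tumor, n_boundary) < 0:
        raise ValidationError("counts must be non-negative")
    if n_healthy + n_tumor + n_boundary < 4:
        raise ValidationError("dataset needs at least 4 targets")
    if seed is None:
        seed = config.seed
    master = np.random.default_rng(seed)
    plan: list[tuple[str, float, str]] = []
    for i in range(n_healthy):
        plan.append((f"h{i:03d}", 0.0, "H"))
    for i in range(n_tumor):
        plan.append((f"t{i:03d}", 1.0, "T"))
    for i in range(n_boundary):
        m = float(master.choice((0.25, 0.5, 0.75)))
        plan.append((f"b{i:03d}", m, "B"))
    spectra = []
    rows = []
    for i, (tid, m, region) in enumerate(plan):
        sub_seed = int(master.integers(0, 2**31 - 1))
        patient = f"sim-p{i % 8:02d}"
        tgt = generate_spectrum(
            config,
            m,
            seed=sub_seed,
            target_id=tid,
            patient_id=patient,
            amplitude_jitter=0.1,
            region_label=region,
        )
        spectra.append(tgt.spectrum)
        rows.append(
            {
                "target_id": tid,
                "patient_id": patient,
                "true_class": tgt.truth_class,
                "mix_fraction": m,
                "histology_quintile": tgt.histology_quintile,
                "region_label": region,
            }
        )
    return SpectrumSet(spectra), pd.DataFrame(rows)


def add_ink_peaks(
    spectrum: RamanSpectrum,
    positions: tuple[float, ...],
    amplitude: float,
    seed: int | None = None,
    fwhm: float = 8.0,
) -> RamanSpectrum:
    """Add narrow surgical-ink contaminant peaks.

    Positions must stay >= 15 cm^-1 away from every diagnostic band so
    that contamination never compromises the nine band fluxes.
    """
    if amplitude < 0:
        raise ValidationError("ink amplitude must be >= 0")
    w = spectrum.wavenumbers
    rng = np.random.default_rng(seed)
    y = spectrum.intensities.copy()
    for pos in positions:
        if pos < w[0] or pos > w[-1]:
            raise ValidationError(f"ink position {pos} outside spectral axis")
        dist = min(abs(pos - c) for c in DEFAULT_BAND_CENTERS)
        if dist < MIN_INK_BAND_DISTANCE:
            raise ValidationError(
                f"ink position {pos} within {MIN_INK_BAND_DISTANCE} cm^-1 of a "
                "diagnostic band"
            )
        amp = amplitude * (rng.uniform(0.8, 1.2) if seed is not None else 1.0)
        y += amp * pseudo_voigt(w, pos, fwhm)
    return spectrum.with_values(intensities=y)
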