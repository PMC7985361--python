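"""Plotting helpers. The silent 1800-2800 cm^-1 detector region is kept in
the data structures everywhere else; only here is it dropped for display."""

from __future__ import annotations

import numpy as np

from .features import DEAD_ZONE
from .io import RamanSpectrum


def dead_zone_mask(wavenumbers: np.ndarray) -> np.ndarray:
    """True for channels outside the silent 1800-2800 cm^-1 region."""
    w = np.asarray(wavenumbers)
    return ~((w > DEAD_ZONE[0]) & (w < DEAD_ZONE[1]))


def plot_spectra(
    spectra: list[RamanSpectrum],
    ax=None,
    drop_dead_zone: bool = True,
    offset: float = 0.0,
    **kwargs,
):
    """Overlay spectra on one axes, optionally hiding the dead zone."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    for i, s in enumerate(spectra):
        w, y = s.wavenumbers, s.intensities + i * offset
        if drop_dead_zone:
            keep = dead_zone_mask(w)
            y = np.where(keep, y, np.nan)  # break the line across the gap
        ax.plot(w, y, label=s.target_id, **kwargs)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    return ax
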