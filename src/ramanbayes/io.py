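"""Plain-text I/O for Raman spectra, manifests, and ensemble reports.

All tables are tab-delimited text; comment lines start with ``#``. Spectrum
files are two columns (wavenumber in cm^-1, intensity in detector counts),
one channel per row. Floats are written with 12 significant digits so a
read(write(x)) round trip recovers values well beyond 9 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IngestionError, ValidationError

VALID_QUINTILES = (0, 25, 50, 75, 100)
VALID_REGIONS = ("T", "H", "B")

_FLOAT_FMT = "%.12g"


@dataclass
class RamanSpectrum:
    """A single target's Raman spectrum with provenance metadata.

    Parameters
    ----------
    target_id, patient_id : str
        Identifiers carried through the whole pipeline.
    wavenumbers : array-like
        Strictly increasing Raman shift axis in cm^-1.
    intensities : array-like
        Detector counts (arbitrary units), same length as the axis.
        May be negative after baseline subtraction / mean centering.
    histology_quintile : int, optional
        Pathologist's tumor-involvement estimate in {0, 25, 50, 75, 100}.
    region_label : str, optional
        Macroscopic site assessment: T (tumor), H (healthy), B (boundary).
    """

    target_id: str
    patient_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    histology_quintile: int | None = None
    region_label: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError(
                f"{self.target_id}: wavenumbers and intensities must be 1-D"
            )
        if len(self.wavenumbers) != len(self.intensities):
            raise ValidationError(
                f"{self.target_id}: axis length {len(self.wavenumbers)} != "
                f"intensity length {len(self.intensities)}"
            )
        if len(self.wavenumbers) < 2:
            raise ValidationError(
                f"{self.target_id}: a spectrum needs at least 2 channels"
            )
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValidationError(
                f"{self.target_id}: wavenumber axis must be strictly increasing"
            )
        if self.histology_quintile is not None:
            q = int(self.histology_quintile)
            if q not in VALID_QUINTILES:
                raise ValidationError(
                    f"{self.target_id}: histology_quintile {q!r} not in "
                    f"{VALID_QUINTILES}"
                )
            self.histology_quintile = q
        if self.region_label is not None and self.region_label not in VALID_REGIONS:
            raise ValidationError(
                f"{self.target_id}: region_label {self.region_label!r} not in "
                f"{VALID_REGIONS}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.wavenumbers)

    def with_values(
        self,
        wavenumbers: np.ndarray | None = None,
        intensities: np.ndarray | None = None,
    ) -> "RamanSpectrum":
        """Copy of this spectrum with replaced data, metadata preserved."""
        return replace(
            self,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=self.intensities if intensities is None else intensities,
        )


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis."""

    spectra: list[RamanSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("SpectrumSet must contain at least one spectrum")
        ids = [s.target_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate target_id(s): {dupes}")
        axis = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if len(s.wavenumbers) != len(axis) or not np.array_equal(
                s.wavenumbers, axis
            ):
                raise ValidationError(
                    f"{s.target_id}: axis differs from the set's common axis"
                )

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def target_ids(self) -> list[str]:
        return [s.target_id for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """n_targets x n_channels matrix in dataset order."""
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[RamanSpectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]


def read_spectrum_file(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavenumber, intensity) delimited text file."""
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except OSError as exc:
        raise IngestionError(f"cannot read spectrum file {path}: {exc}") from exc
    except ValueError as exc:
        raise IngestionError(f"malformed spectrum file {path}: {exc}") from exc
    if data.shape[1] < 2:
        raise IngestionError(f"{path}: expected two columns, got {data.shape[1]}")
    return data[:, 0], data[:, 1]


def _interp_onto(
    axis: np.ndarray, w: np.ndarray, y: np.ndarray
) -> np.ndarray:
    return np.interp(axis, w, y)


def read_manifest(path: str | Path) -> SpectrumSet:
    """Ingest a manifest table and the spectrum files it references.

    The manifest is tab-delimited with header columns ``target_id``,
    ``patient_id``, ``file`` and optional ``histology_quintile`` and
    ``region_label``. Relative file paths resolve against the manifest's
    directory. Spectra whose native axes differ from the first spectrum's
    are linearly interpolated onto it, restricted to the wavenumber range
    covered by every spectrum. Manifest row order defines dataset order.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype={"target_id": str})
    except OSError as exc:
        raise IngestionError(f"cannot read manifest {path}: {exc}") from exc
    required = {"target_id", "patient_id", "file"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"manifest {path} missing columns {sorted(missing)}")
    ids = table["target_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"manifest {path}: duplicate target_id(s) {dupes}")

    raw: list[tuple[pd.Series, np.ndarray, np.ndarray]] = []
    for _, row in table.iterrows():
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        try:
            w, y = read_spectrum_file(fpath)
        except IngestionError as exc:
            raise IngestionError(
                f"target {row['target_id']}: {exc}"
            ) from exc
        if not np.all(np.diff(w) > 0):
            raise ValidationError(
                f"target {row['target_id']}: non-monotone wavenumber axis in {fpath}"
            )
        raw.append((row, w, y))

    # Harmonize axes: common grid = first spectrum's axis over the overlap.
    lo = max(w[0] for _, w, _ in raw)
    hi = min(w[-1] for _, w, _ in raw)
    if lo > hi:
        raise ValidationError("spectra have no overlapping wavenumber range")
    first_axis = raw[0][1]
    axis = first_axis[(first_axis >= lo) & (first_axis <= hi)]
    if len(axis) < 2:
        raise ValidationError("overlapping wavenumber range covers < 2 channels")

    spectra = []
    for row, w, y in raw:
        if len(w) == len(axis) and np.array_equal(w, axis):
            yy = y
        else:
            yy = _interp_onto(axis, w, y)
        q = row.get("histology_quintile")
        q = None if q is None or pd.isna(q) else int(q)
        r = row.get("region_label")
        r = None if r is None or pd.isna(r) else str(r)
        spectra.append(
            RamanSpectrum(
                target_id=str(row["target_id"]),
                patient_id=str(row["patient_id"]),
                wavenumbers=axis.copy(),
                intensities=np.asarray(yy, dtype=float),
                histology_quintile=q,
                region_label=r,
            )
        )
    return SpectrumSet(spectra)


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> Path:
    """Write one spectrum as two-column tab-delimited text."""
    if not isinstance(spectrum, RamanSpectrum):
        raise ValidationError("write_spectrum expects a RamanSpectrum")
    path = Path(path)
    lines = [f"# target_id={spectrum.target_id}\tpatient_id={spectrum.patient_id}"]
    if spectrum.histology_quintile is not None:
        lines.append(f"# histology_quintile={spectrum.histology_quintile}")
    if spectrum.region_label is not None:
        lines.append(f"# region_label={spectrum.region_label}")
    for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{_FLOAT_FMT % w}\t{_FLOAT_FMT % y}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IngestionError(f"cannot write {path}: {exc}") from exc
    return path


def write_manifest(
    sset: SpectrumSet,
    out_dir: str | Path,
    manifest_name: str = "manifest.tsv",
    extra_columns: Mapping[str, Sequence] | None = None,
) -> Path:
    """Write every spectrum of a set plus a manifest referencing them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(sset):
        fname = f"{s.target_id}.txt"
        write_spectrum(s, out_dir / fname)
        row = {
            "target_id": s.target_id,
            "patient_id": s.patient_id,
            "file": fname,
            "histology_quintile": s.histology_quintile,
            "region_label": s.region_label,
        }
        if extra_columns:
            for k, v in extra_columns.items():
                row[k] = v[i]
        rows.append(row)
    table = pd.DataFrame(rows)
    mpath = out_dir / manifest_name
    table.to_csv(mpath, sep="\t", index=False)
    return mpath


REPORT_COLUMNS = [
    "target_id",
    "P_FPHW",
    "P_FP",
    "P_HW",
    "V_RA_FPHW",
    "V_RA_FP",
    "V_RA_HW",
    "V_ER",
    "max_P",
    "quintile_bin",
    "flag_VRA",
    "flag_VER",
]


def write_report(
    records: Iterable,
    path: str | Path,
    metadata: Mapping | None = None,
) -> tuple[Path, Path]:
    """Write the per-target ensemble report plus a JSON summary.

    ``records`` is a collection of :class:`~ramanbayes.uncertainty.EnsembleRecord`.
    The report is a 12-column tab-delimited table (one row per target); the
    summary (``<path>.summary.json``) carries bin counts and any metadata
    (flag thresholds, variance conventions, seeds).
    """
    records = list(records)
    if not records:
        raise ValidationError("write_report requires at least one record")
    rows = []
    for r in records:
        flagged = [tag for tag, v in sorted(r.flag_VRA.items()) if v]
        rows.append(
            {
                "target_id": r.target_id,
                "P_FPHW": r.mean_probs["FPHW"],
                "P_FP": r.mean_probs["FP"],
                "P_HW": r.mean_probs["HW"],
                "V_RA_FPHW": r.v_ra["FPHW"],
                "V_RA_FP": r.v_ra["FP"],
                "V_RA_HW": r.v_ra["HW"],
                "V_ER": r.V_ER,
                "max_P": r.max_prob,
                "quintile_bin": r.quintile_bin,
                "flag_VRA": ";".join(flagged) if flagged else "-",
                "flag_VER": int(r.flag_VER),
            }
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# per-target ensemble report; positive class = tumor\n")
        table.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    bin_counts = {b: 0 for b in range(1, 6)}
    for r in records:
        bin_counts[r.quintile_bin] += 1
    summary = {
        "n_targets": len(records),
        "bin_counts": {str(k): v for k, v in bin_counts.items()},
        "positive_class": "tumor",
    }
    if metadata:
        summary["metadata"] = dict(metadata)
    spath = Path(str(path) + ".summary.json")
    spath.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return path, spath


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back an ensemble report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t", comment="#")
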