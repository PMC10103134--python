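"""Reading, validation, and preprocessing of cryogenic gas-phase IR spectra.

The preprocessing chain turns a library of wavenumber/intensity traces of
mass-selected glycosaminoglycan (GAG) ions into the feature matrix consumed
by the classifiers:

1. raw ion signal is normalised to laser pulse energy and repetition rate,
2. every spectrum is linearly interpolated onto a common 2 cm⁻¹ grid over a
   shared wavenumber window (1010–1786 cm⁻¹ by default),
3. the grid is integrated in fixed windows of 7 consecutive grid points
   (≈15 cm⁻¹) to reduce dimensionality,
4. the resulting bins are min–max scaled to [0, 1] *per spectrum*, because
   helium-nanodroplet band intensities are not quantitative,
5. auxiliary columns are appended: anion charge state, number of sulfate
   groups, and (for libraries containing linker-labelled oligosaccharides)
   a binary reducing-end linker label.

With the defaults this yields 56 spectral bins and 59 total features for a
joint disaccharide/tetrasaccharide library.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAG_CLASSES",
    "OLIGOMER_LENGTHS",
    "LINKERS",
    "DEFAULT_RANGE",
    "SpectraError",
    "SpectrumParseError",
    "EmptyIntersectionError",
    "CoverageError",
    "RawScanRecord",
    "Spectrum",
    "SampleMetadata",
    "SpectrumLibrary",
    "BinningConfig",
    "FeatureMatrix",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "load_library",
    "write_library",
    "normalize_raw_signal",
    "shared_range",
    "interpolate_to_grid",
    "bin_intensities",
    "minmax_scale",
    "assemble_features",
]

GAG_CLASSES = ("HS", "CS")
OLIGOMER_LENGTHS = ("di", "tetra", "hexa")
LINKERS = ("none", "aminopentyl", "p-methoxyphenyl")

#: Canonical fingerprint window (cm⁻¹) shared by the reference library.
DEFAULT_RANGE = (1010.0, 1786.0)


class SpectraError(ValueError):
    """Base class for spectrum-handling errors."""


class SpectrumParseError(SpectraError):
    """Malformed spectrum file; message names the offending line."""


class EmptyIntersectionError(SpectraError):
    """The spectra share no common wavenumber range."""


class CoverageError(SpectraError):
    """A spectrum does not cover the requested wavenumber window."""


@dataclass(frozen=True)
class RawScanRecord:
    """One raw scan point before laser normalisation.

    ``ion_signal`` is the time-of-flight ion count at ``wavenumber``;
    ``pulse_energy`` (mJ) and ``repetition_rate`` (Hz) describe the laser at
    that scan position.
    """

    wavenumber: float
    ion_signal: float
    pulse_energy: float
    repetition_rate: float

    def __post_init__(self) -> None:
        if self.wavenumber <= 0:
            raise SpectraError(f"wavenumber must be positive, got {self.wavenumber}")
        if self.ion_signal < 0:
            raise SpectraError(f"ion_signal must be non-negative, got {self.ion_signal}")
        if self.pulse_energy <= 0 or self.repetition_rate <= 0:
            raise SpectraError(
                "pulse_energy and repetition_rate must be positive "
                f"(got {self.pulse_energy}, {self.repetition_rate})"
            )


@dataclass
class Spectrum:
    """A single IR trace: strictly ascending wavenumbers with intensities."""

    sample_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectraError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise SpectraError(
                f"{self.sample_id}: wavenumber/intensity length mismatch "
                f"({self.wavenumbers.size} vs {self.intensities.size})"
            )
        if self.wavenumbers.size < 2:
            raise SpectraError(f"{self.sample_id}: need at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectraError(f"{self.sample_id}: wavenumbers must be strictly increasing")
        if np.any(self.intensities < 0):
            raise SpectraError(f"{self.sample_id}: intensities must be non-negative")

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


@dataclass(frozen=True)
class SampleMetadata:
    """Structural annotation of one GAG sample.

    The four sulfation flags record whether the motif occurs *anywhere* in
    the molecule; ``sulfation_degree`` counts sulfate groups and ``charge``
    is the magnitude of the anion charge state.
    """

    sample_id: str
    gag_class: str
    ns_flag: bool
    s2_flag: bool
    s4_flag: bool
    s6_flag: bool
    charge: int
    sulfation_degree: int
    oligomer_length: str
    linker: str = "none"

    def __post_init__(self) -> None:
        if self.gag_class not in GAG_CLASSES:
            raise SpectraError(f"{self.sample_id}: gag_class must be one of {GAG_CLASSES}")
        if self.oligomer_length not in OLIGOMER_LENGTHS:
            raise SpectraError(
                f"{self.sample_id}: oligomer_length must be one of {OLIGOMER_LENGTHS}"
            )
        if self.linker not in LINKERS:
            raise SpectraError(f"{self.sample_id}: linker must be one of {LINKERS}")
        if self.charge < 1:
            raise SpectraError(f"{self.sample_id}: charge must be >= 1")
        if self.sulfation_degree < 0:
            raise SpectraError(f"{self.sample_id}: sulfation_degree must be >= 0")
        if self.oligomer_length == "di" and self.linker != "none":
            raise SpectraError(f"{self.sample_id}: disaccharides carry no linker")
        if self.oligomer_length != "di" and self.linker == "none":
            raise SpectraError(
                f"{self.sample_id}: {self.oligomer_length}saccharides require a linker"
            )

    @property
    def has_linker(self) -> bool:
        return self.linker != "none"


@dataclass
class SpectrumLibrary:
    """Paired spectra and metadata with unique sample ids."""

    samples: list[tuple[Spectrum, SampleMetadata]]

    def __post_init__(self) -> None:
        ids = [meta.sample_id for _, meta in self.samples]
        if len(set(ids)) != len(ids):
            raise SpectraError("sample_ids must be unique")
        for spec, meta in self.samples:
            if spec.sample_id != meta.sample_id:
                raise SpectraError(
                    f"spectrum id {spec.sample_id!r} does not match metadata id "
                    f"{meta.sample_id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [meta.sample_id for _, meta in self.samples]

    def get(self, sample_id: str) -> tuple[Spectrum, SampleMetadata]:
        for spec, meta in self.samples:
            if meta.sample_id == sample_id:
                return spec, meta
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "SpectrumLibrary":
        """New library restricted to ``sample_ids`` (library order preserved)."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return SpectrumLibrary([(s, m) for s, m in self.samples if m.sample_id in wanted])


@dataclass
class BinningConfig:
    """Grid and binning parameters of the preprocessing chain.

    ``window_points`` consecutive grid points are integrated into one bin;
    with the 2 cm⁻¹ grid the default of 7 points is the ≈15 cm⁻¹ window that
    yields 56 bins over 1010–1786 cm⁻¹.  ``range_lo``/``range_hi`` crop all
    spectra to a fixed window; ``None`` means "use the largest shared range
    of the library".  ``include_linker_label`` of ``None`` auto-detects:
    the linker column is appended iff any sample carries a linker.
    """

    grid_step: float = 2.0
    window_points: int = 7
    range_lo: float | None = DEFAULT_RANGE[0]
    range_hi: float | None = DEFAULT_RANGE[1]
    include_linker_label: bool | None = None

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise SpectraError("grid_step must be positive")
        if self.window_points < 1:
            raise SpectraError("window_points must be >= 1")


@dataclass
class FeatureMatrix:
    """n × k feature matrix: scaled spectral bins plus auxiliary columns."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    spectral_bin_count: int
    bin_centers: np.ndarray

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        names = list(df.columns)
        centers = [float(n[3:]) for n in names if n.startswith("wn_")]
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=names,
            sample_ids=[str(i) for i in df.index],
            spectral_bin_count=len(centers),
            bin_centers=np.array(centers),
        )


# ---------------------------------------------------------------------------
# file IO


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise SpectraError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_spectrum(path: str | Path, dialect: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, intensity) spectrum file.

    Rows are sorted by ascending wavenumber; duplicate wavenumbers are merged
    by mean intensity.  An optional single header line is skipped.
    """
    path = Path(path)
    delim = _delimiter(path, dialect)
    pairs: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            cells = [c.strip() for c in row if c.strip()]
            if len(cells) != 2:
                raise SpectrumParseError(f"{path.name} line {lineno}: expected 2 columns")
            try:
                pairs.append((float(cells[0]), float(cells[1])))
            except ValueError:
                if lineno == 1 and not pairs:
                    continue  # header line
                raise SpectrumParseError(
                    f"{path.name} line {lineno}: non-numeric value in {cells!r}"
                ) from None
    if len(pairs) < 2:
        raise SpectraError(f"{path.name}: need at least 2 data points")
    w = np.array([p[0] for p in pairs])
    i = np.array([p[1] for p in pairs])
    w, i = _sort_and_merge(w, i)
    return Spectrum(sample_id=path.stem, wavenumbers=w, intensities=i)


def write_spectrum(spectrum: Spectrum, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    delim = _delimiter(path, dialect)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["wavenumber_cm1", "intensity"])
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            writer.writerow([f"{w:.6g}", f"{i:.8g}"])


_MANIFEST_COLUMNS = [
    "sample_id",
    "gag_class",
    "ns",
    "s2",
    "s4",
    "s6",
    "charge",
    "sulfation_degree",
    "oligomer_length",
    "linker",
]


def read_manifest(path: str | Path) -> list[SampleMetadata]:
    """Read the TSV sample manifest into metadata records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraError(f"manifest missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMetadata(
                sample_id=str(r["sample_id"]),
                gag_class=str(r["gag_class"]),
                ns_flag=bool(int(r["ns"])),
                s2_flag=bool(int(r["s2"])),
                s4_flag=bool(int(r["s4"])),
                s6_flag=bool(int(r["s6"])),
                charge=int(r["charge"]),
                sulfation_degree=int(r["sulfation_degree"]),
                oligomer_length=str(r["oligomer_length"]),
                linker=str(r["linker"]),
            )
        )
    return out


def write_manifest(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "gag_class": m.gag_class,
            "ns": int(m.ns_flag),
            "s2": int(m.s2_flag),
            "s4": int(m.s4_flag),
            "s6": int(m.s6_flag),
            "charge": m.charge,
            "sulfation_degree": m.sulfation_degree,
            "oligomer_length": m.oligomer_length,
            "linker": m.linker,
        }
        for m in metadata
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def load_library(
    spectra_dir: str | Path, manifest_path: str | Path, dialect: str | None = None
) -> SpectrumLibrary:
    """Load a library from a directory of spectrum files plus a manifest.

    Spectrum files are located as ``<sample_id>.csv`` / ``<sample_id>.tsv``.
    """
    spectra_dir = Path(spectra_dir)
    samples = []
    for meta in read_manifest(manifest_path):
        for ext in (".csv", ".tsv"):
            candidate = spectra_dir / f"{meta.sample_id}{ext}"
            if candidate.exists():
                spec = read_spectrum(candidate, dialect)
                break
        else:
            raise SpectraError(f"no spectrum file found for sample {meta.sample_id!r}")
        samples.append((spec, meta))
    return SpectrumLibrary(samples)


def write_library(library: SpectrumLibrary, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for spec, _ in library.samples:
        write_spectrum(spec, out_dir / f"{spec.sample_id}.csv")
    write_manifest([m for _, m in library.samples], out_dir / "manifest.tsv")


# ---------------------------------------------------------------------------
# preprocessing operations


def _sort_and_merge(w: np.ndarray, i: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(w, kind="stable")
    w, i = w[order], i[order]
    uw, inverse = np.unique(w, return_inverse=True)
    if uw.size == w.size:
        return w, i
    sums = np.bincount(inverse, weights=i)
    counts = np.bincount(inverse)
    return uw, sums / counts


def normalize_raw_signal(
    records: Sequence[RawScanRecord], sample_id: str = ""
) -> Spectrum:
    """Normalise raw ion signal to laser pulse energy × repetition rate.

    Records at the same wavenumber are averaged after normalisation.
    """
    if not records:
        raise SpectraError("no scan records")
    w = np.array([r.wavenumber for r in records])
    i = np.array(
        [r.ion_signal / (r.pulse_energy * r.repetition_rate) for r in records]
    )
    w, i = _sort_and_merge(w, i)
    return Spectrum(sample_id=sample_id, wavenumbers=w, intensities=i)


def shared_range(spectra: Sequence[Spectrum]) -> tuple[float, float]:
    """Largest wavenumber interval covered by every spectrum."""
    if not spectra:
        raise SpectraError("need at least one spectrum")
    lo = max(s.range[0] for s in spectra)
    hi = min(s.range[1] for s in spectra)
    if lo >= hi:
        raise EmptyIntersectionError(
            f"spectra share no wavenumber range (intersection [{lo}, {hi}])"
        )
    return lo, hi


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    npts = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(npts)


def interpolate_to_grid(
    spectrum: Spectrum, lo: float, hi: float, step: float
) -> np.ndarray:
    """Linearly interpolate a spectrum onto the grid lo, lo+step, … ≤ hi.

    No extrapolation: the grid must lie inside the measured range.
    """
    if step <= 0:
        raise SpectraError("step must be positive")
    w0, w1 = spectrum.range
    eps = 1e-9
    if lo < w0 - eps or hi > w1 + eps:
        raise CoverageError(
            f"{spectrum.sample_id}: grid [{lo}, {hi}] outside measured range "
            f"[{w0}, {w1}]"
        )
    grid = _grid(lo, hi, step)
    return np.interp(grid, spectrum.wavenumbers, spectrum.intensities)


def bin_intensities(grid_values: np.ndarray, config: BinningConfig) -> np.ndarray:
    """Integrate consecutive blocks of ``window_points`` grid points.

    Bin value is the rectangle-rule integral (sum × grid step); a final
    partial block is kept as its own bin, so there are ceil(len/window)
    bins.
    """
    v = np.asarray(grid_values, dtype=float)
    if v.size == 0:
        raise SpectraError("empty grid")
    wp = config.window_points
    nbins = -(-v.size // wp)
    padded = np.zeros(nbins * wp)
    padded[: v.size] = v
    return padded.reshape(nbins, wp).sum(axis=1) * config.grid_step


def minmax_scale(bins: np.ndarray) -> np.ndarray:
    """Scale a vector to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(bins, dtype=float)
    if v.size == 0:
        raise SpectraError("empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def bin_centers_for(lo: float, hi: float, config: BinningConfig) -> np.ndarray:
    """Center wavenumber of each bin (mean of its grid points)."""
    grid = _grid(lo, hi, config.grid_step)
    wp = config.window_points
    nbins = -(-grid.size // wp)
    return np.array([grid[j * wp : (j + 1) * wp].mean() for j in range(nbins)])


def assemble_features(
    library: SpectrumLibrary, config: BinningConfig | None = None
) -> FeatureMatrix:
    """Build the classifier feature matrix from a spectrum library.

    Rows follow library order.  Columns are the per-spectrum scaled spectral
    bins, then ``charge`` and ``sulfation_degree``, and — when the library
    contains linker-labelled samples (or ``include_linker_label`` is forced
    on) — a binary ``linker_label``.
    """
    config = config or BinningConfig()
    if library.n == 0:
        raise SpectraError("empty library")
    spectra = [s for s, _ in library.samples]
    if config.range_lo is None or config.range_hi is None:
        lo, hi = shared_range(spectra)
    else:
        lo, hi = config.range_lo, config.range_hi
        if lo >= hi:
            raise SpectraError(f"invalid crop window [{lo}, {hi}]")
    include_linker = config.include_linker_label
    if include_linker is None:
        include_linker = any(meta.has_linker for _, meta in library.samples)

    rows = []
    for spec, meta in library.samples:
        w0, w1 = spec.range
        if lo < w0 - 1e-9 or hi > w1 + 1e-9:
            raise CoverageError(
                f"sample {meta.sample_id!r} does not cover [{lo}, {hi}] "
                f"(measured [{w0}, {w1}])"
            )
        bins = minmax_scale(
            bin_intensities(interpolate_to_grid(spec, lo, hi, config.grid_step), config)
        )
        aux = [float(meta.charge), float(meta.sulfation_degree)]
        if include_linker:
            aux.append(1.0 if meta.has_linker else 0.0)
        rows.append(np.concatenate([bins, aux]))

    centers = bin_centers_for(lo, hi, config)
    names = [f"wn_{c:g}" for c in centers] + ["charge", "sulfation_degree"]
    if include_linker:
        names.append("linker_label")
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        sample_ids=library.sample_ids,
        spectral_bin_count=centers.size,
        bin_centers=centers,
    )
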