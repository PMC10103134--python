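"""Synthetic GAG IR spectrum generator.

Emulates the band structure of cryogenic helium-nanodroplet spectra of
heparan sulfate (HS) and chondroitin sulfate (CS) oligosaccharides so that
every pipeline stage can be exercised on labeled data:

 - antisymmetric SO₃⁻ stretches in 1150–1350 cm⁻¹, with motif-specific
   sub-ranges per sulfation position (2-O and 6-O deliberately overlap, so
   6-O recovery is harder than 4-O),
 - amide II (1500–1600) and amide I (1600–1700) bands for N-acetylated
   samples only — the amide region is silent for N-sulfated ions, which is
   the dominant N-sulfation cue, together with a marker band near 1300 cm⁻¹,
 - a neutral-carboxyl ν(C=O) band whose center red-shifts with increasing
   sulfation degree (≈1753–1781 → 1739–1762 → ≈1712 cm⁻¹),
 - an antisymmetric COO⁻ stretch near 1664 cm⁻¹ for nonsulfated ions,
 - an unresolved C–O/C–C envelope below 1150 cm⁻¹ and weak class- and
   linker-dependent deformation bands.

Bands are Gaussians with jittered amplitudes and uniformly drawn centers
(conformer splitting is modeled as 1–3 sub-bands); white noise is added at a
configurable signal-to-noise ratio.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .spectra import SampleMetadata, Spectrum, SpectrumLibrary

__all__ = [
    "BandSpec",
    "BandLibrary",
    "SynthConfig",
    "default_band_library",
    "default_composition",
    "band_signal",
    "generate_spectrum",
    "generate_library",
]


@dataclass
class BandSpec:
    """One motif-conditional vibrational band.

    ``motif_condition`` decides from the sample metadata whether the band is
    present; the band center is drawn uniformly from ``center_range`` per
    sub-band, and the amplitude is jittered by ``amplitude_jitter``
    (fractional, uniform).
    """

    name: str
    motif_condition: Callable[[SampleMetadata], bool]
    center_range: tuple[float, float]
    relative_amplitude: float
    width_sigma: float = 6.0
    amplitude_jitter: float = 0.25
    n_subbands: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.center_range
        if not lo < hi:
            raise ValueError(f"{self.name}: center_range must satisfy lo < hi")
        if self.width_sigma <= 0:
            raise ValueError(f"{self.name}: width_sigma must be positive")
        if self.relative_amplitude <= 0:
            raise ValueError(f"{self.name}: relative_amplitude must be positive")


@dataclass
class BandLibrary:
    """A set of band specifications plus the scan grid they live on."""

    bands: list[BandSpec]
    grid: tuple[float, float, float] = (1000.0, 1800.0, 1.0)
    baseline_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        lo, hi, step = self.grid
        for band in self.bands:
            blo, bhi = band.center_range
            if blo < lo or bhi > hi:
                raise ValueError(f"grid does not cover band {band.name}")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


@dataclass
class SynthConfig:
    """Composition and noise settings of a generated library."""

    composition: list[SampleMetadata] | None = None
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def default_band_library() -> BandLibrary:
    """Band library with the motif-diagnostic fingerprint regions."""
    bands = [
        # unresolved C-O / C-C (+ symmetric sulfate) envelope of the core
        BandSpec("co_cc_envelope", lambda m: True, (1020.0, 1140.0), 0.7,
                 width_sigma=16.0, n_subbands=3),
        # weak backbone bands that differ between the two GAG classes
        BandSpec("cs_ring", lambda m: m.gag_class == "CS", (1055.0, 1075.0), 0.35),
        BandSpec("hs_ring", lambda m: m.gag_class == "HS", (1075.0, 1095.0), 0.35),
        # antisymmetric sulfate stretches, one sub-range per position;
        # 2-O and 6-O overlap on purpose
        BandSpec("so3_4o", lambda m: m.s4_flag, (1160.0, 1200.0), 1.0, n_subbands=2),
        BandSpec("so3_2o", lambda m: m.s2_flag, (1240.0, 1278.0), 1.0, n_subbands=2),
        BandSpec("so3_6o", lambda m: m.s6_flag, (1258.0, 1296.0), 1.0, n_subbands=2),
        # single strong N-sulfation marker near 1300
        BandSpec("ns_marker", lambda m: m.ns_flag, (1294.0, 1306.0), 1.0),
        # linker C-H / C-N deformations (any reducing-end linker)
        BandSpec("linker_ch", lambda m: m.has_linker, (1440.0, 1485.0), 0.4,
                 n_subbands=2),
        # amide bands only for N-acetylated ions; centers vary by a bin or
        # two across compounds, keeping the region reliably diagnostic
        BandSpec("amide_ii", lambda m: not m.ns_flag, (1520.0, 1545.0), 0.6,
                 n_subbands=2),
        BandSpec("amide_i", lambda m: not m.ns_flag, (1645.0, 1680.0), 0.9,
                 n_subbands=2),
        # charged carboxylate of nonsulfated ions
        BandSpec("coo_charged", lambda m: m.sulfation_degree == 0,
                 (1660.0, 1668.0), 0.8),
        # neutral carboxyl C=O, red-shifting with sulfation degree
        BandSpec("co_neutral_1s", lambda m: m.sulfation_degree == 1,
                 (1753.0, 1781.0), 0.5, n_subbands=2),
        BandSpec("co_neutral_2s", lambda m: m.sulfation_degree == 2,
                 (1739.0, 1762.0), 0.5, n_subbands=2),
        BandSpec("co_neutral_3s", lambda m: m.sulfation_degree >= 3,
                 (1706.0, 1718.0), 0.5),
    ]
    return BandLibrary(bands=bands)


def default_composition() -> list[SampleMetadata]:
    """The default 23-sample library: 16 disaccharides (8 CS + 8 HS), six
    aminopentyl-linked HS tetrasaccharides, one p-methoxyphenyl-linked HS
    hexasaccharide.  Flag combinations follow the commercially standard
    lyase-derived disaccharide panels; charges are plausible anion states
    for the given sulfation degree."""

    def di(sid, cls, ns=False, s2=False, s4=False, s6=False):
        deg = sum([ns, s2, s4, s6])
        return SampleMetadata(
            sample_id=sid, gag_class=cls, ns_flag=ns, s2_flag=s2, s4_flag=s4,
            s6_flag=s6, charge=1 if deg <= 1 else 2, sulfation_degree=deg,
            oligomer_length="di", linker="none",
        )

    def tetra(sid, s2=False):
        deg = 5 if s2 else 4
        return SampleMetadata(
            sample_id=sid, gag_class="HS", ns_flag=True, s2_flag=s2,
            s4_flag=False, s6_flag=True, charge=3, sulfation_degree=deg,
            oligomer_length="tetra", linker="aminopentyl",
        )

    return [
        di("cs-0s", "CS"),
        di("cs-2s", "CS", s2=True),
        di("cs-4s", "CS", s4=True),
        di("cs-6s", "CS", s6=True),
        di("cs-2s4s", "CS", s2=True, s4=True),
        di("cs-2s6s", "CS", s2=True, s6=True),
        di("cs-4s6s", "CS", s4=True, s6=True),
        di("cs-2s4s6s", "CS", s2=True, s4=True, s6=True),
        di("hs-0s", "HS"),
        di("hs-ns", "HS", ns=True),
        di("hs-2s", "HS", s2=True),
        di("hs-6s", "HS", s6=True),
        di("hs-ns2s", "HS", ns=True, s2=True),
        di("hs-ns6s", "HS", ns=True, s6=True),
        di("hs-2s6s", "HS", s2=True, s6=True),
        di("hs-ns2s6s", "HS", ns=True, s2=True, s6=True),
        tetra("tetra-01"),
        tetra("tetra-02"),
        tetra("tetra-03"),
        tetra("tetra-04"),
        tetra("tetra-05", s2=True),
        tetra("tetra-06", s2=True),
        SampleMetadata(
            sample_id="hexa-01", gag_class="HS", ns_flag=True, s2_flag=False,
            s4_flag=False, s6_flag=True, charge=4, sulfation_degree=6,
            oligomer_length="hexa", linker="p-methoxyphenyl",
        ),
    ]


def band_signal(
    meta: SampleMetadata, library: BandLibrary, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free band sum for one sample: (wavenumbers, signal)."""
    rng = np.random.default_rng(seed)
    w = library.wavenumbers()
    signal = np.zeros_like(w)
    for band in library.bands:
        if not band.motif_condition(meta):
            continue
        lo, hi = band.center_range
        for _ in range(band.n_subbands):
            center = rng.uniform(lo, hi)
            # each conformer sub-band carries the band's nominal strength:
            # droplet intensities are qualitative, not conserved
            amp = band.relative_amplitude * (
                1.0 + band.amplitude_jitter * rng.uniform(-1.0, 1.0)
            )
            signal += amp * np.exp(-0.5 * ((w - center) / band.width_sigma) ** 2)
    return w, signal


def generate_spectrum(
    meta: SampleMetadata,
    library: BandLibrary | None = None,
    snr: float = 10.0,
    seed: int = 0,
) -> Spectrum:
    """Generate one noisy spectrum; deterministic given (meta, seed)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    library = library or default_band_library()
    w, signal = band_signal(meta, library, seed)
    rng = np.random.default_rng((seed, 0x5EED))
    peak = signal.max() if signal.max() > 0 else 1.0
    sigma = peak / snr + library.baseline_noise_sigma * peak
    noisy = signal + rng.normal(0.0, sigma, size=w.size)
    return Spectrum(
        sample_id=meta.sample_id,
        wavenumbers=w,
        intensities=np.clip(noisy, 0.0, None),
    )


def generate_library(
    config: SynthConfig | None = None, library: BandLibrary | None = None
) -> SpectrumLibrary:
    """Generate the full labeled library described by ``config``."""
    config = config or SynthConfig()
    library = library or default_band_library()
    composition = config.composition or default_composition()
    if not composition:
        raise ValueError("empty composition")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(composition))
    samples = []
    for meta, s in zip(composition, child_seeds):
        spec = generate_spectrum(meta, library, config.snr, seed=int(s) % 2**31)
        samples.append((spec, meta))
    return SpectrumLibrary(samples)
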