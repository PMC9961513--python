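"""Synthetic seed spectra and hypercubes with known ground truth.

Class contrasts are Gaussian-shaped absorption features added in absorbance
and converted to reflectance (``R = exp(-A)``), so derivative / scatter
correction steps behave as they would on real NIR data.  Batch effects are an
additive absorbance offset plus a wavelength tilt; per-object scatter is an
affine distortion ``b * R + a``; noise is i.i.d. Gaussian per band.

Geometry, object attributes and noise draw from three independent RNG streams
spawned from one seed, so e.g. changing the noise level leaves the layout
bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .hypercube import Hypercube, ReferenceFrames, SpectraTable

__all__ = [
    "Group",
    "ImageGeometry",
    "SimSpec",
    "GroundTruth",
    "make_spectra",
    "make_hypercube",
    "preset_study",
    "STUDY_GROUPS",
]

N_BANDS = 288
WAVELENGTHS = np.linspace(1000.0, 2500.0, N_BANDS)


@dataclass(frozen=True)
class Group:
    """One homogeneous batch of seeds."""

    count: int
    endophyte_status: str
    cultivar: str = ""
    batch_date: str = ""


@dataclass(frozen=True)
class ImageGeometry:
    ellipse_axes: tuple[float, float] = (6.0, 3.0)  # semi-axes in pixels
    spacing: int = 18  # grid pitch in pixels
    margin: int = 10
    n_columns: int = 8
    background_reflectance: float = 0.02
    white_level: float = 2048.0  # power of two: exact calibration round trip
    dark_level: float = 0.0


@dataclass(frozen=True)
class SimSpec:
    groups: Sequence[Group]
    signals: Mapping[str, Sequence[tuple[int, float]]] = field(default_factory=dict)
    signal_width: float = 8.0  # Gaussian sigma in band units
    batch_effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    scatter_mult: tuple[float, float] = (1.0, 1.0)
    scatter_add: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    n_bands: int = N_BANDS
    image: ImageGeometry = field(default_factory=ImageGeometry)
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        for label, feats in self.signals.items():
            for band, amp in feats:
                if not 0 <= band < self.n_bands:
                    raise InputError(f"signal band {band} out of range for {label!r}")
                if amp < 0:
                    raise InputError("signal amplitudes must be >= 0")


@dataclass
class GroundTruth:
    labels: pd.DataFrame  # object_id, cultivar, endophyte_status, batch_date
    clean_spectra: np.ndarray  # noise-free per-object spectra (scatter included)
    mask: np.ndarray | None = None  # true object-label image (hypercube only)
    pixel_counts: np.ndarray | None = None


def _base_absorbance(n_bands: int) -> np.ndarray:
    """Smooth positive absorbance template with a few broad NIR-like bands."""
    t = np.linspace(0.0, 1.0, n_bands)
    out = 0.35 + 0.15 * t
    for centre, width, depth in ((0.30, 0.05, 0.25), (0.62, 0.07, 0.35), (0.88, 0.04, 0.20)):
        out = out + depth * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return out


def _class_absorbance(spec: SimSpec, labels: Sequence[str]) -> np.ndarray:
    """Sum of the Gaussian features registered for the given label values."""
    bands = np.arange(spec.n_bands, dtype=float)
    total = np.zeros(spec.n_bands)
    for label in labels:
        for centre, amp in spec.signals.get(label, ()):
            total += amp * np.exp(-0.5 * ((bands - centre) / spec.signal_width) ** 2)
    return total


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    geom, attr, noise = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(geom),
        np.random.default_rng(attr),
        np.random.default_rng(noise),
    )


def _object_table(spec: SimSpec) -> pd.DataFrame:
    rows = []
    for group in spec.groups:
        for _ in range(group.count):
            rows.append(
                {
                    "cultivar": group.cultivar,
                    "endophyte_status": group.endophyte_status,
                    "batch_date": group.batch_date,
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "object_id", np.arange(1, len(df) + 1))
    return df


def _clean_object_spectra(spec: SimSpec, labels: pd.DataFrame, attr_rng) -> np.ndarray:
    """Noise-free per-object reflectance rows, scatter and batch applied."""
    base = _base_absorbance(spec.n_bands)
    tilt = np.linspace(-1.0, 1.0, spec.n_bands)
    n = len(labels)
    lo_b, hi_b = spec.scatter_mult
    lo_a, hi_a = spec.scatter_add
    mult = attr_rng.uniform(lo_b, hi_b, size=n)
    add = attr_rng.uniform(lo_a, hi_a, size=n)
    out = np.empty((n, spec.n_bands))
    for i, row in enumerate(labels.itertuples(index=False)):
        absorb = base + _class_absorbance(
            spec, [row.endophyte_status, row.cultivar]
        )
        offset, slope = spec.batch_effects.get(row.batch_date, (0.0, 0.0))
        absorb = absorb + offset + slope * tilt
        out[i] = mult[i] * np.exp(-absorb) + add[i]
    return out


def make_spectra(spec: SimSpec) -> tuple[SpectraTable, GroundTruth]:
    """Object-wise spectra table: ``row = b * R_clean + a + noise``."""
    _, attr_rng, noise_rng = _rngs(spec.rng_seed)
    labels = _object_table(spec)
    clean = _clean_object_spectra(spec, labels, attr_rng)
    noisy = clean + noise_rng.normal(0.0, spec.noise_sd, size=clean.shape) \
        if spec.noise_sd > 0 else clean.copy()
    wl = np.linspace(1000.0, 2500.0, spec.n_bands)
    table = SpectraTable(noisy, wl, labels)
    return table, GroundTruth(labels=labels.copy(), clean_spectra=clean)


def make_hypercube(spec: SimSpec) -> tuple[Hypercube, ReferenceFrames, GroundTruth]:
    """Raw-count cube of elliptical seeds on a dark background, plus references.

    Raw counts are ``dark + (white - dark) * R`` so that reflectance
    calibration inverts the construction; with the default power-of-two white
    level and zero dark level the inversion is floating-point exact.
    """
    geom = spec.image
    _, attr_rng, noise_rng = _rngs(spec.rng_seed)
    labels = _object_table(spec)
    clean = _clean_object_spectra(spec, labels, attr_rng)
    n_obj = len(labels)
    n_cols = max(1, geom.n_columns)
    n_rows = -(-n_obj // n_cols)
    lines = 2 * geom.margin + n_rows * geom.spacing
    pixels = 2 * geom.margin + n_cols * geom.spacing
    wl = np.linspace(1000.0, 2500.0, spec.n_bands)

    refl = np.full((lines, pixels, spec.n_bands), geom.background_reflectance)
    mask = np.zeros((lines, pixels), dtype=int)
    ax_r, ax_c = geom.ellipse_axes
    rr, cc = np.mgrid[0:lines, 0:pixels]
    counts = np.zeros(n_obj, dtype=int)
    for i in range(n_obj):
        r0 = geom.margin + (i // n_cols) * geom.spacing + geom.spacing // 2
        c0 = geom.margin + (i % n_cols) * geom.spacing + geom.spacing // 2
        inside = ((rr - r0) / ax_r) ** 2 + ((cc - c0) / ax_c) ** 2 <= 1.0
        mask[inside] = i + 1
        counts[i] = int(inside.sum())
        refl[inside] = clean[i]
    if spec.noise_sd > 0:
        fg = mask > 0
        refl[fg] += noise_rng.normal(0.0, spec.noise_sd, size=(int(fg.sum()), spec.n_bands))

    white = np.full((pixels, spec.n_bands), geom.white_level)
    dark = np.full((pixels, spec.n_bands), geom.dark_level)
    raw = dark[None, :, :] + (white - dark)[None, :, :] * refl
    cube = Hypercube(raw, wl, is_reflectance=False)
    refs = ReferenceFrames(white=white, dark=dark)
    truth = GroundTruth(
        labels=labels, clean_spectra=clean, mask=mask, pixel_counts=counts
    )
    return cube, refs, truth


# ---------------------------------------------------------------------------
# study-layout preset

# per-group layout of the study population: (count, status, cultivar, received)
STUDY_GROUPS: tuple[Group, ...] = (
    Group(96, "E+", "Alto", "2018-07-11"),
    Group(193, "E+", "Trojan", "2018-07-11"),
    Group(96, "E+", "Rohan", "2017-09-01"),
    Group(96, "E+", "Rohan", "2013-12-17"),
    Group(96, "E+", "Governor", "2017-09-01"),
    Group(96, "E-", "Bronsyn", "2018-07-11"),
    Group(96, "E-", "Trojan", "2018-07-11"),
    Group(96, "E-", "Trojan", "2013-12-17"),
    Group(96, "E-", "Rohan", "2013-12-17"),
    Group(96, "E-", "Governor", "2013-12-17"),
)


def preset_study(seed: int = 0, noise_sd: float = 0.010) -> tuple[SpectraTable, GroundTruth]:
    """1057-row table mirroring the study's class × cultivar × batch layout.

    Effect sizes are tuned so that the reference full-spectrum PLS-DA
    pipeline lands in the ~85-95% CV accuracy range on this synthetic stand-in
    (the real seed images are not public; this is not a data reproduction).
    """
    signals = {
        "E+": [(60, 0.020), (145, 0.016), (228, 0.012)],
        "Trojan": [(30, 0.030), (200, 0.024)],
        "Alto": [(85, 0.030), (250, 0.024)],
        "Rohan": [(110, 0.030), (170, 0.024)],
        "Governor": [(45, 0.024), (265, 0.030)],
        "Bronsyn": [(130, 0.030), (215, 0.024)],
    }
    batch_effects = {
        "2018-07-11": (0.004, 0.006),
        "2017-09-01": (-0.003, -0.005),
        "2013-12-17": (0.006, -0.004),
    }
    spec = SimSpec(
        groups=STUDY_GROUPS,
        signals=signals,
        signal_width=8.0,
        batch_effects=batch_effects,
        scatter_mult=(0.92, 1.08),
        scatter_add=(-0.015, 0.015),
        noise_sd=noise_sd,
        rng_seed=seed,
    )
    return make_spectra(spec)


def two_class_bands_spec(
    n_per_class: int = 100,
    informative_bands: Sequence[int] = tuple(range(100, 120)),
    amplitude: float = 0.02,
    noise_sd: float = 0.012,
    seed: int = 11,
) -> SimSpec:
    """Two-class spec with a known set of informative bands (GA recovery tests)."""
    return SimSpec(
        groups=(
            Group(n_per_class, "E+", "Trojan", "b1"),
            Group(n_per_class, "E-", "Trojan", "b1"),
        ),
        signals={"E+": [(int(b), amplitude) for b in informative_bands]},
        signal_width=0.5,  # features confined to single bands
        noise_sd=noise_sd,
        rng_seed=seed,
    )
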