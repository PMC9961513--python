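"""Hypercube handling: reflectance calibration, seed segmentation, object spectra.

A hypercube is a pushbroom image stack of shape ``(lines, pixels, bands)``.
Raw detector counts are converted to reflectance with white/dark reference
frames; seeds are separated from the dark background with a reverse mask
(background 0, sample 1); each connected object is reduced to the arithmetic
mean spectrum of its pixels.

File formats: ENVI-style ``.hdr`` text header + flat binary cube (BSQ written;
BSQ/BIL/BIP read), and delimited-text spectra tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .exceptions import CalibrationError, FormatError, InputError

__all__ = [
    "Hypercube",
    "ReferenceFrames",
    "SegmentationMask",
    "SpectraTable",
    "calibrate_reflectance",
    "segment_reverse_mask",
    "extract_spectra",
    "read_cube",
    "write_cube",
    "read_spectra_table",
    "write_spectra_table",
]

LABEL_COLUMNS = ("object_id", "cultivar", "endophyte_status", "batch_date")


@dataclass
class Hypercube:
    """3-D image stack ``(lines, pixels, bands)`` with its wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    is_reflectance: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.data.ndim != 3:
            raise InputError(f"cube data must be 3-D, got ndim={self.data.ndim}")
        if self.data.shape[2] != self.wavelengths.size:
            raise InputError(
                f"band dimension {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise InputError("wavelengths must be strictly increasing")
        if self.is_reflectance and not np.all(np.isfinite(self.data)):
            raise InputError("reflectance cube contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index_range(self, wl_range: tuple[float, float] | None) -> np.ndarray:
        """Indices of bands whose wavelength falls inside the closed interval."""
        if wl_range is None:
            return np.arange(self.n_bands)
        lo, hi = wl_range
        idx = np.flatnonzero((self.wavelengths >= lo) & (self.wavelengths <= hi))
        if idx.size == 0:
            raise InputError(f"no bands inside wavelength range {wl_range}")
        return idx


@dataclass
class ReferenceFrames:
    """White (≈100% reflectance) and dark (shutter closed) reference images.

    Frames may be full-frame 3-D ``(lines, pixels, bands)``, per-line 2-D
    ``(pixels, bands)``, per-band 1-D, or scalar; 3-D frames are averaged over
    scan lines before use.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)

    def broadcastable(self) -> tuple[np.ndarray, np.ndarray]:
        """Reduce frames to arrays broadcastable against a (lines, pixels, bands) cube."""

        def reduce(frame: np.ndarray) -> np.ndarray:
            if frame.ndim == 3:
                frame = frame.mean(axis=0)
            return frame

        return reduce(self.white), reduce(self.dark)


@dataclass
class SegmentationMask:
    """Reverse mask (sample = 1) plus contiguous connected-component labels."""

    mask: np.ndarray
    object_labels: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.object_labels = np.asarray(self.object_labels)
        if self.mask.shape != self.object_labels.shape:
            raise InputError("mask and object_labels shapes differ")
        if not np.array_equal(self.mask, self.object_labels > 0):
            raise InputError("mask must equal (object_labels > 0)")
        ids = np.unique(self.object_labels)
        ids = ids[ids > 0]
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise InputError("object ids must be contiguous 1..K")

    @property
    def n_objects(self) -> int:
        return int(self.object_labels.max(initial=0))


@dataclass
class SpectraTable:
    """Object-wise mean spectra ``X`` (n_objects × n_bands) with labels."""

    X: np.ndarray
    wavelengths: np.ndarray
    labels: pd.DataFrame
    object_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        if self.X.ndim != 2:
            raise InputError("X must be 2-D")
        if self.X.shape[1] != self.wavelengths.size:
            raise InputError("X band count != wavelength count")
        if len(self.labels) != self.X.shape[0]:
            raise InputError("labels row count != spectra row count")

    @property
    def n_objects(self) -> int:
        return self.X.shape[0]

    def select_bands(self, band_indices) -> "SpectraTable":
        idx = np.asarray(band_indices, dtype=int)
        return SpectraTable(
            self.X[:, idx],
            self.wavelengths[idx],
            self.labels.reset_index(drop=True),
            self.object_meta,
        )


# ---------------------------------------------------------------------------
# calibration


def calibrate_reflectance(
    raw: Hypercube, refs: ReferenceFrames, clip: bool = False
) -> Hypercube:
    """Convert raw counts to reflectance: ``R = (I_S - I_D) / (I_W - I_D)``.

    The input cube is not modified.  Values outside [0, 1] are retained by
    default (their fraction is recorded in ``metadata['out_of_range_fraction']``);
    pass ``clip=True`` to clamp into [0, 1].
    """
    if raw.is_reflectance:
        raise InputError("cube is already reflectance-calibrated")
    white, dark = refs.broadcastable()
    try:
        denom = np.broadcast_to(white - dark, raw.shape)
    except ValueError as exc:
        raise InputError(
            f"reference frames (white {white.shape}, dark {dark.shape}) do not "
            f"broadcast to cube shape {raw.shape}"
        ) from exc
    bad = denom <= 0
    if np.any(bad):
        pos = tuple(int(v) for v in np.argwhere(bad)[0])
        raise CalibrationError(
            f"white - dark <= 0 at (line, pixel, band) = {pos}; "
            "calibration undefined there"
        )
    refl = (raw.data - dark) / (white - dark)
    out_of_range = float(np.mean((refl < 0) | (refl > 1)))
    if clip:
        refl = np.clip(refl, 0.0, 1.0)
    meta = dict(raw.metadata)
    meta["out_of_range_fraction"] = out_of_range
    meta["clipped"] = bool(clip)
    return Hypercube(refl, raw.wavelengths.copy(), is_reflectance=True, metadata=meta)


# ---------------------------------------------------------------------------
# segmentation


def segment_reverse_mask(
    cube: Hypercube,
    threshold_band_range: tuple[float, float] | None = None,
    threshold: float | str = "auto",
    min_area: int = 10,
) -> SegmentationMask:
    """Separate bright seed objects from the dark background.

    Pixels whose mean reflectance over ``threshold_band_range`` (default: all
    bands) exceeds the threshold are foreground.  ``threshold='auto'`` uses
    Otsu's method; a float fixes the cut directly.  Connected components below
    ``min_area`` pixels are dropped and ids relabelled contiguously.
    """
    if not cube.is_reflectance:
        raise InputError("segmentation expects a reflectance cube")
    idx = cube.band_index_range(threshold_band_range)
    score = cube.data[:, :, idx].mean(axis=2)
    if threshold == "auto":
        if np.allclose(score, score.flat[0]):
            thr = np.inf  # constant image: nothing to separate
        else:
            thr = float(threshold_otsu(score))
    else:
        thr = float(threshold)
    mask = score > thr
    labels = _cc_label(mask, connectivity=2)
    if min_area > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    # relabel contiguously, ordered by first (row-major) occurrence
    ids = np.unique(labels)
    ids = ids[ids > 0]
    relabelled = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        relabelled[labels == old] = new
    if relabelled.max(initial=0) == 0:
        warnings.warn("segmentation found no foreground objects", stacklevel=2)
    return SegmentationMask(mask=relabelled > 0, object_labels=relabelled)


def extract_spectra(
    cube: Hypercube,
    mask: SegmentationMask,
    labels: pd.DataFrame | dict | None = None,
) -> SpectraTable:
    """Average each object's pixel spectra into one row per object.

    ``labels`` (optional) supplies per-object annotations, one entry per
    object id in order; missing annotation columns default to ``""``.
    """
    if mask.object_labels.shape != cube.shape[:2]:
        raise InputError(
            f"mask shape {mask.object_labels.shape} != cube spatial shape {cube.shape[:2]}"
        )
    k = mask.n_objects
    X = np.empty((k, cube.n_bands), dtype=float)
    pixel_counts = np.empty(k, dtype=int)
    centroids = np.empty((k, 2), dtype=float)
    for obj in range(1, k + 1):
        sel = mask.object_labels == obj
        # np.mean over the pixel stack so identical pixels average exactly
        X[obj - 1] = cube.data[sel].mean(axis=0)
        pixel_counts[obj - 1] = int(sel.sum())
        rr, cc = np.nonzero(sel)
        centroids[obj - 1] = (rr.mean(), cc.mean())

    if labels is None:
        lab = pd.DataFrame({"object_id": np.arange(1, k + 1)})
        for col in LABEL_COLUMNS[1:]:
            lab[col] = ""
    else:
        lab = pd.DataFrame(labels).reset_index(drop=True)
        if len(lab) != k:
            raise InputError(f"labels has {len(lab)} rows but mask has {k} objects")
        if "object_id" not in lab.columns:
            lab.insert(0, "object_id", np.arange(1, k + 1))
    meta = pd.DataFrame(
        {
            "object_id": np.arange(1, k + 1),
            "pixel_count": pixel_counts,
            "centroid_line": centroids[:, 0],
            "centroid_pixel": centroids[:, 1],
        }
    )
    return SpectraTable(X, cube.wavelengths.copy(), lab, meta)


# ---------------------------------------------------------------------------
# ENVI-style cube IO

_DTYPE_TO_ENVI = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
    np.dtype("uint32"): 13,
    np.dtype("int64"): 14,
    np.dtype("uint64"): 15,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_cube(cube: Hypercube, path: str | Path) -> None:
    """Write an ENVI header (``<path>.hdr``) plus band-sequential binary cube."""
    path = Path(path)
    lines, pixels, bands = cube.shape
    dtype = cube.data.dtype
    if dtype not in _DTYPE_TO_ENVI:
        dtype = np.dtype("float64")
    code = _DTYPE_TO_ENVI[dtype]
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {pixels}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"reflectance flag = {int(cube.is_reflectance)}\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n" + wl + "}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    arr = np.ascontiguousarray(cube.data.astype(dtype, copy=False).transpose(2, 0, 1))
    if arr.dtype.byteorder == ">":
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    arr.tofile(path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        out[key.strip().lower()] = value.strip()
    return out


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI header + binary cube (BSQ, BIL or BIP interleave)."""
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    hdr = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
        code = int(hdr["data type"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed ENVI header {hdr_path}: {exc}") from exc
    if code not in _ENVI_TO_DTYPE:
        raise FormatError(f"unsupported ENVI data type {code}")
    dtype = _ENVI_TO_DTYPE[code]
    if int(hdr.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    wl_text = hdr.get("wavelength", "")
    wl_match = re.search(r"\{(.*)\}", wl_text)
    if not wl_match:
        raise FormatError("header missing wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in wl_match.group(1).split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    raw = np.fromfile(path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise FormatError(
            f"cube file holds {raw.size} values, header implies {expected}"
        )
    interleave = hdr.get("interleave", "bsq").lower()
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    is_refl = bool(int(hdr.get("reflectance flag", "0")))
    return Hypercube(np.ascontiguousarray(data), wavelengths, is_reflectance=is_refl)


# ---------------------------------------------------------------------------
# spectra table IO


def write_spectra_table(table: SpectraTable, path: str | Path) -> None:
    """CSV with label columns first, then one column per wavelength (nm)."""
    df = table.labels.copy().reset_index(drop=True)
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "object_id" else np.arange(1, table.n_objects + 1)
    df = df[list(LABEL_COLUMNS)]
    spec = pd.DataFrame(table.X, columns=[repr(float(w)) for w in table.wavelengths])
    pd.concat([df, spec], axis=1).to_csv(path, index=False)


def read_spectra_table(path: str | Path) -> SpectraTable:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spectra table missing label columns: {missing}")
    wl_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength column name: {exc}") from exc
    labels = df[list(LABEL_COLUMNS)].copy()
    labels["batch_date"] = labels["batch_date"].fillna("").astype(str)
    labels["cultivar"] = labels["cultivar"].fillna("").astype(str)
    labels["endophyte_status"] = labels["endophyte_status"].fillna("").astype(str)
    return SpectraTable(df[wl_cols].to_numpy(dtype=float), wavelengths, labels)
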