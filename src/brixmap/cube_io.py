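"""Hyperspectral cube I/O, reflectance calibration and ROI extraction.

Cubes are stored in the ENVI dialect: a plain-text ``.hdr`` companion file
describing shape, interleave, data type and the per-band wavelength list,
next to a raw binary raster.  Only the fields needed for a line-scan
reflectance workflow are supported (no map info, no bad-band lists).

Reflectance calibration follows the standard white/dark normalization

    R = (R0 - RD) / (RW - RD)

which removes illumination non-uniformity and dark-current offset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, ExtractionError, FormatError

logger = logging.getLogger(__name__)

_INTERLEAVES = ("bsq", "bil", "bip")

# ENVI numeric codes for the dtypes this package writes/reads.
_DTYPE_TO_CODE = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
    np.dtype("uint32"): 13,
}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}

#: Reflectance values outside this range are physically suspect (specular
#: highlights, dead pixels); they are retained but logged, never clipped.
REFLECTANCE_SANE_RANGE = (0.0, 1.5)


@dataclass
class HyperCube:
    """A lines x samples x bands cube with wavelength metadata.

    ``kind`` distinguishes raw sensor counts from calibrated reflectance so
    that calibration cannot be applied twice silently.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bsq"
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise FormatError("cube data must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise FormatError(
                f"bands ({self.data.shape[2]}) != wavelength count "
                f"({self.wavelengths.size})"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.interleave not in _INTERLEAVES:
            raise FormatError(f"interleave must be one of {_INTERLEAVES}")
        if self.kind not in ("raw", "reflectance"):
            raise FormatError("kind must be 'raw' or 'reflectance'")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise FormatError("reflectance cube contains non-finite values")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationFrames:
    """White and dark reference frames (per-pixel images or per-band vectors)."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)

    def broadcast_to(self, cube_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Explicitly broadcast both frames to the full cube shape."""
        try:
            white = np.broadcast_to(self.white, cube_shape)
            dark = np.broadcast_to(self.dark, cube_shape)
        except ValueError as exc:
            raise CalibrationError(
                f"calibration frames {self.white.shape}/{self.dark.shape} not "
                f"broadcastable to cube {cube_shape}"
            ) from exc
        return white, dark


@dataclass
class ROISet:
    """Circular regions of interest in 0-based pixel coordinates.

    Each ROI is ``(id, center_line, center_sample, radius_px)``; a pixel
    belongs to the ROI when its center lies within ``radius_px`` (Euclidean,
    boundary inclusive).
    """

    rois: list[tuple[str, float, float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def masks(self, lines: int, samples: int) -> list[np.ndarray]:
        ll, ss = np.mgrid[0:lines, 0:samples]
        out = []
        for _id, cl, cs, r in self.rois:
            if r < 1:
                raise FormatError(f"ROI {_id}: radius {r} < 1")
            out.append((ll - cl) ** 2 + (ss - cs) ** 2 <= r**2)
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.rois, columns=["id", "center_line", "center_sample", "radius_px"]
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ROISet":
        df = pd.read_csv(path)
        return cls(
            [
                (str(r.id), float(r.center_line), float(r.center_sample), float(r.radius_px))
                for r in df.itertuples()
            ]
        )


@dataclass
class SpectraTable:
    """ROI-mean spectra paired with (optional) SSC reference values.

    The modelling currency of the whole pipeline: ``x`` is samples x bands,
    ``y`` the per-sample soluble solid content in degrees Brix.
    """

    x: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.x.ndim != 2:
            raise FormatError("spectra matrix must be 2-D")
        if self.x.shape[1] != self.wavelengths.size:
            raise FormatError("band count does not match wavelength count")
        if not np.all(np.isfinite(self.x)):
            raise FormatError("spectra contain non-finite values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.x.shape[0],):
                raise FormatError("y length does not match number of spectra")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:04d}" for i in range(self.x.shape[0])]
        elif len(self.sample_ids) != self.x.shape[0]:
            raise FormatError("sample_ids length does not match number of spectra")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_bands(self) -> int:
        return self.x.shape[1]

    def subset(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            x=self.x[idx],
            wavelengths=self.wavelengths,
            y=None if self.y is None else self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def with_x(self, x: np.ndarray) -> "SpectraTable":
        return SpectraTable(
            x=x, wavelengths=self.wavelengths, y=self.y, sample_ids=list(self.sample_ids)
        )

    def to_csv(self, path: str | Path) -> None:
        cols = {f"wl_{w:.2f}": self.x[:, j] for j, w in enumerate(self.wavelengths)}
        df = pd.DataFrame({"sample_id": self.sample_ids, **cols})
        if self.y is not None:
            df.insert(1, "ssc_brix", self.y)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        y = df["ssc_brix"].to_numpy() if "ssc_brix" in df.columns else None
        return cls(
            x=df[wl_cols].to_numpy(),
            wavelengths=wavelengths,
            y=y,
            sample_ids=[str(s) for s in df["sample_id"]],
        )


# ---------------------------------------------------------------------------
# ENVI header + raster
# ---------------------------------------------------------------------------

_REQUIRED_HDR = ("samples", "lines", "bands", "interleave", "data type")


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic in header")
    fields: dict[str, str] = {}
    # collapse brace-enclosed multi-line values onto single lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    for req in _REQUIRED_HDR:
        if req not in fields:
            raise FormatError(f"header missing required field '{req}'")
    return fields


def read_envi(header_path: str | Path) -> HyperCube:
    """Read a cube from an ENVI header; raster is the sibling ``.img``/``.dat``."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave '{interleave}'")
    code = int(fields["data type"])
    if code not in _CODE_TO_DTYPE:
        raise FormatError(f"unsupported data type code {code}")
    dtype = _CODE_TO_DTYPE[code]
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip()
        if not (wl_text.startswith("{") and wl_text.endswith("}")):
            raise FormatError("wavelength field must be brace-enclosed")
        wavelengths = np.array(
            [float(tok) for tok in wl_text[1:-1].replace(",", " ").split()]
        )
    else:
        wavelengths = np.arange(bands, dtype=float)
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    data_path = None
    for suffix in ("", ".img", ".dat", ".raw"):
        cand = header_path.with_suffix(suffix) if suffix else header_path.with_suffix("")
        if cand != header_path and cand.exists():
            data_path = cand
            break
    if data_path is None:
        raise FormatError(f"no raster file found next to {header_path}")

    flat = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if flat.size != expected:
        raise FormatError(
            f"raster holds {flat.size} values, header implies {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (lines, bands, samples)
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (lines, samples, bands)
        data = flat.reshape(lines, samples, bands)
    kind = fields.get("brixmap kind", "raw")
    return HyperCube(
        data=np.ascontiguousarray(data),
        wavelengths=wavelengths,
        interleave=interleave,
        kind=kind if kind in ("raw", "reflectance") else "raw",
    )


def write_envi(cube: HyperCube, path: str | Path) -> Path:
    """Write ``cube`` as ``<path>.img`` + ``<path>.hdr``; returns the header path."""
    path = Path(path)
    if path.suffix in (".hdr", ".img"):
        path = path.with_suffix("")
    data = cube.data
    if data.dtype not in _DTYPE_TO_CODE:
        data = data.astype(np.float64)
    code = _DTYPE_TO_CODE[np.dtype(data.dtype.str.lstrip("<>=|"))]
    if cube.interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif cube.interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    img_path = path.with_suffix(".img")
    np.ascontiguousarray(ordered).astype(data.dtype.newbyteorder("<")).tofile(img_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {cube.interleave}\n"
        "byte order = 0\n"
        f"brixmap kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


# ---------------------------------------------------------------------------
# Calibration and extraction
# ---------------------------------------------------------------------------


def calibrate_reflectance(raw: HyperCube, frames: CalibrationFrames) -> HyperCube:
    """White/dark reflectance calibration, R = (R0 - RD) / (RW - RD).

    Refuses to run on a cube already in reflectance units.  Raises
    :class:`CalibrationError` when the white reference does not exceed the
    dark reference somewhere, listing the offending positions.
    """
    if raw.kind != "raw":
        raise CalibrationError(
            "cube is already reflectance; calibration is not applied twice"
        )
    white, dark = frames.broadcast_to(raw.data.shape)
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        pos = np.argwhere(bad)[:10]
        raise CalibrationError(
            f"white <= dark at {int(bad.sum())} positions, e.g. "
            + ", ".join(str(tuple(p)) for p in pos)
        )
    refl = (raw.data.astype(float) - dark) / denom
    lo, hi = REFLECTANCE_SANE_RANGE
    n_out = int(np.count_nonzero((refl < lo) | (refl > hi)))
    if n_out:
        logger.warning(
            "%d reflectance values outside [%g, %g] retained (specular/dead pixels?)",
            n_out, lo, hi,
        )
    return HyperCube(
        data=refl, wavelengths=raw.wavelengths, interleave=raw.interleave,
        kind="reflectance",
    )


def extract_mean_spectra(cube: HyperCube, rois: ROISet) -> SpectraTable:
    """Mean spectrum over each circular ROI, one table row per ROI (in order)."""
    if cube.kind != "reflectance":
        raise ExtractionError("ROI extraction requires a reflectance cube")
    flat = cube.data.reshape(-1, cube.bands)
    rows = []
    ids = []
    for (roi_id, *_), mask in zip(rois.rois, rois.masks(cube.lines, cube.samples)):
        n_px = int(mask.sum())
        if n_px == 0:
            raise ExtractionError(f"ROI {roi_id} contains zero pixels")
        rows.append(flat[mask.ravel()].mean(axis=0))
        ids.append(str(roi_id))
    return SpectraTable(
        x=np.vstack(rows), wavelengths=cube.wavelengths, sample_ids=ids
    )
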