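"""Synthetic Vis-NIR spectra, SSC references and full cubes.

The generator emulates the statistical structure of reflectance spectra of
sliced sweet-potato tissue in 400-1000 nm: a smooth convex baseline rising
into the NIR, superimposed absorption dips near 425 nm (carotenoids),
650 nm (chlorophyll) and 770/980 nm (O-H overtones of water, the bands that
actually carry sugar information), per-sample multiplicative/additive
scatter, band-wise noise, and optionally contaminated reference values.

The soluble solid content (SSC) of each virtual region of interest is drawn
from a truncated normal whose mean/SD default to the calibration statistics
of a yellow-flesh cultivar (11.8 +/- 0.78 degrees Brix).  SSC enters the
spectra only through the depths of the coupled absorption dips, so the
information content of the data is controlled by ``ssc_coupling``.

Randomness is consumed from a single seeded generator in a fixed order
(SSC draws, then multiplicative scatter, additive scatter, band noise,
outlier choice), so identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cube_io import HyperCube, ROISet
from .errors import ConfigError, GeometryError


@dataclass(frozen=True)
class SynthConfig:
    """Forward-model parameters for the spectra generator.

    Defaults encode the study conditions: 256 bands over 400-1000 nm,
    SSC ~ N(11.8, 0.78^2) Brix truncated at zero, dips at 425/650/770/980 nm
    with only the water-related NIR dips coupled to SSC.
    """

    n_samples: int = 420
    n_bands: int = 256
    wl_start: float = 400.0
    wl_end: float = 1000.0
    ssc_mean: float = 11.8
    ssc_sd: float = 0.78
    peak_centers: tuple[float, ...] = (425.0, 650.0, 770.0, 980.0)
    peak_widths: tuple[float, ...] = (18.0, 22.0, 28.0, 35.0)
    #: Dip-depth baseline (reflectance units) at nominal SSC.
    peak_depths: tuple[float, ...] = (0.12, 0.05, 0.05, 0.08)
    #: Sensitivity of each dip depth to SSC, in reflectance units per Brix.
    #: Only the water-overtone dips respond; the magnitudes are set so that a
    #: band-limited calibration on these spectra reaches the predictive
    #: quality typical of real Vis-NIR SSC work (prediction R2 ~ 0.85-0.95).
    ssc_coupling: tuple[float, ...] = (0.0, 0.0, 0.010, 0.020)
    scatter_mult_sd: float = 0.05
    scatter_add_sd: float = 0.02
    noise_sd: float = 0.005
    n_outliers: int = 0
    outlier_shift: float = 3.9  # +5 x ssc_sd, reference-value contamination
    #: Baseline polynomial coefficients in u = (wl - wl_start)/(wl_end - wl_start).
    baseline_coef: tuple[float, ...] = (0.30, 0.45, -0.15)
    seed: int = 0

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ConfigError("n_bands must be >= 2")
        if not self.wl_start < self.wl_end:
            raise ConfigError("wl_start must be < wl_end")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        for c in self.peak_centers:
            if not (self.wl_start <= c <= self.wl_end):
                raise ConfigError(f"peak_centers: {c} nm outside wavelength range")
        n_peaks = len(self.peak_centers)
        for name in ("peak_widths", "peak_depths", "ssc_coupling"):
            if len(getattr(self, name)) != n_peaks:
                raise ConfigError(f"{name} length must match peak_centers")
        if any(w <= 0 for w in self.peak_widths):
            raise ConfigError("peak_widths must be positive")
        for name in ("scatter_mult_sd", "scatter_add_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ssc_sd < 0:
            raise ConfigError("ssc_sd must be >= 0")
        if not 0 <= self.n_outliers < self.n_samples:
            raise ConfigError("n_outliers must satisfy 0 <= n_outliers < n_samples")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_bands)


@dataclass
class SynthDataset:
    """Generated spectra with ground-truth SSC and outlier bookkeeping."""

    spectra: np.ndarray
    ssc: np.ndarray
    wavelengths: np.ndarray
    outlier_index: list[int] = field(default_factory=list)
    provenance: SynthConfig | None = None

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != self.ssc.shape[0]:
            raise ConfigError("spectra row count must equal ssc length")
        if not np.all(np.isfinite(self.spectra)):
            raise ConfigError("spectra must be finite")
        idx = self.outlier_index
        if len(set(idx)) != len(idx) or any(
            not 0 <= i < self.spectra.shape[0] for i in idx
        ):
            raise ConfigError("outlier_index entries must be unique and in range")

    def to_table(self):
        from .cube_io import SpectraTable

        return SpectraTable(x=self.spectra, wavelengths=self.wavelengths, y=self.ssc)


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal draws redrawn until positive (truncation at 0 Brix)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def clean_spectrum(config: SynthConfig, ssc: np.ndarray) -> np.ndarray:
    """Noise- and scatter-free forward model: baseline minus coupled dips.

    ``ssc`` may be scalar or (n,) -> returns (n, n_bands).
    """
    ssc = np.atleast_1d(np.asarray(ssc, dtype=float))
    wl = config.wavelengths
    u = (wl - config.wl_start) / (config.wl_end - config.wl_start)
    base = np.polynomial.polynomial.polyval(u, config.baseline_coef)
    spec = np.tile(base, (ssc.size, 1))
    for c, w, d0, k in zip(
        config.peak_centers, config.peak_widths, config.peak_depths, config.ssc_coupling
    ):
        depth = d0 + k * (ssc - config.ssc_mean)  # (n,)
        shape = np.exp(-0.5 * ((wl - c) / w) ** 2)  # (b,)
        spec -= depth[:, None] * shape[None, :]
    return spec


def generate_spectra(config: SynthConfig) -> SynthDataset:
    """Draw a seeded synthetic dataset of ROI-mean spectra and SSC references."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, b = config.n_samples, config.n_bands

    ssc = _truncated_normal(rng, config.ssc_mean, config.ssc_sd, n)
    spec = clean_spectrum(config, ssc)
    mult = rng.normal(0.0, config.scatter_mult_sd, n) if config.scatter_mult_sd else np.zeros(n)
    add = rng.normal(0.0, config.scatter_add_sd, n) if config.scatter_add_sd else np.zeros(n)
    spec = spec * (1.0 + mult)[:, None] + add[:, None]
    if config.noise_sd:
        spec = spec + rng.normal(0.0, config.noise_sd, (n, b))

    dataset = SynthDataset(
        spectra=spec, ssc=ssc, wavelengths=config.wavelengths, provenance=config
    )
    if config.n_outliers:
        dataset = inject_outliers(
            dataset, config.n_outliers, config.outlier_shift, rng=rng
        )
    return dataset


def inject_outliers(
    dataset: SynthDataset,
    k: int,
    shift: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SynthDataset:
    """Contaminate ``k`` reference values by ``+shift`` Brix.

    Reference-value contamination (spectra untouched) is the abnormality a
    residual-based screen attributes to a sample; the returned dataset's
    ``outlier_index`` records the ground truth.
    """
    n = dataset.ssc.shape[0]
    if k >= n:
        raise ConfigError(f"n_outliers: k={k} must be < n_samples={n}")
    if k == 0:
        return dataset
    if rng is None:
        rng = np.random.default_rng(seed)
    chosen = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
    ssc = dataset.ssc.copy()
    ssc[chosen] += shift
    return SynthDataset(
        spectra=dataset.spectra,
        ssc=ssc,
        wavelengths=dataset.wavelengths,
        outlier_index=sorted(set(dataset.outlier_index) | set(chosen)),
        provenance=dataset.provenance,
    )


def generate_cube(
    config: SynthConfig,
    n_discs: int,
    disc_radius_px: int,
    image_shape: tuple[int, int],
    background_reflectance: float = 0.05,
    pixel_noise_sd: float = 0.0,
    max_tries: int = 2000,
) -> tuple[HyperCube, ROISet, pd.DataFrame]:
    """Render a reflectance cube of circular sample discs on dark background.

    Each disc shares one generated ROI spectrum plus independent per-pixel
    noise, emulating punched markers on a slice.  Returns the cube, the disc
    geometry and a reference table ``sample_id,slice,ssc_brix``.
    """
    lines, samples = image_shape
    r = disc_radius_px
    if r < 1:
        raise GeometryError("disc_radius_px must be >= 1")
    if 2 * r + 2 > min(lines, samples):
        raise GeometryError(
            f"radius {r} discs cannot fit a {lines}x{samples} image"
        )
    disc_cfg = replace(config, n_samples=n_discs, noise_sd=0.0)
    dataset = generate_spectra(disc_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_discs:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n_discs} non-overlapping discs of radius {r} "
                f"in {lines}x{samples} after {max_tries} tries"
            )
        tries += 1
        cl = int(rng.integers(r, lines - r))
        cs = int(rng.integers(r, samples - r))
        if all((cl - a) ** 2 + (cs - b) ** 2 > (2 * r + 1) ** 2 for a, b in centers):
            centers.append((cl, cs))

    data = np.full((lines, samples, config.n_bands), background_reflectance)
    rois = ROISet(
        [(f"roi{i:03d}", float(cl), float(cs), float(r)) for i, (cl, cs) in enumerate(centers)]
    )
    for i, mask in enumerate(rois.masks(lines, samples)):
        data[mask] = dataset.spectra[i]
        if pixel_noise_sd:
            data[mask] += rng.normal(0.0, pixel_noise_sd, (int(mask.sum()), config.n_bands))

    cube = HyperCube(
        data=data, wavelengths=config.wavelengths, interleave="bsq", kind="reflectance"
    )
    reference = pd.DataFrame(
        {
            "sample_id": [rid for rid, *_ in rois.rois],
            "slice": ["A"] * n_discs,
            "ssc_brix": dataset.ssc,
        }
    )
    return cube, rois, reference
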