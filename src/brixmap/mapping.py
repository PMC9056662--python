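"""Pixel-wise SSC prediction and pseudo-color distribution maps.

The visualization procedure mirrors standard hyperspectral chemical
mapping: (1) take the reflectance cube, (2) extract every foreground
pixel's spectrum, (3) push each spectrum through the fitted model bundle
(pretreatment, band subset, regressor), (4) render the per-pixel
predictions as a blue-to-red pseudo-color map over a gray-scale background
band, with a Brix color bar.

Predicted values are stored untouched; display clipping to the render range
happens only at render time.  Background pixels are never pretreated
(row-wise transforms like SNV are undefined on near-constant spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bundle import ModelBundle
from .cube_io import HyperCube
from .errors import MappingError, RenderError, SegmentationError


@dataclass
class SSCMap:
    """Per-pixel predicted SSC with a foreground mask."""

    values: np.ndarray  # lines x samples, NaN outside the mask
    mask: np.ndarray  # boolean foreground
    render_range: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise MappingError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise MappingError("non-finite prediction inside the mask")
        lo, hi = self.render_range
        if not lo < hi:
            raise RenderError(f"degenerate render range ({lo}, {hi})")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def default_render_range(values: np.ndarray) -> tuple[float, float]:
    """2nd-98th percentile of the masked predictions (robust to speculars)."""
    lo, hi = np.percentile(values, [2, 98])
    if lo == hi:  # uniform map: widen symmetrically so rendering still works
        lo, hi = lo - 0.5, hi + 0.5
    return float(lo), float(hi)


def predict_pixels(
    cube: HyperCube,
    bundle: ModelBundle,
    mask: np.ndarray | None = None,
    render_range: tuple[float, float] | None = None,
) -> SSCMap:
    """Apply a model bundle to every masked pixel of a reflectance cube."""
    if cube.kind != "reflectance":
        raise MappingError("pixel-wise prediction requires a reflectance cube")
    bundle.check_wavelengths(cube.wavelengths)
    if mask is None:
        mask = np.ones((cube.lines, cube.samples), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (cube.lines, cube.samples):
        raise MappingError("mask shape does not match cube")
    if not mask.any():
        raise MappingError("empty mask: no pixels to predict")

    spectra = cube.data[mask]  # (n_px, bands)
    preds = bundle.predict_full(spectra)
    values = np.full((cube.lines, cube.samples), np.nan)
    values[mask] = preds
    rng = render_range if render_range is not None else default_render_range(preds)
    return SSCMap(
        values=values,
        mask=mask,
        render_range=rng,
        provenance={"bands": [int(b) for b in bundle.selected_bands], **bundle.meta},
    )


def segment_foreground(
    cube: HyperCube,
    threshold_band: int,
    threshold: float,
    keep_components: int | None = None,
) -> np.ndarray:
    """Threshold a single band and keep the largest connected components."""
    if cube.kind != "reflectance":
        raise SegmentationError("segmentation requires a reflectance cube")
    mask = cube.data[:, :, threshold_band] > threshold
    if not mask.any():
        raise SegmentationError(
            f"no pixel exceeds {threshold} at band {threshold_band}"
        )
    if keep_components is not None:
        labels, n = ndimage.label(mask)
        if n > keep_components:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.argsort(-sizes, kind="stable")[:keep_components] + 1
            mask = np.isin(labels, keep)
    return mask


def render_map(
    ssc_map: SSCMap,
    cube: HyperCube | None = None,
    background_band: int = 0,
    path=None,
    cmap: str = "jet",
    title: str | None = None,
):
    """Render the map: blue->red ramp over a gray background band.

    Returns the matplotlib figure; saves to ``path`` when given.  Rendering
    never modifies ``ssc_map.values``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = ssc_map.render_range
    if not lo < hi:
        raise RenderError("degenerate render range")
    fig, ax = plt.subplots(figsize=(6, 5))
    if cube is not None:
        ax.imshow(cube.data[:, :, background_band], cmap="gray")
    shown = np.ma.array(ssc_map.values, mask=~ssc_map.mask)
    im = ax.imshow(shown, cmap=cmap, vmin=lo, vmax=hi)
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("SSC (°Brix)")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def ramp_color(value: float, lo: float, hi: float, cmap: str = "jet"):
    """Color assigned to a value on the render ramp (for tests/inspection)."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    if not lo < hi:
        raise RenderError("degenerate render range")
    t = np.clip((value - lo) / (hi - lo), 0.0, 1.0)
    return colormaps[cmap](float(t))
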