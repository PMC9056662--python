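"""ModelBundle: the replayable unit applied to every pixel.

A bundle captures everything between a raw full-band reflectance spectrum
and a predicted SSC value: the fitted pretreatment, the selected band
indices, and the fitted regressor (standardization state included).  It is
serializable to JSON text so a distribution map can be reproduced later
without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MappingError
from .pretreat import pretreatment_from_state, pretreatment_to_state
from .regress import model_from_state


@dataclass
class ModelBundle:
    pretreatment: object  # fitted spectral transformer
    selected_bands: np.ndarray  # indices into the full-band axis
    model: object  # fitted calibrator with .predict
    wavelengths: np.ndarray  # full-band axis the bundle was trained on
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_bands = np.asarray(self.selected_bands, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.selected_bands.size == 0:
            raise ConfigError("bundle needs at least one selected band")
        if self.selected_bands.min() < 0 or self.selected_bands.max() >= self.wavelengths.size:
            raise ConfigError("selected band indices outside wavelength axis")

    def check_wavelengths(self, wavelengths: np.ndarray, atol: float = 1e-6) -> None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.shape != self.wavelengths.shape or not np.allclose(
            wavelengths, self.wavelengths, atol=atol
        ):
            bad = (
                np.flatnonzero(~np.isclose(wavelengths, self.wavelengths, atol=atol))[:8].tolist()
                if wavelengths.shape == self.wavelengths.shape
                else "all"
            )
            raise MappingError(
                f"cube wavelength axis differs from the bundle's (bands {bad})"
            )

    def predict_full(self, X_full: np.ndarray) -> np.ndarray:
        """Predict SSC from full-band spectra: pretreat -> subset -> model."""
        X_full = np.atleast_2d(np.asarray(X_full, dtype=float))
        if X_full.shape[1] != self.wavelengths.size:
            raise MappingError(
                f"expected {self.wavelengths.size} bands, got {X_full.shape[1]}"
            )
        Xt = self.pretreatment.transform(X_full)
        return np.asarray(self.model.predict(Xt[:, self.selected_bands])).ravel()

    def to_json(self, path=None) -> str:
        payload = {
            "pretreatment": pretreatment_to_state(self.pretreatment),
            "selected_bands": [int(i) for i in self.selected_bands],
            "model": self.model.get_state(),
            "wavelengths": [float(w) for w in self.wavelengths],
            "meta": self.meta,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ModelBundle":
        if "\n" not in source and not source.lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        payload = json.loads(source)
        return cls(
            pretreatment=pretreatment_from_state(payload["pretreatment"]),
            selected_bands=np.asarray(payload["selected_bands"], dtype=int),
            model=model_from_state(payload["model"]),
            wavelengths=np.asarray(payload["wavelengths"], dtype=float),
            meta=payload.get("meta", {}),
        )
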