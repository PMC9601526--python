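"""Color sample containers and delimited-text I/O.

A :class:`ColorSet` is the signal at any stage of a color-vision network:
an ``n x 3`` matrix of tristimulus values together with a color-space tag
(LMS, opponent, CIELAB, ...) and the illuminant condition it was acquired
under.  Sets are written as plain CSV with a JSON sidecar for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: Valid color-space tags, in the order signals move through a network.
SPACES = (
    "LMS_linear",
    "LMS_adapted",
    "ATD_linear",
    "ATD_nonlinear",
    "LAB",
    "BENCHMARK",
    "RESCALED",
)

#: Default minimum sample size for information estimates on a ColorSet.
MIN_SAMPLES_FOR_ESTIMATION = 1000


class ParameterError(ValueError):
    """A parameter is outside its valid range."""


class DegenerateInputError(ValueError):
    """Input data is degenerate (constant dimension, singular covariance)."""


class UsageError(RuntimeError):
    """Operations combined inconsistently (space mismatch, unpaired sets)."""


@dataclass
class ColorSet:
    """n x 3 color samples with a space tag and illuminant label.

    Parameters
    ----------
    samples
        Real matrix of shape ``(n, 3)``; all entries finite.  For
        ``LMS_linear`` sets all entries must be non-negative (cone
        responses are physically realizable).
    space
        One of :data:`SPACES`.
    illuminant
        Free label for the acquisition condition (e.g. ``"D65like"``),
        ``"none"`` when not applicable.
    meta
        Free-form provenance record (seeds, fitted-map flags, scale
        factors...).
    """

    samples: np.ndarray
    space: str = "LMS_linear"
    illuminant: str = "none"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ParameterError(
                f"samples must be an (n, 3) matrix, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 2:
            raise ParameterError("need at least 2 samples for moments")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite entries")
        if self.space not in SPACES:
            raise ParameterError(f"unknown space tag {self.space!r}")
        if self.space == "LMS_linear" and np.any(self.samples < 0):
            raise ParameterError("LMS_linear samples must be non-negative")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def with_samples(self, samples: np.ndarray, space: str | None = None,
                     **meta: Any) -> "ColorSet":
        """New set with replaced samples, optionally a new space tag, and
        extra meta entries merged on top of the current provenance."""
        return ColorSet(np.asarray(samples, dtype=float),
                        space=space if space is not None else self.space,
                        illuminant=self.illuminant,
                        meta={**self.meta, **meta})

    # ------------------------------------------------------------------ I/O

    _COLUMNS = ("c1", "c2", "c3")

    def to_csv(self, path: str | Path) -> None:
        """Write samples as CSV plus a ``<path>.meta.json`` sidecar.

        Values are written with 17 significant digits so a round-trip is
        bit-exact.
        """
        path = Path(path)
        header = [f"{c}[{self.space}|{self.illuminant}]" for c in self._COLUMNS]
        df = pd.DataFrame(self.samples, columns=header)
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar = {"space": self.space, "illuminant": self.illuminant,
                   "n": self.n, "meta": _jsonable(self.meta)}
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorSet":
        path = Path(path)
        try:
            # the default float parser is not correctly rounded; round_trip
            # keeps the CSV round-trip bit-exact
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
            raise ParameterError(f"malformed CSV {path}: {exc}") from exc
        if df.shape[1] != 3:
            raise ParameterError(
                f"{path}: expected 3 value columns, found {df.shape[1]}")
        space, illuminant = "LMS_linear", "none"
        first = str(df.columns[0])
        if "[" in first and "|" in first:
            tag = first[first.index("[") + 1:first.rindex("]")]
            space, illuminant = tag.split("|", 1)
        meta: dict[str, Any] = {}
        sidecar = Path(str(path) + ".meta.json")
        if sidecar.exists():
            record = json.loads(sidecar.read_text())
            space = record.get("space", space)
            illuminant = record.get("illuminant", illuminant)
            meta = record.get("meta", {})
        return cls(df.to_numpy(dtype=float), space=space,
                   illuminant=illuminant, meta=meta)


def _jsonable(obj: Any) -> Any:
    """Best-effort conversion of meta records to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
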