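"""File formats and configuration.

Images are 8- or 16-bit grayscale PNG/TIFF, normalized to [0, 1] on read;
masks are strictly {0, 1} PNGs.  Curves travel as human-readable JSON: an
ordered list of [row, col] integer pairs per curve plus metadata (image size,
pipeline stage, parameters).  The pipeline configuration is one YAML/JSON
document with strict key validation, with sections mirroring the scene,
training, loss and grouping parameter dataclasses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from wiretrace.grouping import GroupingParams
from wiretrace.losses import LossConfig
from wiretrace.mslnet import TrainConfig
from wiretrace.synthetic import SceneConfig


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image, normalized to float [0, 1] by the dtype range."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        warnings.warn(f"{path}: multi-channel input converted to grayscale")
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG/TIFF."""
    arr = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any positive value maps to 1."""
    arr = read_image(path)
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as an 8-bit PNG (0/255); round-trips bit-exactly."""
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_curves(
    path: str | Path,
    curves,
    image_size: tuple[int, int],
    stage: str = "",
    params: dict | None = None,
    gap_bridged: bool = False,
) -> None:
    """Write curves as JSON: ordered [row, col] lists plus metadata."""
    doc = {
        "image_size": list(image_size),
        "stage": stage,
        "params": params or {},
        "gap_bridged": gap_bridged,
        "curves": [np.asarray(c).astype(int).tolist() for c in curves],
    }
    Path(path).write_text(json.dumps(doc))


def read_curves(path: str | Path) -> tuple[list[np.ndarray], dict]:
    """Read a curve JSON; returns (curves, metadata)."""
    doc = json.loads(Path(path).read_text())
    curves = [np.asarray(c, dtype=int) for c in doc["curves"]]
    meta = {k: v for k, v in doc.items() if k != "curves"}
    return curves, meta


# ---------------------------------------------------------------------------
# configuration

_SECTIONS = {
    "scene": SceneConfig,
    "train": TrainConfig,
    "loss": LossConfig,
    "grouping": GroupingParams,
}
_TOP_KEYS = set(_SECTIONS) | {"tolerance", "fill_gaps"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load the pipeline configuration with strict key validation.

    Returns a dict with instantiated section dataclasses plus the scalar
    evaluation settings (``tolerance``, ``fill_gaps``).  Unknown top-level or
    section keys raise ``ValueError``.  ``overrides`` maps dotted keys
    (e.g. ``"grouping.tau"``) to replacement values.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sections: dict = {}
    for name, cls in _SECTIONS.items():
        kwargs = dict(raw.get(name, {}))
        valid = {f.name for f in fields(cls)}
        bad = set(kwargs) - valid
        if bad:
            raise ValueError(f"unknown keys in section '{name}': {sorted(bad)}")
        if "gap_len_range" in kwargs:
            kwargs["gap_len_range"] = tuple(kwargs["gap_len_range"])
        sections[name] = (cls, kwargs)
    cfg: dict = {"tolerance": float(raw.get("tolerance", 3.0)),
                 "fill_gaps": bool(raw.get("fill_gaps", False))}
    for key, value in (overrides or {}).items():
        if "." in key:
            sec, field_name = key.split(".", 1)
            cls, kwargs = sections[sec]
            if field_name not in {f.name for f in fields(cls)}:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[field_name] = value
        elif key in cfg:
            cfg[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    for name, (cls, kwargs) in sections.items():
        cfg[name] = cls(**kwargs)
    return cfg
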