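"""End-to-end localization pipeline.

segmentation -> thinning + chain extraction -> perceptual grouping ->
cleanup.  Deterministic given the checkpoint and configuration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from wiretrace.extraction import extract_curves
from wiretrace.grouping import GroupingParams, cleanup, group
from wiretrace.mslnet import MSLNet


def run_pipeline(
    image: np.ndarray,
    model: MSLNet | str | Path,
    params: GroupingParams = GroupingParams(),
    thin_method: str = "thin",
    save_intermediates: dict | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run the full four-stage pipeline on one grayscale [0, 1] image.

    ``model`` is an :class:`MSLNet` or a checkpoint path.  Returns the binary
    segmentation mask and the final list of curves.  If
    ``save_intermediates`` is a dict it receives the per-stage artifacts
    (``segmentation``, ``initial_curves``, ``grouped_curves``).
    """
    if not isinstance(model, MSLNet):
        model = MSLNet.load(model)
    try:
        out = model.predict(image)
    except ValueError as exc:
        raise RuntimeError(f"segmentation stage failed: {exc}") from exc
    mask = out.mask
    initial = extract_curves(mask, method=thin_method)
    grouped = group(initial, params)
    final = cleanup(grouped, params.lmin)
    if save_intermediates is not None:
        save_intermediates["segmentation"] = mask
        save_intermediates["initial_curves"] = initial
        save_intermediates["grouped_curves"] = grouped
    return mask, final
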