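"""Lysosome-association (acidification) assay.

Quantifies the fraction of internalized T cells overlapping a detected
acidified compartment in the lysosome channel.  The internalized set is
found with the same masking cascade as the main assay; the membrane channel
is optional here — the acidification experiment runs without a surface
label, so surface cells are excluded by the cytoplasm-displacement test
alone.  Association is strictly overlap-based: a cell is lysosome-associated
when at least one detected acidification object is assigned to it by
parent/child relation (most shared pixels, ≥ 1 shared pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .image_io import FieldOfView
from .pipeline import run_cascade
from .segmentation import identify_primary_objects, relate_objects


@dataclass
class LysoSummary:
    """Per-field acidification readout.

    ``percent_associated`` = 100 x associated / evaluated, NaN when no
    internalized cell was evaluated.
    """

    field_id: str
    n_internalized_evaluated: int
    n_lysosome_associated: int
    percent_associated: float


def quantify_lysosome_association(
    fov: FieldOfView, config: PipelineConfig | None = None
) -> LysoSummary:
    """Percentage of internalized T cells overlapping acidified objects."""
    config = config or PipelineConfig()
    fov.require("bec", "tcell", "lysosome")
    use_membrane = "membrane" in fov.channels
    res = run_cascade(fov, config, use_membrane=use_membrane)
    internal = res.internalized

    lyso_objs = identify_primary_objects(fov.channels["lysosome"], config.lysosome)
    _, counts = relate_objects(children=lyso_objs, parents=internal)
    n_assoc = int((counts > 0).sum())
    n_eval = internal.n_objects
    percent = 100.0 * n_assoc / n_eval if n_eval else float("nan")
    return LysoSummary(
        field_id=fov.field_id,
        n_internalized_evaluated=n_eval,
        n_lysosome_associated=n_assoc,
        percent_associated=percent,
    )


def percent_associated(summaries: list[LysoSummary]) -> float:
    """Pooled percentage across fields (total associated / total evaluated)."""
    n_eval = sum(s.n_internalized_evaluated for s in summaries)
    n_assoc = sum(s.n_lysosome_associated for s in summaries)
    return 100.0 * n_assoc / n_eval if n_eval else float("nan")
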