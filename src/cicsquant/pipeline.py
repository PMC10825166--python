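"""The internalisation decision cascade.

A CD8+ T cell is classed as *internalized* within a biliary epithelial cell
(BEC) when it (a) lies on a BEC footprint, (b) carries no surface-membrane
label (the enclosing cell shields it from the medium-borne label), and
(c) displaces BEC cytoplasm fluorescence — it sits in a dark "hole" of the
BEC channel.  The cascade is a sequence of object-masking steps:

1. BEC objects from the BEC channel, hole-filled (the holes *are* the
   internalized cells, so BEC footprints must cover them).
2. T-cell channel masked by BEC footprints; T-cell objects detected there
   are the on-BEC set.
3. Membrane channel masked by the T-cell footprints; T cells covered by
   detected membrane-label objects beyond a small fraction of their area
   are deleted (surface cells).
4. Remaining T cells are tested for cytoplasm displacement: a cell whose
   footprint carries above-threshold BEC signal over at least the cutoff
   fraction is *on top of* cytoplasm, not displacing it.
5. After each masking step, clipped remnants are removed by the
   eccentricity filter (default 0.92).

Survivors are the internalized set.  The per-field readout is the
internalized count per 100 BEC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InsufficientDataError, UndefinedRateError
from .image_io import OBJECT_TABLE_COLUMNS, FieldOfView
from .segmentation import (
    LabelMap,
    compute_morphometrics,
    compute_threshold,
    filter_by_eccentricity,
    identify_primary_objects,
    mask_image_by_objects,
    select_objects,
    _smoothed,
)


@dataclass
class FieldSummary:
    """Per-field counts and the per-100-BEC internalisation rate.

    ``internalized_per_100_bec`` is NaN and ``valid`` False when no BEC was
    detected; such fields are excluded (and counted) during well
    aggregation.
    """

    field_id: str
    well_id: str
    condition: str
    n_bec: int
    n_tcell_total: int
    n_tcell_on_bec: int
    n_membrane_positive: int
    n_internalized: int
    internalized_per_100_bec: float
    mean_internalized_area_um2: float
    mean_internalized_eccentricity: float
    valid: bool = True


@dataclass
class CascadeResult:
    """Intermediate label maps and per-object flags of one cascade run."""

    bec_objects: LabelMap
    tcell_all: LabelMap
    tcell_on_bec: LabelMap
    internalized: LabelMap
    flags: pd.DataFrame  # per on-BEC T cell: membrane_positive, cytoplasm_displacing, internalized


def _overlap_fraction_per_object(objects: LabelMap, region: np.ndarray) -> pd.Series:
    """Fraction of each object's footprint covered by a boolean region."""
    labels = objects.labels
    areas = np.bincount(labels.ravel(), minlength=objects.n_objects + 1)[1:]
    covered = np.bincount(
        labels.ravel(), weights=region.ravel().astype(float),
        minlength=objects.n_objects + 1,
    )[1:]
    frac = np.divide(covered, areas, out=np.zeros_like(covered), where=areas > 0)
    return pd.Series(frac, index=pd.RangeIndex(1, objects.n_objects + 1, name="label"))


def run_cascade(fov: FieldOfView, config: PipelineConfig | None = None,
                use_membrane: bool = True) -> CascadeResult:
    """Execute the masking cascade on one field of view.

    With ``use_membrane=False`` (the acidification assay, which runs without
    a membrane label) the membrane-exclusion step is skipped and surface
    cells are excluded by the cytoplasm-displacement test alone.
    """
    config = config or PipelineConfig()
    fov.require("bec", "tcell")
    if use_membrane:
        fov.require("membrane")

    bec_ch = fov.channels["bec"]
    tc_ch = fov.channels["tcell"]

    # step 1: BEC objects, hole-filled so internalized cells stay on-footprint
    bec_objs = identify_primary_objects(bec_ch, config.bec)

    # all detected T cells (for the monotone exclusion chain)
    tcell_all = identify_primary_objects(tc_ch, config.tcell)

    # step 2: T cells restricted to BEC areas
    tc_masked = mask_image_by_objects(tc_ch, bec_objs)
    tcell_on = identify_primary_objects(tc_masked, config.tcell)
    tcell_on = filter_by_eccentricity(tcell_on, config.max_eccentricity)

    n_on = tcell_on.n_objects
    idx = pd.RangeIndex(1, n_on + 1, name="label")
    flags = pd.DataFrame(
        {
            "membrane_positive": pd.array([pd.NA] * n_on, dtype="boolean"),
            "cytoplasm_displacing": pd.array([pd.NA] * n_on, dtype="boolean"),
            "internalized": pd.array([False] * n_on, dtype="boolean"),
        },
        index=idx,
    )

    # step 3: delete T cells that possess membrane label
    if use_membrane and n_on:
        mem_masked = mask_image_by_objects(fov.channels["membrane"], tcell_on)
        mem_objs = identify_primary_objects(mem_masked, config.membrane)
        if mem_objs.n_objects:
            areas = np.bincount(mem_objs.labels.ravel())[1:]
            big = np.flatnonzero(areas >= config.membrane_min_area_px) + 1
            mem_objs = select_objects(mem_objs, big, provenance="membrane>=min_area")
        frac = _overlap_fraction_per_object(tcell_on, mem_objs.footprint)
        flags["membrane_positive"] = pd.array(
            frac >= config.membrane_overlap_fraction, dtype="boolean")
    elif n_on:
        flags["membrane_positive"] = pd.array([False] * n_on, dtype="boolean")

    mem_neg = flags.index[~flags["membrane_positive"].fillna(False).to_numpy()]

    # step 4: cytoplasm-displacement test on membrane-negative cells
    if len(mem_neg):
        thr_bec = compute_threshold(bec_ch, config.bec)
        bec_signal = _smoothed(bec_ch.pixels, config.bec.smoothing_sigma) > thr_bec
        frac_sig = _overlap_fraction_per_object(tcell_on, bec_signal)
        displacing = frac_sig < config.cytoplasm_overlap_cutoff
        flags.loc[mem_neg, "cytoplasm_displacing"] = pd.array(
            displacing.loc[mem_neg].to_numpy(), dtype="boolean")

    internal_labels = flags.index[
        (~flags["membrane_positive"].fillna(True).to_numpy())
        & flags["cytoplasm_displacing"].fillna(False).to_numpy()
    ].to_numpy()
    # step 5: remnant filter after the final masking step (kept consistent
    # with the flags by filtering the label list before selection)
    if len(internal_labels):
        ecc = compute_morphometrics(tcell_on).set_index("label")["eccentricity"]
        internal_labels = internal_labels[
            ecc.loc[internal_labels].to_numpy() <= config.max_eccentricity
        ]
    internal = select_objects(tcell_on, internal_labels, provenance="internalized")
    flags.loc[internal_labels, "internalized"] = True

    return CascadeResult(bec_objs, tcell_all, tcell_on, internal, flags)


def detect_internalized(
    fov: FieldOfView, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, FieldSummary, LabelMap]:
    """Detect internalized T cells in one field.

    Returns per-object records (BEC objects and on-BEC T cells with their
    classification flags), the field summary, and the label map of
    internalized objects.  Deterministic for fixed input and config.
    """
    config = config or PipelineConfig()
    fov.require("bec", "tcell", "membrane")
    res = run_cascade(fov, config, use_membrane=True)
    records = _object_records(fov, res, config)
    summary = _field_summary(fov, res, records)
    return records, summary, res.internalized


def _object_records(fov: FieldOfView, res: CascadeResult, config: PipelineConfig) -> pd.DataFrame:
    px = fov.pixel_size
    rows = []
    bec_m = compute_morphometrics(res.bec_objects, px)
    for r in bec_m.itertuples():
        rows.append(dict(field_id=fov.field_id, object_id=f"bec_{r.label}",
                         obj_class="bec", area_px=r.area_px, area_um2=r.area_um2,
                         eccentricity=r.eccentricity, centroid_row=r.centroid_row,
                         centroid_col=r.centroid_col, on_bec=pd.NA,
                         membrane_positive=pd.NA, cytoplasm_displacing=pd.NA,
                         internalized=pd.NA, lysosome_associated=pd.NA))
    tc_m = compute_morphometrics(res.tcell_on_bec, px).set_index("label")
    for label, fl in res.flags.iterrows():
        r = tc_m.loc[label]
        rows.append(dict(field_id=fov.field_id, object_id=f"tcell_{label}",
                         obj_class="tcell", area_px=int(r.area_px), area_um2=r.area_um2,
                         eccentricity=r.eccentricity, centroid_row=r.centroid_row,
                         centroid_col=r.centroid_col, on_bec=True,
                         membrane_positive=fl["membrane_positive"],
                         cytoplasm_displacing=fl["cytoplasm_displacing"],
                         internalized=fl["internalized"], lysosome_associated=pd.NA))
    df = pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS)
    for col in ("on_bec", "membrane_positive", "cytoplasm_displacing",
                "internalized", "lysosome_associated"):
        df[col] = df[col].astype("boolean")
    return df


def _field_summary(fov: FieldOfView, res: CascadeResult, records: pd.DataFrame) -> FieldSummary:
    n_bec = res.bec_objects.n_objects
    n_int = res.internalized.n_objects
    n_mem_pos = int(res.flags["membrane_positive"].fillna(False).sum())
    tc = records[records["obj_class"] == "tcell"]
    internal_rows = tc[tc["internalized"].fillna(False)]
    if n_bec > 0:
        rate = per_100_bec(n_int, n_bec)
        valid = True
    else:
        rate = float("nan")
        valid = False
    return FieldSummary(
        field_id=fov.field_id,
        well_id=fov.well_id,
        condition=fov.condition,
        n_bec=n_bec,
        n_tcell_total=res.tcell_all.n_objects,
        n_tcell_on_bec=res.tcell_on_bec.n_objects,
        n_membrane_positive=n_mem_pos,
        n_internalized=n_int,
        internalized_per_100_bec=rate,
        mean_internalized_area_um2=float(internal_rows["area_um2"].mean()) if len(internal_rows) else float("nan"),
        mean_internalized_eccentricity=float(internal_rows["eccentricity"].mean()) if len(internal_rows) else float("nan"),
        valid=valid,
    )


def per_100_bec(n_internalized: int, n_bec: int) -> float:
    """Internalized cells per 100 host epithelial cells."""
    if n_bec <= 0:
        raise UndefinedRateError("per-100-BEC rate undefined with n_bec = 0")
    return 100.0 * n_internalized / n_bec


@dataclass
class WellSummary:
    """Per-well (technical repeat) means across its fields of view."""

    well_id: str
    n_fields: int
    n_fields_excluded: int
    mean_internalized_per_100_bec: float
    mean_internalized_area_um2: float
    mean_internalized_eccentricity: float


def summarize_well(field_summaries: list[FieldSummary]) -> WellSummary:
    """Average field summaries to the well level.

    Fields with an undefined rate (no BEC) are excluded and counted; area
    and eccentricity means ignore fields without internalized cells.
    """
    if not field_summaries:
        raise InsufficientDataError("summarize_well needs at least one field")
    wells = {s.well_id for s in field_summaries}
    if len(wells) > 1:
        raise ValueError(f"fields span multiple wells: {sorted(wells)}")
    valid = [s for s in field_summaries if s.valid]
    rates = [s.internalized_per_100_bec for s in valid]
    areas = [s.mean_internalized_area_um2 for s in valid
             if np.isfinite(s.mean_internalized_area_um2)]
    eccs = [s.mean_internalized_eccentricity for s in valid
            if np.isfinite(s.mean_internalized_eccentricity)]
    return WellSummary(
        well_id=field_summaries[0].well_id,
        n_fields=len(field_summaries),
        n_fields_excluded=len(field_summaries) - len(valid),
        mean_internalized_per_100_bec=float(np.mean(rates)) if rates else float("nan"),
        mean_internalized_area_um2=float(np.mean(areas)) if areas else float("nan"),
        mean_internalized_eccentricity=float(np.mean(eccs)) if eccs else float("nan"),
    )
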