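"""Synthetic multi-channel co-culture fields with per-cell ground truth.

The generator emulates the optical signatures a cell-in-cell detection
cascade relies on, for a co-culture of biliary epithelial cells (BEC,
cytoplasm dye channel) with labelled CD8+ T cells (second dye channel) under
a surface-membrane label (wheat-germ agglutinin channel) and optionally an
acidified-compartment (lysosome) channel:

* BEC are large irregular blobs (harmonically perturbed ellipses) of bright
  cytoplasm signal.
* An **internalized** T cell sits fully inside a BEC footprint, displaces the
  cytoplasm there (the BEC channel is suppressed to background under its
  footprint — a dark "hole"), carries full T-cell signal, and carries *no*
  membrane label, because the enclosing cell shields it from the
  medium-borne label.
* An **attached** T cell overlies intact BEC cytoplasm and carries a bright
  membrane rim.
* A **free** T cell sits off every BEC footprint, also membrane-rimmed.
* BEC outlines themselves are membrane-labelled.
* The lysosome channel carries punctate signal scattered in BEC cytoplasm
  plus puncta overlapping a designated fraction of internalized cells.

Holes are punched before PSF blur so blurred hole edges resemble real
displacement rings.  Noise is Poisson on the photon-scaled intensities
followed by additive Gaussian read noise; both are off by default so that
exactness tests have a deterministic target.  A fixed seed gives
bit-identical images and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .errors import PlacementError
from .image_io import ChannelImage, FieldOfView

_DEFAULT_INTENSITIES = {"bec": 200.0, "tcell": 230.0, "membrane": 240.0, "lysosome": 200.0}

# placement clearances, px
_BEC_GAP = 6.0          # between BEC footprints (on top of max blob radii)
_TCELL_GAP = 7.0        # between T-cell footprints
_INNER_MARGIN = 5.0     # internalized cell edge to BEC boundary
_ATTACH_MARGIN = 2.0    # attached cell edge inside BEC boundary
_FREE_CLEARANCE = 6.0   # free cell edge to nearest BEC
_MAX_TRIES = 400

_PUNCTUM_RADIUS = 2.5


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic field.

    Defaults describe a typical 10x-20x high-content field at 0.65 µm/px:
    epithelial blobs of 13-20 µm radius, T cells of 3-5 µm semi-major axis.
    Counts are exact (not sampled); the truth table reports them back.
    """

    field_shape: tuple[int, int] = (640, 640)
    pixel_size: float = 0.65
    n_bec: int = 10
    n_internalized: int = 4
    n_attached: int = 3
    n_free: int = 5
    bec_radius_range: tuple[float, float] = (20.0, 30.0)
    tcell_radius_range: tuple[float, float] = (5.0, 8.0)
    tcell_axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    channel_intensities: dict = field(default_factory=lambda: dict(_DEFAULT_INTENSITIES))
    membrane_rim_width: float = 2.5
    include_lysosome: bool = False
    lysosome_puncta_per_bec: int = 3
    lysosome_overlap_fraction: float = 0.0
    psf_sigma: float = 1.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bec", "n_internalized", "n_attached", "n_free",
                     "lysosome_puncta_per_bec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bec_radius_range", "tcell_radius_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive with lo <= hi")
        lo, hi = self.tcell_axis_ratio_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("tcell_axis_ratio_range must lie in (0, 1]")
        if not 0 <= self.lysosome_overlap_fraction <= 1:
            raise ValueError("lysosome_overlap_fraction must lie in [0, 1]")
        if (self.n_internalized + self.n_attached) > 0 and self.n_bec == 0:
            raise ValueError("internalized/attached cells require n_bec >= 1")


def noisy_spec(**overrides) -> SyntheticSpec:
    """The default noise model: photon (Poisson) noise plus 2-count read noise."""
    kw = dict(poisson_noise=True, gaussian_noise_sd=2.0)
    kw.update(overrides)
    return SyntheticSpec(**kw)


@dataclass
class GroundTruth:
    """Per-object truth table: one row per BEC and per T cell.

    ``cells`` columns: object_id, state (bec/internalized/attached/free),
    parent_bec_id (nullable), centre row/col, semi-axes, orientation,
    lysosome_associated.  Totals are derived from the rows, so they can
    never disagree with them.
    """

    cells: pd.DataFrame
    field_id: str = ""

    def _count(self, state: str) -> int:
        return int((self.cells["state"] == state).sum())

    @property
    def n_bec(self) -> int:
        return self._count("bec")

    @property
    def n_internalized(self) -> int:
        return self._count("internalized")

    @property
    def n_attached(self) -> int:
        return self._count("attached")

    @property
    def n_free(self) -> int:
        return self._count("free")

    @property
    def totals(self) -> tuple[int, int, int, int]:
        return (self.n_bec, self.n_internalized, self.n_attached, self.n_free)

    def tcells(self, state: str | None = None) -> pd.DataFrame:
        df = self.cells[self.cells["state"] != "bec"]
        if state is not None:
            df = df[df["state"] == state]
        return df

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, field_id: str = "") -> "GroundTruth":
        df = pd.read_csv(path)
        df["parent_bec_id"] = df["parent_bec_id"].astype("Int64")
        df["lysosome_associated"] = df["lysosome_associated"].astype(bool)
        return cls(df, field_id=field_id)


def _blob_coords(rng, center, r0, shape):
    """Rasterize a harmonically perturbed ellipse (irregular epithelial blob)."""
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    radius = np.full_like(theta, r0)
    for k in (2, 3, 4):
        amp = rng.uniform(0.02, 0.08)
        phase = rng.uniform(0, 2 * np.pi)
        radius = radius + r0 * amp * np.cos(k * theta + phase)
    rows = center[0] + radius * np.sin(theta)
    cols = center[1] + radius * np.cos(theta)
    return draw_polygon(rows, cols, shape=shape)


def _place_becs(rng, spec):
    H, W = spec.field_shape
    r_lo, r_hi = spec.bec_radius_range
    centers, radii = [], []
    for i in range(spec.n_bec):
        for _ in range(_MAX_TRIES):
            r0 = rng.uniform(r_lo, r_hi)
            pad = 1.25 * r0 + 3
            if 2 * pad >= min(H, W):
                continue
            cy = rng.uniform(pad, H - 1 - pad)
            cx = rng.uniform(pad, W - 1 - pad)
            ok = all(
                np.hypot(cy - yj, cx - xj) > 1.25 * (r0 + rj) + _BEC_GAP
                for (yj, xj), rj in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r0)
                break
        else:
            raise PlacementError(
                f"could not place BEC {i + 1} of {spec.n_bec} after {_MAX_TRIES} "
                f"attempts; field {spec.field_shape} too crowded for n_bec={spec.n_bec}"
            )
    return centers, radii


def _sample_tcell_geometry(rng, spec):
    a = rng.uniform(*spec.tcell_radius_range)
    b = a * rng.uniform(*spec.tcell_axis_ratio_range)
    orientation = rng.uniform(0, np.pi)
    return a, b, orientation


def _ellipse_coords(center, a, b, orientation, shape):
    return draw_ellipse(center[0], center[1], a, b, shape=shape, rotation=orientation)


def _place_tcell_in_bec(rng, spec, bec_dists, forbidden, margin, kind, index, total):
    """Place one T cell whose footprint lies inside some BEC with clearance."""
    shape = spec.field_shape
    bec_ids = list(bec_dists)
    for _ in range(_MAX_TRIES):
        j = bec_ids[rng.integers(len(bec_ids))]
        a, b, orientation = _sample_tcell_geometry(rng, spec)
        (roff, coff), dist = bec_dists[j]
        valid = np.argwhere(dist > a + margin)
        if len(valid) == 0:
            continue
        vr, vc = valid[rng.integers(len(valid))]
        center = (float(vr + roff), float(vc + coff))
        rr, cc = _ellipse_coords(center, a, b, orientation, shape)
        if forbidden[rr, cc].any():
            continue
        return j, center, a, b, orientation, (rr, cc)
    raise PlacementError(
        f"could not place {kind} cell {index + 1} of {total} after {_MAX_TRIES} "
        f"attempts; BEC too crowded for n_{kind}={total}"
    )


def _mark_forbidden(forbidden, center, a, b, orientation, gap, shape):
    rr, cc = _ellipse_coords(center, a + gap, b + gap, orientation, shape)
    forbidden[rr, cc] = True


def generate_field(spec: SyntheticSpec, field_id: str = "sim000", **ids) -> tuple[FieldOfView, GroundTruth]:
    """Render one field and its truth table.

    Placement uses bounded rejection sampling; an overcrowded request raises
    :class:`~cicsquant.errors.PlacementError` naming the limiting count.
    The same spec (same seed) always returns bit-identical arrays and truth.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.field_shape
    shape = (H, W)

    bec_centers, bec_radii = _place_becs(rng, spec)

    bec_union = np.zeros(shape, dtype=bool)
    bec_masks = {}
    bec_dists = {}
    for j, (center, r0) in enumerate(zip(bec_centers, bec_radii), start=1):
        rr, cc = _blob_coords(rng, center, r0, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        bec_masks[j] = mask
        bec_union |= mask
        # local distance-to-boundary map for interior placement
        r0_int = int(np.ceil(1.3 * r0)) + 2
        rlo = max(0, int(center[0]) - r0_int)
        rhi = min(H, int(center[0]) + r0_int + 1)
        clo = max(0, int(center[1]) - r0_int)
        chi = min(W, int(center[1]) + r0_int + 1)
        local = mask[rlo:rhi, clo:chi]
        bec_dists[j] = ((rlo, clo), ndi.distance_transform_edt(local))

    forbidden = np.zeros(shape, dtype=bool)   # T-cell exclusion zones
    tcell_union = np.zeros(shape, dtype=bool)
    holes = np.zeros(shape, dtype=bool)
    rows: list[dict] = []
    tcell_coords: dict[int, tuple] = {}
    next_id = spec.n_bec + 1

    for j, (center, r0) in enumerate(zip(bec_centers, bec_radii), start=1):
        rows.append(dict(object_id=j, state="bec", parent_bec_id=pd.NA,
                         row=center[0], col=center[1], semi_major_px=r0,
                         semi_minor_px=r0, orientation_rad=0.0,
                         lysosome_associated=False))

    for i in range(spec.n_internalized):
        j, center, a, b, orient, (rr, cc) = _place_tcell_in_bec(
            rng, spec, bec_dists, forbidden, _INNER_MARGIN,
            "internalized", i, spec.n_internalized)
        holes[rr, cc] = True
        tcell_union[rr, cc] = True
        tcell_coords[next_id] = (rr, cc)
        _mark_forbidden(forbidden, center, a, b, orient, _TCELL_GAP, shape)
        rows.append(dict(object_id=next_id, state="internalized", parent_bec_id=j,
                         row=center[0], col=center[1], semi_major_px=a,
                         semi_minor_px=b, orientation_rad=orient,
                         lysosome_associated=False))
        next_id += 1

    attached_rims = []
    for i in range(spec.n_attached):
        j, center, a, b, orient, (rr, cc) = _place_tcell_in_bec(
            rng, spec, bec_dists, forbidden, _ATTACH_MARGIN,
            "attached", i, spec.n_attached)
        tcell_union[rr, cc] = True
        tcell_coords[next_id] = (rr, cc)
        attached_rims.append((center, a, b, orient))
        _mark_forbidden(forbidden, center, a, b, orient, _TCELL_GAP, shape)
        rows.append(dict(object_id=next_id, state="attached", parent_bec_id=j,
                         row=center[0], col=center[1], semi_major_px=a,
                         semi_minor_px=b, orientation_rad=orient,
                         lysosome_associated=False))
        next_id += 1

    dist_to_bec = ndi.distance_transform_edt(~bec_union) if spec.n_bec else np.full(shape, np.inf)
    for i in range(spec.n_free):
        placed = False
        for _ in range(_MAX_TRIES):
            a, b, orient = _sample_tcell_geometry(rng, spec)
            pad = a + spec.membrane_rim_width + 2
            cy = rng.uniform(pad, H - 1 - pad)
            cx = rng.uniform(pad, W - 1 - pad)
            iy, ix = int(round(cy)), int(round(cx))
            if dist_to_bec[iy, ix] <= a + _FREE_CLEARANCE:
                continue
            rr, cc = _ellipse_coords((cy, cx), a, b, orient, shape)
            if forbidden[rr, cc].any():
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place free cell {i + 1} of {spec.n_free} after "
                f"{_MAX_TRIES} attempts; field too crowded for n_free={spec.n_free}")
        tcell_union[rr, cc] = True
        tcell_coords[next_id] = (rr, cc)
        attached_rims.append(((cy, cx), a, b, orient))
        _mark_forbidden(forbidden, (cy, cx), a, b, orient, _TCELL_GAP, shape)
        rows.append(dict(object_id=next_id, state="free", parent_bec_id=pd.NA,
                         row=cy, col=cx, semi_major_px=a, semi_minor_px=b,
                         orientation_rad=orient, lysosome_associated=False))
        next_id += 1

    truth = pd.DataFrame(rows)
    truth["parent_bec_id"] = truth["parent_bec_id"].astype("Int64")

    # ---- render channels (pre-noise) ----
    inten = {**_DEFAULT_INTENSITIES, **spec.channel_intensities}
    bg = spec.background_level

    bec_ch = np.full(shape, bg)
    bec_ch[bec_union] = inten["bec"]
    bec_ch[holes] = bg  # displaced cytoplasm: holes punched before blur

    tc_ch = np.full(shape, bg)
    tc_ch[tcell_union] = inten["tcell"]

    mem_ch = np.zeros(shape)  # surface label has no diffuse background
    rim_w = spec.membrane_rim_width
    for j, mask in bec_masks.items():
        (roff, coff), dist = bec_dists[j]
        rim_local = (dist > 0) & (dist <= rim_w)
        mem_ch[roff:roff + rim_local.shape[0], coff:coff + rim_local.shape[1]][rim_local] = inten["membrane"]
    for center, a, b, orient in attached_rims:  # exposed (attached + free) cells
        rr_o, cc_o = _ellipse_coords(center, a, b, orient, shape)
        rr_i, cc_i = _ellipse_coords(center, max(a - rim_w, 0.5), max(b - rim_w, 0.5), orient, shape)
        ring = np.zeros(shape, dtype=bool)
        ring[rr_o, cc_o] = True
        ring[rr_i, cc_i] = False
        mem_ch[ring] = inten["membrane"]

    channels = {
        "bec": bec_ch,
        "tcell": tc_ch,
        "membrane": mem_ch,
    }

    if spec.include_lysosome:
        channels["lysosome"] = _render_lysosome(
            rng, spec, truth, bec_masks, bec_dists, tcell_union, tcell_coords, inten["lysosome"]
        )

    # ---- PSF blur, then noise ----
    for role, img in channels.items():
        if spec.psf_sigma > 0:
            img = ndi.gaussian_filter(img, sigma=spec.psf_sigma)
        if spec.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if spec.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=shape)
        channels[role] = np.clip(img, 0, None)

    fov = FieldOfView(
        field_id=field_id,
        channels={
            role: ChannelImage(img, role, spec.pixel_size, f"synthetic:{field_id}")
            for role, img in channels.items()
        },
        **ids,
    )
    return fov, GroundTruth(truth, field_id=field_id)


def _render_lysosome(rng, spec, truth, bec_masks, bec_dists, tcell_union, tcell_coords, intensity):
    """Puncta in BEC cytoplasm plus puncta on a fraction of internalized cells."""
    shape = spec.field_shape
    img = np.full(shape, spec.background_level)
    # keep-out: T cells plus a guard band so stray puncta never touch a
    # detected internalized footprint
    keepout = ndi.binary_dilation(tcell_union, iterations=4)
    for j in bec_masks:
        (roff, coff), dist = bec_dists[j]
        valid = np.argwhere(dist > _PUNCTUM_RADIUS + 1.5)
        placed = 0
        for _ in range(_MAX_TRIES):
            if placed >= spec.lysosome_puncta_per_bec or len(valid) == 0:
                break
            vr, vc = valid[rng.integers(len(valid))]
            center = (float(vr + roff), float(vc + coff))
            rr, cc = draw_disk(center, _PUNCTUM_RADIUS, shape=shape)
            if keepout[rr, cc].any():
                continue
            img[rr, cc] = intensity
            placed += 1

    internal = truth.index[truth["state"] == "internalized"].to_numpy()
    k = int(round(spec.lysosome_overlap_fraction * len(internal)))
    if k > 0:
        chosen = rng.choice(internal, size=k, replace=False)
        for idx in chosen:
            row = truth.loc[idx]
            jitter = rng.uniform(-1.0, 1.0, size=2)
            center = (row["row"] + jitter[0], row["col"] + jitter[1])
            rr, cc = draw_disk(center, _PUNCTUM_RADIUS, shape=shape)
            img[rr, cc] = intensity
            truth.loc[idx, "lysosome_associated"] = True
    return img


def generate_batch(
    spec_template: SyntheticSpec,
    n_fields: int,
    count_range: tuple[int, int] | None = None,
    seed: int | None = None,
    field_prefix: str = "sim",
    **ids,
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Generate a batch of fields with independently drawn true counts.

    ``count_range=(lo, hi)`` draws each field's true internalized count
    uniformly from the closed integer interval; per-field seeds are derived
    deterministically from *seed* (default: the template's seed), so a fixed
    seed reproduces the whole batch bit-exactly.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    master = np.random.default_rng(spec_template.seed if seed is None else seed)
    field_seeds = master.integers(0, 2**31 - 1, size=n_fields)
    if count_range is not None:
        lo, hi = count_range
        if not 0 <= lo <= hi:
            raise ValueError("count_range must satisfy 0 <= lo <= hi")
        counts = master.integers(lo, hi + 1, size=n_fields)
    else:
        counts = np.full(n_fields, spec_template.n_internalized)
    out = []
    for i in range(n_fields):
        spec = replace(spec_template, seed=int(field_seeds[i]),
                       n_internalized=int(counts[i]))
        out.append(generate_field(spec, field_id=f"{field_prefix}{i:03d}", **ids))
    return out
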