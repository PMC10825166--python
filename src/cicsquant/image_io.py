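"""Image and table I/O for multi-channel co-culture fields of view.

Channel assignment follows the high-content-screening convention of carrying
a channel/fluorophore token in the file name (e.g. ``field03_CTR.tif``):
each exported single-channel TIFF is matched against a token map and given a
channel *role* (``bec``, ``tcell``, ``membrane``, ``lysosome``, ``nuclei``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import find_boundaries

from .errors import ChannelAssignmentError, DimensionMismatchError, MissingChannelError

CHANNEL_ROLES = ("bec", "tcell", "membrane", "lysosome", "nuclei")

#: Default filename-token -> channel-role map.  Tokens follow the dyes the
#: assay uses: CellTracker Green (epithelial cytoplasm), CellTracker Red
#: (T cells), WGA-AF680 (surface membranes), Lysotracker Blue (acidified
#: compartments).
DEFAULT_TOKEN_MAP: dict[str, str] = {
    "CTG": "bec",
    "CTR": "tcell",
    "WGA680": "membrane",
    "LTB": "lysosome",
}


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity raster with a channel role.

    Parameters
    ----------
    pixels : ndarray
        2-D, finite, non-negative intensity raster.
    role : str
        One of :data:`CHANNEL_ROLES`.
    pixel_size : float
        Physical pixel size in µm/px.
    source_path : str
        Where the raster came from ('' for in-memory images).
    """

    pixels: np.ndarray
    role: str
    pixel_size: float = 0.65
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"channel raster must be 2-D, got {self.pixels.ndim}-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel raster contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("channel raster contains negative intensities")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {CHANNEL_ROLES}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FieldOfView:
    """A set of co-registered single-channel images plus identifiers."""

    field_id: str
    channels: dict[str, ChannelImage]
    well_id: str = ""
    condition: str = ""
    experiment_id: str = ""

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len({s for s in shapes.values()}) > 1:
            raise DimensionMismatchError(f"channel rasters differ in shape: {shapes}")
        sizes = {ch.pixel_size for ch in self.channels.values()}
        if len(sizes) > 1:
            raise DimensionMismatchError(f"channel pixel sizes differ: {sizes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def require(self, *roles: str) -> None:
        missing = [r for r in roles if r not in self.channels]
        if missing:
            raise MissingChannelError(
                f"field {self.field_id!r} lacks required channel(s): {missing}"
            )


def _match_token(path: Path, token_map: dict[str, str]) -> str:
    """Return the role for *path*, requiring exactly one token match."""
    name = path.name
    hits = [tok for tok in token_map if re.search(rf"(?<![A-Za-z0-9]){re.escape(tok)}(?![A-Za-z0-9])", name)]
    if len(hits) == 0:
        raise ChannelAssignmentError(f"no channel token of {sorted(token_map)} found in {name!r}")
    if len(hits) > 1:
        raise ChannelAssignmentError(f"file {name!r} matches multiple tokens: {sorted(hits)}")
    return token_map[hits[0]]


def read_fov(
    paths: list[str | Path],
    token_map: dict[str, str] | None = None,
    field_id: str = "",
    pixel_size: float = 0.65,
    **ids,
) -> FieldOfView:
    """Read per-channel TIFF files into a :class:`FieldOfView`.

    Each path must contain exactly one token of *token_map* in its file name;
    the token decides the channel role. Duplicate roles and shape mismatches
    are rejected with the offending file named.
    """
    token_map = dict(DEFAULT_TOKEN_MAP if token_map is None else token_map)
    channels: dict[str, ChannelImage] = {}
    for p in map(Path, paths):
        role = _match_token(p, token_map)
        if role in channels:
            raise ChannelAssignmentError(
                f"file {p.name!r} assigns role {role!r} already taken by "
                f"{Path(channels[role].source_path).name!r}"
            )
        pixels = tifffile.imread(p)
        if pixels.ndim != 2:
            raise DimensionMismatchError(f"{p.name!r} is not a single-page 2-D image")
        channels[role] = ChannelImage(pixels.astype(np.float64), role, pixel_size, str(p))
    if not field_id:
        field_id = _common_stem([Path(p).stem for p in paths])
    return FieldOfView(field_id=field_id, channels=channels, **ids)


def _common_stem(stems: list[str]) -> str:
    prefix = stems[0]
    for s in stems[1:]:
        while not s.startswith(prefix) and prefix:
            prefix = prefix[:-1]
    return prefix.rstrip("_-") or stems[0]


def write_fov(
    fov: FieldOfView,
    out_dir: str | Path,
    token_map: dict[str, str] | None = None,
    multipage: bool = False,
) -> list[Path]:
    """Write a field as per-channel 16-bit single-page TIFFs.

    File names are ``<field>_<token>.tif`` so that :func:`read_fov` round-trips.
    With ``multipage=True`` a single ``<field>.tif`` stack is written instead
    (page order = sorted roles).
    """
    token_map = dict(DEFAULT_TOKEN_MAP if token_map is None else token_map)
    role_to_token = {role: tok for tok, role in token_map.items()}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if multipage:
        roles = sorted(fov.channels)
        stack = np.stack([_to_uint16(fov.channels[r].pixels) for r in roles])
        path = out_dir / f"{fov.field_id}.tif"
        tifffile.imwrite(path, stack, metadata={"roles": roles})
        return [path]
    for role, ch in fov.channels.items():
        token = role_to_token.get(role)
        if token is None:
            raise ChannelAssignmentError(f"no filename token defined for role {role!r}")
        path = out_dir / f"{fov.field_id}_{token}.tif"
        tifffile.imwrite(path, _to_uint16(ch.pixels))
        written.append(path)
    return written


def _to_uint16(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)


#: Stable column order of the per-object CSV.
OBJECT_TABLE_COLUMNS = [
    "field_id",
    "object_id",
    "obj_class",
    "area_px",
    "area_um2",
    "eccentricity",
    "centroid_row",
    "centroid_col",
    "on_bec",
    "membrane_positive",
    "cytoplasm_displacing",
    "internalized",
    "lysosome_associated",
]


def write_object_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-object records as CSV with stable column order.

    Tri-state flags are serialised as ``True``/``False``/empty (not evaluated).
    An empty record set yields a header-only file.
    """
    df = records.reindex(columns=OBJECT_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_object_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_object_table`."""
    df = pd.read_csv(path)
    for col in ("on_bec", "membrane_positive", "cytoplasm_displacing",
                "internalized", "lysosome_associated"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    return df


def overlay_image(bec: ChannelImage, labels: np.ndarray, color=(255, 0, 255)) -> np.ndarray:
    """RGB overlay: contrast-scaled BEC channel with object outlines burned in.

    The outline pixel set is the inner morphological boundary of each object
    footprint, so the overlay validates exactly what the cascade detected.
    """
    if labels.shape != bec.shape:
        raise DimensionMismatchError(
            f"label map shape {labels.shape} != image shape {bec.shape}"
        )
    img = bec.pixels.astype(np.float64)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    rgb = np.repeat((scaled * 255).astype(np.uint8)[..., None], 3, axis=2)
    boundary = find_boundaries(labels, mode="inner")
    rgb[boundary] = np.asarray(color, dtype=np.uint8)
    return rgb


def write_overlay(bec: ChannelImage, labels: np.ndarray, path: str | Path) -> None:
    """Write the validation overlay (outlines over raw BEC channel) as PNG."""
    iio.imwrite(Path(path), overlay_image(bec, labels), extension=".png")
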