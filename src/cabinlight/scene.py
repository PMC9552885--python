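"""Scene decomposition: 360-degree renders, perspective extraction, block fields.

An equirectangular render (2:1 aspect, longitude/latitude mapped linearly
to pixels) is reduced to the fixed rating perspective by gnomonic
projection, divided into square pixel blocks, and each block is summarized
by its mean cone response computed on *linear* light (physical light
averages linearly; averaging gamma codes would bias dark regions).
A boolean scene mask then splits blocks into external scenery and
in-vehicle interior for the contrast statistic.

Coordinate conventions (frozen for reproducibility):
  * longitude lambda in [-180, 180) maps left -> right across the image,
  * latitude phi in [-90, 90] maps top -> bottom (phi = -90 at the top),
  * pixel centers sit at half-integer offsets (pixel j covers [j, j+1)).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .color import linear_rgb_to_xyz, srgb8_to_linear, xyz_to_lms_ipt

__all__ = [
    "EquirectImage",
    "PerspectiveView",
    "BlockGrid",
    "RegionBlocks",
    "SceneMask",
    "load_image",
    "save_image",
    "extract_perspective_view",
    "decompose_blocks",
    "apply_scene_mask",
    "default_scene_mask",
]

DEFAULT_FOV_DEG = 86.0
DEFAULT_BLOCK = 32


@dataclass
class EquirectImage:
    """A 360-degree equirectangular render: H x W x 3 8-bit sRGB, W = 2H."""

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("equirectangular image must be H x W x 3")
        if p.shape[1] != 2 * p.shape[0]:
            raise ValueError(
                f"equirectangular image must have 2:1 aspect, got {p.shape[1]}x{p.shape[0]}"
            )
        self.pixels = p.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PerspectiveView:
    """A pinhole perspective view: h x w x 3 8-bit sRGB plus its geometry."""

    pixels: np.ndarray
    yaw: float = 0.0
    pitch: float = 0.0
    fov: float = DEFAULT_FOV_DEG

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("perspective view must be h x w x 3")
        if not 0.0 < self.fov < 180.0:
            raise ValueError("field of view must lie in (0, 180) degrees")
        self.pixels = p.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BlockGrid:
    """Per-block mean cone responses of a decomposed image.

    ``lms`` and ``xyz`` are (n_rows, n_cols, 3) arrays of block means
    computed in the linear domain.  ``meta`` records source geometry.
    """

    lms: np.ndarray
    xyz: np.ndarray
    block_size: int
    meta: dict

    @property
    def n_rows(self) -> int:
        return self.lms.shape[0]

    @property
    def n_cols(self) -> int:
        return self.lms.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col", "L", "M", "S", "X", "Y", "Z"])
            for r in range(self.n_rows):
                for c in range(self.n_cols):
                    w.writerow(
                        [r, c, *(f"{v:.10g}" for v in self.lms[r, c])]
                        + [f"{v:.10g}" for v in self.xyz[r, c]]
                    )


@dataclass
class RegionBlocks:
    """A flat set of blocks belonging to one scene region."""

    lms: np.ndarray  # (n, 3)
    xyz: np.ndarray  # (n, 3)
    label: str

    def __len__(self) -> int:
        return self.lms.shape[0]


class SceneMask:
    """Per-block external/internal labels: True marks external scenery."""

    def __init__(self, external: np.ndarray):
        external = np.asarray(external, dtype=bool)
        if external.ndim != 2:
            raise ValueError("scene mask must be a 2-D boolean grid")
        if external.all() or not external.any():
            raise ValueError(
                "scene mask must contain both external and internal blocks"
            )
        self.external = external

    @property
    def shape(self):
        return self.external.shape

    @property
    def external_fraction(self) -> float:
        return float(self.external.mean())

    def to_json(self, path) -> None:
        payload = {
            "n_rows": self.external.shape[0],
            "n_cols": self.external.shape[1],
            "external": self.external.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SceneMask":
        payload = json.loads(Path(path).read_text())
        grid = np.asarray(payload["external"], dtype=bool)
        if grid.shape != (payload["n_rows"], payload["n_cols"]):
            raise ValueError("mask grid does not match its declared geometry")
        return cls(grid)

    @classmethod
    def from_csv(cls, path) -> "SceneMask":
        grid = np.loadtxt(path, delimiter=",", dtype=int)
        return cls(np.atleast_2d(grid).astype(bool))


def default_scene_mask(n_rows: int = 16, n_cols: int = 32) -> SceneMask:
    """The packaged rating-view mask: a window band of external scenery.

    Marks a centered horizontal band of blocks (the cabin glazing seen
    from the rating perspective) as external such that exactly 25% of
    blocks are external and 75% internal, reconstructing the region
    ratio of the reference rating view.  Requires n_rows * n_cols
    divisible by 4.
    """
    total = n_rows * n_cols
    if total % 4:
        raise ValueError("grid size must be divisible by 4 for the 25% band")
    n_ext = total // 4
    band_rows = max(1, int(round(n_ext / n_cols)))
    while band_rows * n_cols > n_ext:
        band_rows -= 1
    grid = np.zeros((n_rows, n_cols), dtype=bool)
    top = max(0, n_rows // 4)
    grid[top : top + band_rows, :] = True
    remainder = n_ext - band_rows * n_cols
    if remainder:
        row = top + band_rows
        start = (n_cols - remainder) // 2
        grid[row, start : start + remainder] = True
    return SceneMask(grid)


def load_image(path, kind: str = "auto"):
    """Load an 8-bit RGB raster; 2:1 images are tagged equirectangular.

    ``kind`` may be "auto", "equirect" or "perspective" to override the
    aspect-ratio heuristic.  Pixels are preserved bit-exactly.
    """
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ValueError(
                    f"{path}: expected an 8-bit RGB image, got mode {im.mode!r}"
                )
            pixels = np.asarray(im, dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"{path}: unreadable image file ({exc})") from exc
    h, w = pixels.shape[:2]
    if kind == "equirect" or (kind == "auto" and w == 2 * h):
        return EquirectImage(pixels)
    return PerspectiveView(pixels)


def save_image(pixels_or_image, path) -> None:
    pixels = getattr(pixels_or_image, "pixels", pixels_or_image)
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def extract_perspective_view(
    img: EquirectImage,
    yaw: float = 0.0,
    pitch: float = 0.0,
    fov: float = DEFAULT_FOV_DEG,
    out_size: tuple[int, int] = (512, 512),
) -> PerspectiveView:
    """Gnomonic projection of an equirectangular image to a pinhole view.

    ``yaw`` rotates the optical axis toward positive longitude, ``pitch``
    tilts it toward positive latitude (downward, matching the top->bottom
    latitude convention).  ``fov`` is the horizontal field of view in
    degrees; ``out_size`` is (width, height).  Sampling is bilinear with
    the horizontal seam wrapped.
    """
    if not 0.0 < fov < 180.0:
        raise ValueError("field of view must lie in (0, 180) degrees")
    out_w, out_h = out_size
    if out_w <= 0 or out_h <= 0:
        raise ValueError("output size must be positive")

    H, W = img.pixels.shape[:2]
    f = (out_w / 2.0) / np.tan(np.radians(fov) / 2.0)

    # Camera rays: x right, y down, z forward; pixel centers.
    xs = (np.arange(out_w) + 0.5) - out_w / 2.0
    ys = (np.arange(out_h) + 0.5) - out_h / 2.0
    x, y = np.meshgrid(xs, ys)
    z = np.full_like(x, f)

    cp, sp = np.cos(np.radians(pitch)), np.sin(np.radians(pitch))
    cy, sy = np.cos(np.radians(yaw)), np.sin(np.radians(yaw))
    # Pitch about the x-axis (positive pitch looks down), then yaw about y.
    y2 = y * cp + z * sp
    z2 = -y * sp + z * cp
    x3 = x * cy + z2 * sy
    z3 = -x * sy + z2 * cy

    lon = np.degrees(np.arctan2(x3, z3))
    lat = np.degrees(np.arcsin(y2 / np.sqrt(x3**2 + y2**2 + z3**2)))

    u = (lon / 360.0 + 0.5) * W - 0.5
    v = (lat / 180.0 + 0.5) * H - 0.5
    u = np.mod(u, W)
    v = np.clip(v, 0.0, H - 1.0)

    # Pad one wrapped column so bilinear sampling crosses the seam.
    padded = np.concatenate([img.pixels, img.pixels[:, :1]], axis=1).astype(float)
    out = np.empty((out_h, out_w, 3))
    for ch in range(3):
        out[..., ch] = map_coordinates(
            padded[..., ch], [v, u], order=1, mode="nearest"
        )
    return PerspectiveView(
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        yaw=yaw,
        pitch=pitch,
        fov=fov,
    )


def decompose_blocks(image, block: int = DEFAULT_BLOCK) -> BlockGrid:
    """Divide an image into square pixel blocks of mean linear cone response.

    Pixels are linearized, converted to XYZ then LMS, and averaged per
    block in the linear domain.  Dimensions must divide evenly; partial
    blocks are rejected rather than padded (padding would bias region
    means).
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    H, W = pixels.shape[:2]
    if block <= 0:
        raise ValueError("block size must be positive")
    if H % block or W % block:
        raise ValueError(
            f"image dimensions {W}x{H} are not divisible by block size {block}"
        )
    linear = srgb8_to_linear(pixels)
    n_rows, n_cols = H // block, W // block
    mean_linear = linear.reshape(n_rows, block, n_cols, block, 3).mean(axis=(1, 3))
    xyz = linear_rgb_to_xyz(mean_linear)
    lms = xyz_to_lms_ipt(xyz)
    meta = {
        "source_shape": [int(H), int(W)],
        "block_size": int(block),
        "geometry": type(image).__name__ if hasattr(image, "pixels") else "array",
    }
    for attr in ("yaw", "pitch", "fov"):
        if hasattr(image, attr):
            meta[attr] = float(getattr(image, attr))
    return BlockGrid(lms=lms, xyz=xyz, block_size=block, meta=meta)


def apply_scene_mask(grid: BlockGrid, mask: SceneMask):
    """Split a block grid into (external, internal, external_fraction).

    The two regions are disjoint and cover the grid; the fraction is the
    share of external blocks.
    """
    if mask.shape != (grid.n_rows, grid.n_cols):
        raise ValueError(
            f"mask shape {mask.shape} does not match block grid "
            f"{(grid.n_rows, grid.n_cols)}"
        )
    ext = mask.external
    external = RegionBlocks(lms=grid.lms[ext], xyz=grid.xyz[ext], label="external")
    internal = RegionBlocks(lms=grid.lms[~ext], xyz=grid.xyz[~ext], label="internal")
    return external, internal, mask.external_fraction
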