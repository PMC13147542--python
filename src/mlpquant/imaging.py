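"""Adhesion-to-agar quantification from pre/post-wash plate scans.

Colonies are pinned in an 8 x 12 grid, scanned on a flatbed scanner before
and after washing the plate. Cell density blocks transmitted light, so
density is measured as inverse pixel intensity, rescaled per image by its
darkest pixel. A reference grid layout is built once from an example plate
with growth at every position, fitted to each prewash scan by translation,
and reused for the paired postwash scan. Per-square mean densities are
background-corrected against negative-control (empty) squares, and the
post/pre density ratio is the fraction of cells sticking to the agar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "GrayImage",
    "PlateLayout",
    "DensityGrid",
    "LayoutError",
    "read_image",
    "read_strain_map",
    "invert_normalize",
    "build_reference_layout",
    "fit_layout",
    "measure_grid",
    "adhesion_from_pair",
    "summarize_strain",
    "quantify_adhesion",
]

#: Prewash normalized density below which a position is considered not growing.
GROWTH_MIN = 0.1

#: Reserved strain-map token marking negative-control (empty) squares.
EMPTY_TOKEN = "EMPTY"


class LayoutError(RuntimeError):
    """Raised when a plate grid cannot be constructed from an image."""


@dataclass(frozen=True)
class GrayImage:
    """A grayscale scan: 2-D pixel intensities plus the white level."""

    pixels: np.ndarray
    white_level: float = 255.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must form a non-empty 2-D array")
        if arr.min() < 0 or arr.max() > self.white_level:
            raise ValueError("pixel values must lie in [0, white_level]")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF scan (8- or 16-bit, grayscale or RGB) as a GrayImage.

    RGB images are converted to luminance grayscale first; the white level
    is taken from the integer dtype (255 or 65535).
    """
    from skimage import io as skio
    from skimage.color import rgb2gray

    raw = skio.imread(str(path))
    if raw.dtype == np.uint8:
        white = 255.0
    elif raw.dtype == np.uint16:
        white = 65535.0
    else:
        white = float(max(1.0, np.max(raw)))
    if raw.ndim == 3:
        gray = rgb2gray(raw[..., :3]) * white  # rgb2gray returns [0, 1]
    else:
        gray = raw.astype(float)
    return GrayImage(pixels=gray, white_level=white)


def read_strain_map(path: str | Path, n_rows: int = 8, n_cols: int = 12) -> np.ndarray:
    """Read the plate strain map: a headerless CSV of n_rows x n_cols labels.

    The token ``EMPTY`` marks negative-control squares.
    """
    frame = pd.read_csv(path, header=None, dtype=str)
    if frame.shape != (n_rows, n_cols):
        raise ValueError(
            f"strain map must be {n_rows} x {n_cols}, got {frame.shape[0]} x "
            f"{frame.shape[1]}"
        )
    return frame.fillna("").to_numpy(dtype=object)


@dataclass(frozen=True)
class PlateLayout:
    """Pixel-space grid of the 96 plate positions.

    ``boxes[r, c]`` is (top, left, bottom, right), half-open and 0-based.
    """

    n_rows: int
    n_cols: int
    boxes: np.ndarray  # (n_rows, n_cols, 4) int

    def __post_init__(self) -> None:
        boxes = np.asarray(self.boxes, dtype=int)
        if boxes.shape != (self.n_rows, self.n_cols, 4):
            raise ValueError("boxes must have shape (n_rows, n_cols, 4)")
        object.__setattr__(self, "boxes", boxes)

    @property
    def edge_mask(self) -> np.ndarray:
        """True for the perimeter ring (36 of 96 positions on an 8 x 12 grid)."""
        mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
        return mask

    @property
    def centers(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of (row, col) box centers."""
        t, l, b, r = (self.boxes[..., i] for i in range(4))
        return np.stack([(t + b) / 2.0, (l + r) / 2.0], axis=-1)

    @property
    def extent(self) -> tuple[int, int, int, int]:
        return (
            int(self.boxes[..., 0].min()),
            int(self.boxes[..., 1].min()),
            int(self.boxes[..., 2].max()),
            int(self.boxes[..., 3].max()),
        )

    def translate(self, dy: int, dx: int) -> "PlateLayout":
        shifted = self.boxes + np.array([dy, dx, dy, dx])
        return replace(self, boxes=shifted)


@dataclass(frozen=True)
class DensityGrid:
    """Background-corrected normalized densities per plate position."""

    values: np.ndarray  # (n_rows, n_cols), in [0, 1]
    control_positions: tuple[tuple[int, int], ...]
    background: float

    def __post_init__(self) -> None:
        if not self.control_positions:
            raise ValueError("control_positions must be non-empty")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)


def invert_normalize(image: GrayImage) -> np.ndarray:
    """Per-pixel normalized inverse intensity (cell-density proxy).

    density = (white_level - pixel) / max(white_level - pixel); the darkest
    pixel of the image maps to exactly 1. A uniform image at the white level
    has no dark reference and returns all zeros (with a warning).
    """
    inverse = image.white_level - image.pixels
    peak = inverse.max()
    if peak == 0:
        warnings.warn(
            "image is uniformly at the white level; densities set to 0",
            stacklevel=2,
        )
        return np.zeros_like(inverse)
    return inverse / peak


def _profile_peaks(
    density: np.ndarray, axis: int, n_expected: int, axis_name: str
) -> np.ndarray:
    """Centers of the n strongest periodic peaks of a projection profile."""
    profile = density.sum(axis=axis)
    profile = profile - profile.min()
    pitch_guess = len(profile) / (n_expected + 1)
    smoothed = gaussian_filter1d(profile, sigma=max(1.0, pitch_guess / 10.0))
    peaks, props = find_peaks(
        smoothed, distance=max(2, int(0.5 * pitch_guess)), prominence=0.0
    )
    if len(peaks) < n_expected:
        raise LayoutError(
            f"found only {len(peaks)} density peaks along the {axis_name} axis, "
            f"expected {n_expected}"
        )
    if len(peaks) > n_expected:
        keep = np.argsort(props["prominences"])[-n_expected:]
        peaks = np.sort(peaks[keep])
    # flat-topped colony profiles make the raw argmax jitter inside the
    # plateau; refine each peak to the local intensity centroid
    pitch = float(np.median(np.diff(peaks))) if len(peaks) > 1 else pitch_guess
    half = max(2, int(round(0.5 * pitch)))
    refined = []
    for p in peaks:
        center = float(p)
        for _ in range(3):  # recenter: plateau edges bias a single pass
            lo = max(0, int(round(center)) - half)
            hi = min(len(profile), int(round(center)) + half + 1)
            window = profile[lo:hi]
            weights = np.clip(window - window.min(), 0, None)
            if weights.sum() == 0:
                break
            center = lo + float(np.average(np.arange(hi - lo), weights=weights))
        refined.append(center)
    return np.asarray(refined)


def build_reference_layout(
    filled_image: GrayImage, n_rows: int = 8, n_cols: int = 12
) -> PlateLayout:
    """Construct the raw 96-position layout from an example filled plate.

    The filled plate has growing strains at every position; row and column
    sums of its inverted image show one peak per grid line. The n strongest
    peaks per axis are regularized to an equal-pitch grid (least-squares
    line through peak positions), and boxes are placed with edges midway
    between adjacent centers.
    """
    density = invert_normalize(filled_image)
    row_centers = _profile_peaks(density, axis=1, n_expected=n_rows, axis_name="row")
    col_centers = _profile_peaks(density, axis=0, n_expected=n_cols, axis_name="column")

    def regularize(centers: np.ndarray) -> tuple[float, float]:
        idx = np.arange(len(centers))
        pitch, origin = np.polyfit(idx, centers, 1)
        return origin, pitch

    row0, row_pitch = regularize(row_centers)
    col0, col_pitch = regularize(col_centers)
    if row_pitch <= 1 or col_pitch <= 1:
        raise LayoutError("degenerate grid pitch")

    h, w = filled_image.shape
    # equal-size boxes centered on the regularized grid: uniform box area
    # keeps per-square mean densities comparable across the plate
    row_size, col_size = int(row_pitch), int(col_pitch)
    row_tops = np.round(row0 + np.arange(n_rows) * row_pitch - row_size / 2)
    col_lefts = np.round(col0 + np.arange(n_cols) * col_pitch - col_size / 2)
    row_tops = np.clip(row_tops, 0, h - row_size).astype(int)
    col_lefts = np.clip(col_lefts, 0, w - col_size).astype(int)
    boxes = np.empty((n_rows, n_cols, 4), dtype=int)
    for r in range(n_rows):
        for c in range(n_cols):
            boxes[r, c] = (
                row_tops[r],
                col_lefts[c],
                row_tops[r] + row_size,
                col_lefts[c] + col_size,
            )
    return PlateLayout(n_rows=n_rows, n_cols=n_cols, boxes=boxes)


def _integral(density: np.ndarray) -> np.ndarray:
    padded = np.zeros((density.shape[0] + 1, density.shape[1] + 1))
    padded[1:, 1:] = density.cumsum(axis=0).cumsum(axis=1)
    return padded


def _box_sums(integral: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    t, l, b, r = (boxes[..., i] for i in range(4))
    return integral[b, r] - integral[t, r] - integral[b, l] + integral[t, l]


def fit_layout(
    layout: PlateLayout,
    image: GrayImage,
    max_shift_px: int = 20,
    fit_inset_frac: float = 0.1,
) -> PlateLayout:
    """Fit the reference layout to one image by integer translation.

    Searches offsets within +/- ``max_shift_px`` per axis for the translation
    maximizing total in-box inverse intensity. The score is computed over
    boxes shrunk by ``fit_inset_frac`` of their size per side: colonies sit
    inside their squares with a margin, so full boxes give a flat score
    plateau around the optimum while inset boxes peak sharply. Fit on the
    prewash image and reuse the result for the paired postwash image:
    pre/post pairs come from the same physical plate on the same scanner and
    are not misaligned with respect to each other. A best offset on the
    search boundary triggers a warning (the true misalignment may be
    larger).
    """
    density = invert_normalize(image)
    h, w = density.shape
    top, left, bottom, right = layout.extent
    if top < 0 or left < 0 or bottom > h or right > w:
        raise ValueError("image smaller than the layout extent")
    # shifted boxes are clipped at the image border during the search
    integral = _integral(density)
    shifts = np.arange(-max_shift_px, max_shift_px + 1)
    best, best_score = (0, 0), -np.inf
    flat = layout.boxes.reshape(-1, 4).copy()
    inset_y = int(round(fit_inset_frac * (flat[:, 2] - flat[:, 0]).mean()))
    inset_x = int(round(fit_inset_frac * (flat[:, 3] - flat[:, 1]).mean()))
    flat[:, 0] += inset_y
    flat[:, 2] -= inset_y
    flat[:, 1] += inset_x
    flat[:, 3] -= inset_x
    for dy in shifts:
        t = np.clip(flat[:, 0] + dy, 0, h)
        b = np.clip(flat[:, 2] + dy, 0, h)
        for dx in shifts:
            l = np.clip(flat[:, 1] + dx, 0, w)
            r = np.clip(flat[:, 3] + dx, 0, w)
            score = float(
                (integral[b, r] - integral[t, r] - integral[b, l] + integral[t, l]).sum()
            )
            if score > best_score:
                best_score, best = score, (int(dy), int(dx))
    if max(abs(best[0]), abs(best[1])) == max_shift_px:
        warnings.warn(
            f"best layout offset {best} lies on the search boundary "
            f"(max_shift_px={max_shift_px}); misalignment may be larger",
            stacklevel=2,
        )
    return layout.translate(*best)


def measure_grid(
    image: GrayImage,
    layout: PlateLayout,
    controls: list[tuple[int, int]],
) -> DensityGrid:
    """Mean normalized density per box, background-corrected.

    The background is the mean density over the negative-control (empty)
    squares and is subtracted from every position; negative corrected
    values are floored at 0. At least one control position is required.
    """
    if not controls:
        raise ValueError("at least one negative-control (empty) square is required")
    density = invert_normalize(image)
    h, w = density.shape
    top, left, bottom, right = layout.extent
    if top < 0 or left < 0 or bottom > h or right > w:
        raise ValueError("layout does not fit inside the image")
    integral = _integral(density)
    sums = _box_sums(integral, layout.boxes)
    areas = (layout.boxes[..., 2] - layout.boxes[..., 0]) * (
        layout.boxes[..., 3] - layout.boxes[..., 1]
    )
    means = sums / np.maximum(areas, 1)
    background = float(np.mean([means[r, c] for r, c in controls]))
    values = np.clip(means - background, 0.0, None)
    return DensityGrid(
        values=values,
        control_positions=tuple((int(r), int(c)) for r, c in controls),
        background=background,
    )


def adhesion_from_pair(
    pre: DensityGrid, post: DensityGrid, growth_min: float = GROWTH_MIN
) -> pd.DataFrame:
    """Per-position adhesion ratios from a pre/post-wash density pair.

    ratio = post / pre where the prewash density reaches ``growth_min``;
    positions below it are flagged not grown with a missing ratio. Ratios
    above 1 are reported as-is and flagged (per-image normalization, not
    clipping, is the guard against scanner drift).
    """
    if pre.values.shape != post.values.shape:
        raise ValueError("pre and post grids have different shapes")
    n_rows, n_cols = pre.values.shape
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    pre_v = pre.values.ravel()
    post_v = post.values.ravel()
    grew = pre_v >= growth_min
    ratio = np.where(grew, post_v / np.where(grew, pre_v, 1.0), np.nan)
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "pre_density": pre_v,
            "post_density": post_v,
            "ratio": ratio,
            "grew": grew,
            "ratio_above_one": np.where(grew, ratio > 1.0, False),
        }
    )


def summarize_strain(
    records: pd.DataFrame,
    strain_map: np.ndarray,
    interior_only: bool = False,
    growth_min: float = GROWTH_MIN,
) -> pd.DataFrame:
    """Per-strain summary across replicate plates.

    ``records`` is the long table from :func:`adhesion_from_pair` (optionally
    with a ``plate`` column for replicates); positions are mapped to strains
    through the plate map. Strains whose mean prewash density is below
    ``growth_min`` are marked excluded from downstream analysis. With
    ``interior_only`` the 36 perimeter positions are dropped first, keeping
    the middle 60 (edge colonies are more adhesive and less reliable).
    """
    n_rows, n_cols = strain_map.shape
    labels = np.asarray(strain_map, dtype=object)
    recs = records.copy()
    mapped = labels[recs["row"].to_numpy(int), recs["col"].to_numpy(int)]
    unmapped = [
        (int(r), int(c))
        for r, c, s in zip(recs["row"], recs["col"], mapped)
        if not str(s).strip()
    ]
    if unmapped:
        raise ValueError(f"positions without a strain label in the map: {unmapped}")
    recs["strain"] = mapped
    recs["excluded_edge"] = (
        (recs["row"] == 0)
        | (recs["row"] == n_rows - 1)
        | (recs["col"] == 0)
        | (recs["col"] == n_cols - 1)
    )
    if interior_only:
        recs = recs[~recs["excluded_edge"]]
    recs = recs[recs["strain"] != EMPTY_TOKEN]
    grouped = recs.groupby("strain", sort=True)
    summary = pd.DataFrame(
        {
            "n_replicates": grouped.size(),
            "n_valid": grouped["grew"].sum().astype(int),
            "mean_pre": grouped["pre_density"].mean(),
            "mean_ratio": recs[recs["grew"]]
            .groupby("strain")["ratio"]
            .mean()
            .reindex(grouped.size().index),
        }
    )
    summary["excluded"] = summary["mean_pre"] < growth_min
    return summary.reset_index()


def _paired_files(pre_dir: Path, post_dir: Path) -> list[tuple[Path, Path]]:
    exts = {".png", ".tif", ".tiff"}
    pre = sorted(p for p in pre_dir.iterdir() if p.suffix.lower() in exts)
    post = sorted(p for p in post_dir.iterdir() if p.suffix.lower() in exts)
    if [p.name for p in pre] != [p.name for p in post]:
        raise ValueError(
            "pre/post folders do not contain matching filenames; refusing to "
            "guess the pairing"
        )
    if not pre:
        raise ValueError("no images found")
    return list(zip(pre, post))


def quantify_adhesion(
    pre_dir: str | Path,
    post_dir: str | Path,
    strain_map_path: str | Path,
    filled_path: str | Path,
    growth_min: float = GROWTH_MIN,
    interior_only: bool = False,
    max_shift_px: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full adhesion pipeline over folders of paired pre/post scans.

    Pairs files across the two folders by identical (lexicographically
    sorted) filenames, fits the reference layout per prewash image, reuses
    it for the paired postwash image, and returns the per-position long
    table and the per-strain summary.
    """
    strain_map = read_strain_map(strain_map_path)
    controls = [
        (r, c)
        for r in range(strain_map.shape[0])
        for c in range(strain_map.shape[1])
        if strain_map[r, c] == EMPTY_TOKEN
    ]
    reference = build_reference_layout(read_image(filled_path))
    tables = []
    for pre_path, post_path in _paired_files(Path(pre_dir), Path(post_dir)):
        pre_img = read_image(pre_path)
        post_img = read_image(post_path)
        layout = fit_layout(reference, pre_img, max_shift_px=max_shift_px)
        pre_grid = measure_grid(pre_img, layout, controls)
        post_grid = measure_grid(post_img, layout, controls)
        table = adhesion_from_pair(pre_grid, post_grid, growth_min=growth_min)
        table.insert(0, "plate", pre_path.stem)
        labels = strain_map[table["row"].to_numpy(int), table["col"].to_numpy(int)]
        table["strain"] = labels
        tables.append(table)
    long = pd.concat(tables, ignore_index=True)
    summary = summarize_strain(
        long, strain_map, interior_only=interior_only, growth_min=growth_min
    )
    return long, summary
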