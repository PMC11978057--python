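"""Local binary pattern codes and gridded histograms.

A pixel's LBP code compares it against its neighborhood: bit b is set when
neighbor b compares true against the center (``>=`` by default), neighbors
ordered clockwise starting from the top-left, least-significant bit first.
Because only order relations enter, the code — and hence the histogram — is
exactly invariant under any strictly increasing intensity remapping, which
is what makes LBP robust to lighting changes.

Neighbor positions are integer-rounded offsets on a circle of the given
radius, so no interpolation is involved (interpolated sampling would break
the exact monotone invariance).  For radius 1 with 8 neighbors these are the
8 adjacent pixels.  Codes are computed only where the full neighborhood lies
inside the image; histograms are taken per grid cell and L1-normalized so
cells with different pixel counts contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GridTooFineError(ValueError):
    """A grid cell is smaller than the LBP neighborhood."""


@dataclass(frozen=True)
class LBPSpec:
    """LBP configuration: neighborhood geometry, grid partition, comparison."""

    radius: int = 1
    neighbors: int = 8
    grid_rows: int = 8
    grid_cols: int = 8
    comparison: str = ">="  # ">=" or ">"

    def __post_init__(self) -> None:
        if self.neighbors < 4:
            raise ValueError("need at least 4 neighbors")
        if self.comparison not in (">=", ">"):
            raise ValueError("comparison must be '>=' or '>'")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def n_bins(self) -> int:
        return 2 ** self.neighbors


def _offsets(spec: LBPSpec) -> list[tuple[int, int]]:
    if spec.neighbors == 8:
        # square ring, clockwise from top-left
        r = spec.radius
        return [(-r, -r), (-r, 0), (-r, r), (0, r), (r, r), (r, 0), (r, -r), (0, -r)]
    # general case: integer-rounded circle, clockwise from up-left diagonal
    out = []
    for b in range(spec.neighbors):
        theta = 3 * np.pi / 4 - 2 * np.pi * b / spec.neighbors
        dy = int(round(-spec.radius * np.sin(theta)))
        dx = int(round(spec.radius * np.cos(theta)))
        out.append((dy, dx))
    return out


def lbp_code(patch: np.ndarray, spec: LBPSpec = LBPSpec()) -> int:
    """LBP code of the center pixel of a (2r+1) x (2r+1) patch.

    Bit b (LSB first) is set iff neighbor b compares true against the center
    under ``spec.comparison``; neighbors run clockwise from the top-left.
    """
    patch = np.asarray(patch)
    side = 2 * spec.radius + 1
    if patch.shape != (side, side):
        raise ValueError(f"expected a {side} x {side} patch, got {patch.shape}")
    c = patch[spec.radius, spec.radius]
    code = 0
    for b, (dy, dx) in enumerate(_offsets(spec)):
        v = patch[spec.radius + dy, spec.radius + dx]
        hit = v >= c if spec.comparison == ">=" else v > c
        if hit:
            code |= 1 << b
    return code


def lbp_code_image(image: np.ndarray, spec: LBPSpec = LBPSpec()) -> np.ndarray:
    """Codes for every interior pixel (full neighborhood inside the image).

    Returns an (H - 2r, W - 2r) integer array aligned with the interior.
    """
    image = np.asarray(image)  # comparisons only: any ordered dtype works
    r = spec.radius
    h, w = image.shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError("image smaller than the LBP neighborhood")
    center = image[r:h - r, r:w - r]
    codes = np.zeros(center.shape, dtype=np.int64)
    for b, (dy, dx) in enumerate(_offsets(spec)):
        nb = image[r + dy:h - r + dy, r + dx:w - r + dx]
        hit = nb >= center if spec.comparison == ">=" else nb > center
        codes |= hit.astype(np.int64) << b
    return codes


def _cell_edges(n: int, cells: int) -> np.ndarray:
    """Cell boundaries dividing n pixels into `cells` parts, remainder last."""
    base = n // cells
    edges = np.arange(cells + 1) * base
    edges[-1] = n
    return edges


def lbp_histogram(image: np.ndarray, spec: LBPSpec = LBPSpec()) -> np.ndarray:
    """Gridded LBP histogram feature: per-cell code histograms, L1-normalized
    and concatenated.  Length = grid_rows * grid_cols * 2**neighbors.
    """
    image = np.asarray(image)
    h, w = image.shape
    if h // spec.grid_rows < 2 * spec.radius + 1 or w // spec.grid_cols < 2 * spec.radius + 1:
        raise GridTooFineError(
            f"grid {spec.grid_rows}x{spec.grid_cols} gives cells smaller than "
            f"the {2 * spec.radius + 1}x{2 * spec.radius + 1} neighborhood"
        )
    codes = lbp_code_image(image, spec)
    r = spec.radius
    # cell edges in full-image coordinates, shifted into code-image coords
    ye = _cell_edges(h, spec.grid_rows)
    xe = _cell_edges(w, spec.grid_cols)
    feats = []
    for i in range(spec.grid_rows):
        y0, y1 = max(ye[i] - r, 0), max(ye[i + 1] - r, 0)
        y1 = min(y1, codes.shape[0])
        for j in range(spec.grid_cols):
            x0, x1 = max(xe[j] - r, 0), max(xe[j + 1] - r, 0)
            x1 = min(x1, codes.shape[1])
            cell = codes[y0:y1, x0:x1]
            hist = np.bincount(cell.ravel(), minlength=spec.n_bins).astype(np.float64)
            total = hist.sum()
            if total > 0:
                hist /= total
            feats.append(hist)
    return np.concatenate(feats)
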