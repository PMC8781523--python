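"""Registration and blending of laterally tiled volumes into a large
field-of-view mosaic.

Adjacent tiles are acquired with a small nominal overlap (5% by default) by a
motorized stage moving in x and y; registration refines the nominal integer
offsets by normalized cross-correlation of mean-over-depth projections, and
blending feathers the overlap linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import ContrastVolume

__all__ = ["TileSet", "StitchLayout", "register_pair", "stitch", "stitch_tileset"]


@dataclass
class TileSet:
    """Ordered tiles of one contrast plus their nominal grid offsets."""

    tiles: list[ContrastVolume]
    nominal_offsets: list[tuple[int, int]]
    overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if len(self.tiles) < 1:
            raise ValueError("TileSet needs at least one tile")
        if len(self.nominal_offsets) != len(self.tiles):
            raise ValueError("one nominal offset per tile required")
        if not 0.0 < self.overlap_fraction < 0.5:
            raise ValueError(
                f"overlap_fraction must lie in (0, 0.5), got {self.overlap_fraction}")
        kinds = {t.kind for t in self.tiles}
        units = {t.units for t in self.tiles}
        if len(kinds) > 1 or len(units) > 1:
            raise ValueError(f"tiles mix contrast kinds/units: {kinds}, {units}")
        depths = {t.shape[0] for t in self.tiles}
        if len(depths) > 1:
            raise ValueError(f"tiles have differing depths: {sorted(depths)}")


@dataclass
class StitchLayout:
    """Refined integer offsets plus pairwise registration scores."""

    refined_offsets: list[tuple[int, int]]
    pairwise_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.refined_offsets and tuple(self.refined_offsets[0]) != (0, 0):
            raise ValueError("the first tile anchors the mosaic at offset (0, 0)")
        for s in self.pairwise_scores.values():
            if not -1.0 - 1e-9 <= s <= 1.0 + 1e-9:
                raise ValueError(f"correlation score {s} outside [-1, 1]")


def _projection(vol: ContrastVolume) -> np.ndarray:
    return vol.data.mean(axis=0)


def _overlap_views(pa: np.ndarray, pb: np.ndarray,
                   dx: int, dy: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping crops of two projections with tile b placed at (dx, dy)."""
    ax0, ay0 = max(0, dx), max(0, dy)
    ax1 = min(pa.shape[0], dx + pb.shape[0])
    ay1 = min(pa.shape[1], dy + pb.shape[1])
    if ax1 <= ax0 or ay1 <= ay0:
        return np.empty((0, 0)), np.empty((0, 0))
    return pa[ax0:ax1, ay0:ay1], pb[ax0 - dx:ax1 - dx, ay0 - dy:ay1 - dy]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, -1.0, 1.0))


def register_pair(a: ContrastVolume,
                  b: ContrastVolume,
                  nominal: tuple[int, int],
                  search_radius: int = 10,
                  min_score: float = 0.3) -> tuple[tuple[int, int], float]:
    """Refine the nominal (x, y) offset of tile ``b`` relative to tile ``a``.

    Exhaustively maximizes the normalized cross-correlation of the
    mean-over-depth projections within ``±search_radius`` pixels of the
    nominal offset.  Candidates are visited nearest-the-nominal first, so
    exact ties resolve toward the nominal offset; if no candidate reaches
    ``min_score`` the nominal offset is returned with the best score
    (featureless or uncorrelated overlap).
    """
    pa, pb = _projection(a), _projection(b)
    nx, ny = int(nominal[0]), int(nominal[1])
    va, vb = _overlap_views(pa, pb, nx, ny)
    if va.size == 0 or min(va.shape) < 8:
        raise ValueError(
            f"nominal offset {nominal} implies an overlap narrower than 8 px "
            f"(got {va.shape})")

    candidates = [(dx, dy)
                  for dx in range(-search_radius, search_radius + 1)
                  for dy in range(-search_radius, search_radius + 1)]
    candidates.sort(key=lambda d: (d[0] * d[0] + d[1] * d[1], abs(d[0]), abs(d[1])))

    best_off, best_score = (nx, ny), -np.inf
    for dx, dy in candidates:
        va, vb = _overlap_views(pa, pb, nx + dx, ny + dy)
        if va.size == 0:
            continue
        score = _ncc(va, vb)
        if score > best_score + 1e-12:
            best_off, best_score = (nx + dx, ny + dy), score
    if best_score < min_score:
        return (nx, ny), best_score
    return best_off, best_score


def _feather_weight(shape: tuple[int, int], ramp: int) -> np.ndarray:
    """2D weight, linearly ramping from the tile borders over ``ramp`` pixels."""
    w, h = shape
    wx = np.minimum(np.arange(1, w + 1), np.arange(w, 0, -1)).astype(float)
    wy = np.minimum(np.arange(1, h + 1), np.arange(h, 0, -1)).astype(float)
    wx = np.minimum(wx, ramp)
    wy = np.minimum(wy, ramp)
    return np.minimum(wx[:, None], wy[None, :])


def stitch(tiles: TileSet, layout: StitchLayout) -> ContrastVolume:
    """Blend the tiles onto the union canvas with linear feathering.

    Where a single tile contributes the output equals that tile exactly;
    overlaps are weighted averages, so constant fields are conserved.  The
    mosaic validity mask is the union of tile validity.
    """
    if len(layout.refined_offsets) != len(tiles.tiles):
        raise ValueError("layout offsets do not match the tile count")
    offs = [tuple(map(int, o)) for o in layout.refined_offsets]
    minx = min(o[0] for o in offs)
    miny = min(o[1] for o in offs)
    offs = [(o[0] - minx, o[1] - miny) for o in offs]
    nz = tiles.tiles[0].shape[0]
    W = max(o[0] + t.shape[1] for o, t in zip(offs, tiles.tiles))
    H = max(o[1] + t.shape[2] for o, t in zip(offs, tiles.tiles))

    acc = np.zeros((nz, W, H))
    wsum = np.zeros((W, H))
    valid = np.zeros((nz, W, H), dtype=bool)
    for (ox, oy), tile in zip(offs, tiles.tiles):
        _, tw, th = tile.shape
        ramp = max(1, int(np.ceil(tiles.overlap_fraction * max(tw, th))))
        w = _feather_weight((tw, th), ramp)
        sl = np.s_[:, ox:ox + tw, oy:oy + th]
        acc[sl] += tile.data * w[None, :, :]
        wsum[ox:ox + tw, oy:oy + th] += w
        valid[sl] |= tile.valid_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        out = acc / wsum[None, :, :]
    out[:, wsum == 0] = 0.0
    valid[:, wsum == 0] = False

    ref = tiles.tiles[0]
    params = {"n_tiles": len(tiles.tiles), "offsets": offs,
              "overlap_fraction": tiles.overlap_fraction,
              "scores": {str(k): v for k, v in layout.pairwise_scores.items()}}
    return ContrastVolume(out, kind=ref.kind, units=ref.units,
                          valid_mask=valid, params=params)


def stitch_tileset(tiles: TileSet, search_radius: int = 10) -> tuple[ContrastVolume, StitchLayout]:
    """Register each tile against the previous one, then blend."""
    offsets = [tuple(map(int, tiles.nominal_offsets[0]))]
    scores: dict[tuple[int, int], float] = {}
    for i in range(1, len(tiles.tiles)):
        prev_ref = offsets[i - 1]
        nominal_rel = (tiles.nominal_offsets[i][0] - tiles.nominal_offsets[i - 1][0],
                       tiles.nominal_offsets[i][1] - tiles.nominal_offsets[i - 1][1])
        rel, score = register_pair(tiles.tiles[i - 1], tiles.tiles[i],
                                   nominal_rel, search_radius=search_radius)
        offsets.append((prev_ref[0] + rel[0], prev_ref[1] + rel[1]))
        scores[(i - 1, i)] = score
    base = offsets[0]
    offsets = [(o[0] - base[0], o[1] - base[1]) for o in offsets]
    layout = StitchLayout(refined_offsets=offsets, pairwise_scores=scores)
    return stitch(tiles, layout), layout
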