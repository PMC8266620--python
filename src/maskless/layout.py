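"""DMD layouts and per-cycle photomask generation.

A digital micromirror device (DMD) is a grid of individually addressable
mirrors (XGA: 1024x768, 14 um pitch).  Oligos are synthesized on *features* --
square blocks of mirrors separated by unused "street" mirrors:

* ``2SZ``  -- 4x4-mirror features with 2-mirror streets (6x6 unit cell, 44% of
  mirrors active),
* ``4SZ``  -- 2x2-mirror features with 4-mirror streets (6x6 unit cell, 11%),
* ``CB``   -- single-mirror features on one parity of the checkerboard (50%),
* ``FULL`` -- every mirror a feature (100%; the 786 432-sequence limit of an
  XGA device).

Bases are coupled in the fixed order A->C->G->T (then back to A); synthesis
proceeds 3'->5'.  At each cycle the mask turns ON exactly the features whose
next unsynthesized base equals the cycle base, so decoding a feature's ON
cycles reconstructs its sequence.

Coordinates are 0-based (row, col), row-major, origin at the top-left mirror.
Cycle indices are 0-based.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COUPLING_ORDER = "ACGT"
_ORDER_INDEX = {b: i for i, b in enumerate(COUPLING_ORDER)}

#: (feature edge in mirrors, street width in mirrors) per gridded design
GRID_DESIGNS = {"2SZ": (4, 2), "4SZ": (2, 4)}


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class DmdGeometry:
    rows: int = 768
    cols: int = 1024
    mirror_pitch_um: float = 14.0
    mirror_gap_um: float = 1.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise LayoutError("DMD dimensions must be positive")
        if not self.mirror_pitch_um > self.mirror_gap_um > 0:
            raise LayoutError("require pitch > gap > 0")

    @property
    def n_mirrors(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class Feature:
    feature_id: str
    top_row: int
    left_col: int
    height: int
    width: int

    @property
    def n_mirrors(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return (self.top_row + (self.height - 1) / 2.0,
                self.left_col + (self.width - 1) / 2.0)



@dataclass
class ArrayLayout:
    geometry: DmdGeometry
    design_name: str
    features: list[Feature]
    assignment: dict[str, str] = field(default_factory=dict)
    street: int = 0
    #: feature-grid (cell) coordinates, parallel to ``features``
    cell_coords: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {f.feature_id: f for f in self.features}
        self._cell_of = dict(zip([f.feature_id for f in self.features],
                                 self.cell_coords))
        self._id_of_cell = {c: fid for fid, c in self._cell_of.items()}

    def __len__(self) -> int:
        return len(self.features)

    def feature(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def cell_of(self, feature_id: str) -> tuple[int, int]:
        return self._cell_of[feature_id]

    def feature_at_cell(self, cell: tuple[int, int]) -> str | None:
        return self._id_of_cell.get(cell)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def oligo_of(self, feature_id: str) -> str:
        return self.assignment[feature_id]

    def feature_edge_um(self) -> float:
        """Edge length of a feature in um (feature mirrors x mirror pitch)."""
        return self.features[0].height * self.geometry.mirror_pitch_um

    def neighbor_ids(self, feature_id: str, diagonal: bool) -> list[str]:
        """Feature ids in side-adjacent (or corner-adjacent) grid cells."""
        r, c = self._cell_of[feature_id]
        if diagonal:
            deltas = [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        else:
            deltas = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        out = []
        for dr, dc in deltas:
            fid = self._id_of_cell.get((r + dr, c + dc))
            if fid is not None:
                out.append(fid)
        return out

    def normalized_center_distance(self, feature_id: str, norm: str = "max") -> float:
        """Distance of a feature's center from the array center, in [0, 1].

        ``norm="max"`` is the Chebyshev distance with each axis scaled to its
        half-extent (the whole border has r=1).  ``norm="euclid"`` scales the
        per-axis offsets the same way but combines them radially (corners r=1,
        edge midpoints r≈0.71), which is the profile used for illumination.
        """
        f = self._by_id[feature_id]
        fr, fc = f.center
        g = self.geometry
        cr, cc = (g.rows - 1) / 2.0, (g.cols - 1) / 2.0
        dr = abs(fr - cr) / cr if cr else 0.0
        dc = abs(fc - cc) / cc if cc else 0.0
        if norm == "max":
            return min(1.0, max(dr, dc))
        if norm == "euclid":
            return min(1.0, math.hypot(dr, dc) / math.sqrt(2.0))
        raise ValueError(f"unknown norm {norm!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, (cr, cc) in zip(self.features, self.cell_coords):
            rows.append({
                "feature_id": f.feature_id,
                "row": f.top_row, "col": f.left_col,
                "height": f.height, "width": f.width,
                "cell_row": cr, "cell_col": cc,
                "oligo_id": self.assignment.get(f.feature_id, ""),
                "area": concentric_area_of(self, f.feature_id),
            })
        return pd.DataFrame(rows)


def design_capacity(design: str, geometry: DmdGeometry) -> int:
    """Maximum number of features the design supports on this DMD."""
    if design in GRID_DESIGNS:
        feat, street = GRID_DESIGNS[design]
        unit = feat + street
        return (geometry.rows // unit) * (geometry.cols // unit)
    if design == "CB":
        return (geometry.n_mirrors + 1) // 2
    if design == "FULL":
        return geometry.n_mirrors
    raise LayoutError(f"unknown design {design!r}")


def build_layout(
    design: str,
    geometry: DmdGeometry | None = None,
    n_features: int | None = None,
    seed: int = 0,
    oligo_ids: list[str] | None = None,
) -> ArrayLayout:
    """Place *n_features* on the DMD and (optionally) assign oligos to them.

    Features fill unit cells row-major from the origin; leftover border
    mirrors stay unused.  When *oligo_ids* is given, the oligo->feature
    assignment is a seeded random permutation (sequences are spread over the
    surface rather than laid out in design order).
    """
    geometry = geometry or DmdGeometry()
    cap = design_capacity(design, geometry)
    if n_features is None:
        n_features = len(oligo_ids) if oligo_ids is not None else cap
    if n_features > cap:
        raise LayoutError(
            f"{design} on {geometry.rows}x{geometry.cols} holds at most "
            f"{cap} features ({n_features} requested)"
        )
    if oligo_ids is not None and len(oligo_ids) != n_features:
        raise LayoutError("oligo_ids length != n_features")

    feats: list[Feature] = []
    cells: list[tuple[int, int]] = []
    width = len(str(max(n_features - 1, 1)))
    if design in GRID_DESIGNS:
        feat, street = GRID_DESIGNS[design]
        unit = feat + street
        ncr, ncc = geometry.rows // unit, geometry.cols // unit
        k = 0
        for cr in range(ncr):
            for cc in range(ncc):
                if k >= n_features:
                    break
                feats.append(Feature(f"F{k:0{width}d}", cr * unit, cc * unit,
                                     feat, feat))
                cells.append((cr, cc))
                k += 1
            if k >= n_features:
                break
    elif design in ("CB", "FULL"):
        k = 0
        for r in range(geometry.rows):
            for c in range(geometry.cols):
                if design == "CB" and (r + c) % 2 == 1:
                    continue
                if k >= n_features:
                    break
                feats.append(Feature(f"F{k:0{width}d}", r, c, 1, 1))
                cells.append((r, c))
                k += 1
            if k >= n_features:
                break
    else:
        raise LayoutError(f"unknown design {design!r}")

    assignment: dict[str, str] = {}
    if oligo_ids is not None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(oligo_ids))
        assignment = {
            feats[i].feature_id: oligo_ids[perm[i]] for i in range(n_features)
        }
    street = GRID_DESIGNS.get(design, (1, 0))[1]
    return ArrayLayout(geometry=geometry, design_name=design, features=feats,
                       assignment=assignment, street=street, cell_coords=cells)


def active_mirror_fraction(layout: ArrayLayout | None = None,
                           design: str | None = None) -> float:
    """Fraction of mirrors inside feature blocks.

    With a *layout*, the fraction is computed over the tiled region (complete
    unit cells for gridded designs, the whole DMD otherwise).  With only a
    *design* name, the infinite-tiling unit-cell ratio is returned (16/36 for
    2SZ, 4/36 for 4SZ, 1/2 for CB, 1 for FULL).
    """
    if layout is None:
        if design is None:
            raise ValueError("provide a layout or a design name")
        if design in GRID_DESIGNS:
            feat, street = GRID_DESIGNS[design]
            return feat**2 / (feat + street) ** 2
        if design == "CB":
            return 0.5
        if design == "FULL":
            return 1.0
        raise LayoutError(f"unknown design {design!r}")
    g = layout.geometry
    if layout.design_name in GRID_DESIGNS:
        feat, street = GRID_DESIGNS[layout.design_name]
        unit = feat + street
        total = (g.rows // unit) * unit * (g.cols // unit) * unit
    else:
        total = g.n_mirrors
    active = sum(f.n_mirrors for f in layout.features)
    return active / total


def cycles_required(sequence: str) -> int:
    """Number of A->C->G->T cycles needed to synthesize *sequence* (5'->3').

    Synthesis is 3'->5'; the first synthesized base waits for its first slot
    in the cycle order, each further base for its next slot.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(COUPLING_ORDER)
    if bad:
        raise ValueError(f"invalid characters: {sorted(bad)}")
    total = 0
    prev: int | None = None
    for base in reversed(sequence):  # 3'->5' synthesis order
        idx = _ORDER_INDEX[base]
        if prev is None:
            total += idx + 1
        else:
            total += (idx - prev - 1) % 4 + 1
        prev = idx
    return total


@dataclass
class MaskStack:
    """Ordered per-cycle exposure patterns: (cycle index, base, ON features)."""

    cycles: list[tuple[int, str, frozenset[str]]]
    layout: ArrayLayout | None = None

    def __len__(self) -> int:
        return len(self.cycles)

    def on_cycles_of(self, feature_id: str) -> list[tuple[int, str]]:
        return [(c, b) for c, b, on in self.cycles if feature_id in on]

    def decode_feature(self, feature_id: str) -> str:
        """Reconstruct the feature's sequence (5'->3') from its ON cycles."""
        bases_3to5 = [b for _, b, on in self.cycles if feature_id in on]
        return "".join(reversed(bases_3to5))

    def bitmap(self, cycle: int) -> np.ndarray:
        """Boolean mirror bitmap (rows x cols) for one cycle; needs a layout."""
        if self.layout is None:
            raise LayoutError("MaskStack has no layout attached")
        g = self.layout.geometry
        img = np.zeros((g.rows, g.cols), dtype=bool)
        _, _, on = self.cycles[cycle]
        for fid in on:
            f = self.layout.feature(fid)
            img[f.top_row:f.top_row + f.height,
                f.left_col:f.left_col + f.width] = True
        return img

    def on_mirror_fraction(self, cycle: int) -> float:
        if self.layout is None:
            raise LayoutError("MaskStack has no layout attached")
        _, _, on = self.cycles[cycle]
        active = sum(self.layout.feature(fid).n_mirrors for fid in on)
        return active / self.layout.geometry.n_mirrors


def generate_masks(layout: ArrayLayout, sequences: dict[str, str]) -> MaskStack:
    """Build the per-cycle ON/OFF mask stack for an assigned layout.

    *sequences* maps oligo id -> 5'->3' sequence.  Every feature must be
    assigned.  The stack length is the maximum :func:`cycles_required` over
    the panel; trailing all-OFF cycles are trimmed.
    """
    pending: dict[str, list[str]] = {}
    for f in layout.features:
        oid = layout.assignment.get(f.feature_id)
        if oid is None:
            raise LayoutError(f"feature {f.feature_id} has no assigned oligo")
        seq = sequences[oid]
        pending[f.feature_id] = list(reversed(seq))  # 3'->5' queue
    n_cycles = max(cycles_required("".join(reversed(q)))
                   for q in pending.values())
    cycles = []
    for c in range(n_cycles):
        base = COUPLING_ORDER[c % 4]
        on = frozenset(
            fid for fid, q in pending.items() if q and q[0] == base
        )
        for fid in on:
            pending[fid].pop(0)
        cycles.append((c, base, on))
    while cycles and not cycles[-1][2]:
        cycles.pop()
    return MaskStack(cycles=cycles, layout=layout)


def concentric_area_of(layout: ArrayLayout, feature_id: str,
                       n_areas: int = 4) -> int:
    """Concentric-rectangle area index: 1 = innermost, n_areas = outer ring.

    Rings have equal width in the normalized Chebyshev distance, so area
    ``n_areas`` contains the array border including all four corners.
    """
    r = layout.normalized_center_distance(feature_id, norm="max")
    return min(n_areas, int(r * n_areas) + 1)


# ---------------------------------------------------------------------------
# PBM (portable bitmap, ASCII P1) mask files.  ON mirrors are written as 1
# (black).  One file per cycle, named mask_<cycle>_<base>.pbm.
# ---------------------------------------------------------------------------

def write_pbm(path: str | Path, bitmap: np.ndarray) -> None:
    rows, cols = bitmap.shape
    lines = ["P1", f"{cols} {rows}"]
    lines.extend(" ".join("1" if v else "0" for v in row) for row in bitmap)
    Path(path).write_text("\n".join(lines) + "\n")


def read_pbm(path: str | Path) -> np.ndarray:
    tokens = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not an ASCII PBM (P1) file")
    cols, rows = int(tokens[1]), int(tokens[2])
    data = np.array([int(t) for t in tokens[3:3 + rows * cols]], dtype=bool)
    if data.size != rows * cols:
        raise ValueError(f"{path}: expected {rows * cols} pixels, got {data.size}")
    return data.reshape(rows, cols)


def write_masks(stack: MaskStack, directory: str | Path) -> list[Path]:
    if stack.layout is None:
        raise LayoutError("MaskStack has no layout attached")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(max(len(stack) - 1, 1)))
    paths = []
    for c, base, _ in stack.cycles:
        p = directory / f"mask_{c:0{width}d}_{base}.pbm"
        write_pbm(p, stack.bitmap(c))
        paths.append(p)
    return paths


def read_masks(directory: str | Path, layout: ArrayLayout) -> MaskStack:
    """Rebuild a MaskStack from PBM files; inverse of :func:`write_masks`."""
    directory = Path(directory)
    pat = re.compile(r"mask_(\d+)_([ACGT])\.pbm$")
    found = []
    for p in sorted(directory.glob("mask_*.pbm")):
        m = pat.search(p.name)
        if m:
            found.append((int(m.group(1)), m.group(2), p))
    found.sort()
    g = layout.geometry
    cycles = []
    for c, base, p in found:
        img = read_pbm(p)
        if img.shape != (g.rows, g.cols):
            raise ValueError(
                f"{p}: dimensions {img.shape} != DMD ({g.rows}, {g.cols})"
            )
        if base != COUPLING_ORDER[c % 4]:
            raise ValueError(f"{p}: base {base} inconsistent with cycle {c}")
        on = []
        for f in layout.features:
            block = img[f.top_row:f.top_row + f.height,
                        f.left_col:f.left_col + f.width]
            if block.all():
                on.append(f.feature_id)
            elif block.any():
                raise ValueError(f"{p}: feature {f.feature_id} partially ON")
        cycles.append((c, base, frozenset(on)))
    return MaskStack(cycles=cycles, layout=layout)
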