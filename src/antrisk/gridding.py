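"""Grid-based quantification of invasion outcome between two survey waves.

The island is divided into square cells (200 m by default). Each cell is
marked, per survey wave, with the severity scale of its most severe sampling
tube (ordinal 0-3). Comparing the two waves classifies every cell as

* ``SIRH`` — successful invasion or remaining at the highest level: the cell's
  maximum scale increased, or stayed at scale 3 in both waves;
* ``USIRL`` — unsuccessful invasion or remaining at low levels: the maximum
  scale decreased, or stayed constant below scale 3;
* ``undefined`` — the cell was not sampled in one (or both) of the waves.

Wave-2 tubes then inherit their cell's binary label for modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIRH = "SIRH"
USIRL = "USIRL"
UNDEFINED = "undefined"

VALID_SCALES = (0, 1, 2, 3)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the square surveillance grid (planar meters).

    Cell ``(i, j)`` (row, column) covers the half-open rectangle
    ``[origin_x + j*cs, origin_x + (j+1)*cs) x [origin_y + i*cs, origin_y + (i+1)*cs)``;
    points on the top/right boundary of the grid are assigned to the last
    row/column so the closed extent is fully covered.
    """

    origin_x: float
    origin_y: float
    cell_size: float = 200.0
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @classmethod
    def from_extent(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, cell_size: float = 200.0
    ) -> "GridSpec":
        """Smallest grid with this origin/cell size covering the extent."""
        n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size - 1e-9)))
        n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size - 1e-9)))
        return cls(xmin, ymin, cell_size, n_rows, n_cols)

    @property
    def xmax(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def ymax(self) -> float:
        return self.origin_y + self.n_rows * self.cell_size

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        cs = self.cell_size
        return (self.origin_x + (j + 0.5) * cs, self.origin_y + (i + 0.5) * cs)


def cell_index(x, y, grid: GridSpec):
    """Map point(s) to (row, col) cell indices with half-open binning.

    Points on the grid's top/right outer boundary fall in the last cell.
    Points outside the grid extent raise ``ValueError`` naming the offending
    coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    bad = (
        (x < grid.origin_x)
        | (x > grid.xmax)
        | (y < grid.origin_y)
        | (y > grid.ymax)
    )
    if np.any(bad):
        k = int(np.argmax(bad))
        raise ValueError(
            f"point ({x[k]}, {y[k]}) lies outside the grid extent "
            f"[{grid.origin_x}, {grid.xmax}] x [{grid.origin_y}, {grid.ymax}]"
        )
    j = np.minimum(
        np.floor((x - grid.origin_x) / grid.cell_size).astype(int), grid.n_cols - 1
    )
    i = np.minimum(
        np.floor((y - grid.origin_y) / grid.cell_size).astype(int), grid.n_rows - 1
    )
    if scalar:
        return int(i[0]), int(j[0])
    return i, j


def max_scale_per_cell(tubes: pd.DataFrame, grid: GridSpec) -> dict[tuple[int, int], int]:
    """Per-cell maximum severity scale for one survey wave.

    ``tubes`` needs columns ``x``, ``y``, ``scale``. Cells with no tube are
    absent from the result.
    """
    if len(tubes) == 0:
        return {}
    scales = np.asarray(tubes["scale"])
    if not np.isin(scales, VALID_SCALES).all():
        bad = sorted(set(scales) - set(VALID_SCALES))
        raise ValueError(f"severity scale(s) outside 0-3: {bad}")
    i, j = cell_index(tubes["x"].to_numpy(), tubes["y"].to_numpy(), grid)
    out: dict[tuple[int, int], int] = {}
    for ii, jj, s in zip(i, j, scales):
        key = (int(ii), int(jj))
        s = int(s)
        if s > out.get(key, -1):
            out[key] = s
    return out


def classify_cell(s1, s2) -> str:
    """Classify one cell from its two per-wave maximum scales.

    ``None`` (or NaN) means the cell was unsampled in that wave. SIRH iff the
    scale increased or remained at 3; USIRL iff it decreased or remained
    constant below 3; undefined iff either wave is missing. Total and mutually
    exclusive by construction.
    """
    def missing(s):
        return s is None or (isinstance(s, float) and np.isnan(s))

    if missing(s1) or missing(s2):
        return UNDEFINED
    s1, s2 = int(s1), int(s2)
    for s in (s1, s2):
        if s not in VALID_SCALES:
            raise ValueError(f"severity scale outside 0-3: {s}")
    if s2 > s1 or (s1 == 3 and s2 == 3):
        return SIRH
    return USIRL


def classify_cells(
    wave1_tubes: pd.DataFrame, wave2_tubes: pd.DataFrame, grid: GridSpec
) -> pd.DataFrame:
    """Full cell table: per-wave max scales and SIRH/USIRL/undefined label.

    Includes every cell sampled in at least one wave.
    """
    m1 = max_scale_per_cell(wave1_tubes, grid)
    m2 = max_scale_per_cell(wave2_tubes, grid)
    rows = []
    for key in sorted(set(m1) | set(m2)):
        s1, s2 = m1.get(key), m2.get(key)
        rows.append(
            {
                "i": key[0],
                "j": key[1],
                "max_s1": s1,
                "max_s2": s2,
                "label": classify_cell(s1, s2),
            }
        )
    return pd.DataFrame(rows, columns=["i", "j", "max_s1", "max_s2", "label"])


def label_tubes(
    wave2_tubes: pd.DataFrame, cells: pd.DataFrame, grid: GridSpec
) -> tuple[pd.DataFrame, int]:
    """Assign each wave-2 tube its cell's binary SIRH indicator.

    Returns ``(labelled, n_excluded)``: tubes in defined cells with an added
    ``y`` column (1 = SIRH, 0 = USIRL), and the count of tubes dropped because
    their cell is undefined. Labelled + excluded equals the input count. The
    coordinate column ``y`` is renamed ``y_coord`` to free the name for the
    binary response.
    """
    i, j = cell_index(wave2_tubes["x"].to_numpy(), wave2_tubes["y"].to_numpy(), grid)
    label_map = {(r.i, r.j): r.label for r in cells.itertuples()}
    labels = np.array([label_map.get((ii, jj), UNDEFINED) for ii, jj in zip(i, j)])
    keep = labels != UNDEFINED
    labelled = wave2_tubes.loc[keep].rename(columns={"y": "y_coord"}).copy()
    labelled["y"] = (labels[keep] == SIRH).astype(int)
    labelled["cell_i"] = np.asarray(i)[keep]
    labelled["cell_j"] = np.asarray(j)[keep]
    return labelled, int((~keep).sum())
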