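"""Two-wave synthetic surveillance data with known invasion-risk structure.

The data-generating truth is the same logistic form the analysis fits: the
per-cell probability of a successful invasion (or remaining at the highest
severity) is

    P(SIRH) = invlogit( beta0 + landuse offset + g_cat(road distance) + field(x, y) )

with natural land cover as the zero-offset reference, an optional
category-specific distance effect and an optional smooth spatial field. Cell
labels are then translated back into per-tube severity-scale pairs that are
consistent with the classification rule, so the quantification stage can be
round-trip tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .covariates import REFERENCE_LEVEL, attach_covariates
from .gridding import GridSpec, SIRH, USIRL, cell_index
from .landscape import LandscapeBundle

#: severity pairs (wave1, wave2) consistent with each label
SIRH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (3, 3)]
USIRL_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 0), (2, 0), (2, 1), (3, 2), (3, 1), (3, 0)]


@dataclass
class TrueModel:
    """Data-generating truth on the log-odds scale.

    ``category_logodds`` maps each five-level land-use category to an additive
    offset (the reference, natural land cover, must be 0 — offsets are then
    log odds ratios versus natural). ``g_dist`` is either a single callable
    ``d -> log-odds`` shared by all categories, or a mapping from category to
    callable (a category-specific distance effect). ``spatial_field`` maps
    ``(x, y) -> log-odds``.
    """

    beta0: float = 0.0
    category_logodds: Mapping[str, float] = field(default_factory=dict)
    g_dist: Callable | Mapping[str, Callable] | None = None
    spatial_field: Callable | None = None

    def __post_init__(self) -> None:
        ref = self.category_logodds.get(REFERENCE_LEVEL, 0.0)
        if ref != 0.0:
            raise ValueError(
                f"reference category '{REFERENCE_LEVEL}' must carry log-odds 0, got {ref}"
            )

    def linear_predictor(self, category, road_dist, x, y) -> np.ndarray:
        category = np.asarray(category)
        road_dist = np.asarray(road_dist, float)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        lp = np.full(category.shape, self.beta0, dtype=float)
        for cat, off in self.category_logodds.items():
            lp[category == cat] += off
        if callable(self.g_dist):
            lp += self.g_dist(road_dist)
        elif self.g_dist is not None:
            for cat, g in self.g_dist.items():
                m = category == cat
                if m.any():
                    lp[m] += g(road_dist[m])
        if self.spatial_field is not None:
            lp += self.spatial_field(x, y)
        return lp

    def probability(self, category, road_dist, x, y) -> np.ndarray:
        return invlogit(self.linear_predictor(category, road_dist, x, y))


def invlogit(eta):
    eta = np.clip(np.asarray(eta, float), -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-eta))


def place_tubes(
    bundle: LandscapeBundle,
    grid: GridSpec,
    tubes_per_cell: int = 1,
    jitter: float = 20.0,
    seed: int = 0,
    sample_fraction: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place 1-2 tubes per grid cell for two survey waves.

    Wave-2 tube positions are the wave-1 positions perturbed by at most
    ``jitter`` meters in each axis, clamped so the tube never leaves its cell
    (surveyors relocate tubes slightly between years but stay in the grid
    square). Returns ``(wave1, wave2)`` tables with columns
    ``tube_id, x, y, period, cell_i, cell_j``.
    """
    if jitter >= grid.cell_size / 2:
        raise ValueError("jitter must be below half the cell size")
    if tubes_per_cell not in (1, 2):
        raise ValueError("tubes_per_cell must be 1 or 2")
    rng = np.random.default_rng(seed)
    eps = 1e-6
    rows1, rows2 = [], []
    tid = 0
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            if sample_fraction < 1.0 and rng.random() >= sample_fraction:
                continue
            x0 = grid.origin_x + j * grid.cell_size
            y0 = grid.origin_y + i * grid.cell_size
            hi = grid.cell_size - eps
            for _ in range(tubes_per_cell):
                xa = x0 + rng.uniform(0, hi)
                ya = y0 + rng.uniform(0, hi)
                xb = np.clip(xa + rng.uniform(-jitter, jitter), x0, x0 + hi)
                yb = np.clip(ya + rng.uniform(-jitter, jitter), y0, y0 + hi)
                rows1.append((f"t{tid:06d}", xa, ya, "wave1", i, j))
                rows2.append((f"t{tid:06d}", xb, yb, "wave2", i, j))
                tid += 1
    cols = ["tube_id", "x", "y", "period", "cell_i", "cell_j"]
    return pd.DataFrame(rows1, columns=cols), pd.DataFrame(rows2, columns=cols)


def simulate_sirh_labels(
    table: pd.DataFrame, truth: TrueModel, seed: int = 0
) -> pd.DataFrame:
    """Draw one Bernoulli SIRH indicator per cell from the true model.

    ``table`` carries one representative row per cell with covariates attached
    (columns ``landuse5, road_dist, x, y_coord`` and cell indices
    ``cell_i, cell_j``). Returns the table with added ``p_true`` and ``label``
    columns.
    """
    for col in ("landuse5", "road_dist"):
        if col not in table:
            raise ValueError(f"covariate column '{col}' missing; attach covariates first")
    rng = np.random.default_rng(seed)
    p = truth.probability(
        table["landuse5"].to_numpy(),
        table["road_dist"].to_numpy(float),
        table["x"].to_numpy(float),
        table["y_coord"].to_numpy(float),
    )
    draw = rng.random(len(table)) < p
    out = table.copy()
    out["p_true"] = p
    out["label"] = np.where(draw, SIRH, USIRL)
    return out


def labels_to_severity(labels, seed: int = 0) -> np.ndarray:
    """Draw a (wave1, wave2) severity-scale pair consistent with each label.

    SIRH cells get a strictly increasing pair or (3, 3); USIRL cells get a
    non-increasing pair that is not (3, 3). Pairs are drawn uniformly within
    each consistent set (the surveillance record gives no within-class
    transition frequencies). Classifying the pair recovers the label exactly.
    """
    labels = np.asarray(labels)
    bad = set(labels) - {SIRH, USIRL}
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    rng = np.random.default_rng(seed)
    sirh_pairs = np.array(SIRH_PAIRS)
    usirl_pairs = np.array(USIRL_PAIRS)
    out = np.empty((len(labels), 2), dtype=int)
    is_s = labels == SIRH
    out[is_s] = sirh_pairs[rng.integers(0, len(sirh_pairs), is_s.sum())]
    out[~is_s] = usirl_pairs[rng.integers(0, len(usirl_pairs), (~is_s).sum())]
    return out


def simulate_survey(
    bundle: LandscapeBundle,
    grid: GridSpec,
    truth: TrueModel,
    tubes_per_cell: int = 1,
    jitter: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full generator: tubes for two waves with severity scales.

    Returns ``(wave1, wave2, cell_truth)``. Tube tables carry
    ``tube_id, x, y, period, scale``; ``cell_truth`` carries the per-cell true
    probability and drawn label for diagnostics. All tubes in a cell share the
    cell's severity scale (per-wave), so the per-cell maximum equals it.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    wave1, wave2 = place_tubes(
        bundle, grid, tubes_per_cell=tubes_per_cell, jitter=jitter, seed=int(seeds[0])
    )
    # representative wave-2 tube per cell carries the covariates for the draw
    rep = wave2.drop_duplicates(["cell_i", "cell_j"])
    rep_in = pd.DataFrame(
        {"tube_id": rep["tube_id"], "x": rep["x"], "y_coord": rep["y"], "y": 0}
    )
    rep_cov = attach_covariates(rep_in, bundle)
    rep_cov["cell_i"] = rep["cell_i"].to_numpy()
    rep_cov["cell_j"] = rep["cell_j"].to_numpy()
    cell_truth = simulate_sirh_labels(rep_cov, truth, seed=int(seeds[1]))
    pairs = labels_to_severity(cell_truth["label"].to_numpy(), seed=int(seeds[2]))
    cell_truth = cell_truth.assign(s1=pairs[:, 0], s2=pairs[:, 1])

    key = ["cell_i", "cell_j"]
    s_map = cell_truth.set_index(key)[["s1", "s2"]]
    wave1 = wave1.join(s_map["s1"].rename("scale"), on=key)
    wave2 = wave2.join(s_map["s2"].rename("scale"), on=key)
    cols = ["tube_id", "x", "y", "period", "scale"]
    return wave1[cols], wave2[cols], cell_truth


def simulate_model_table(
    n: int,
    truth: TrueModel,
    seed: int = 0,
    category_probs: Mapping[str, float] | None = None,
    dist_max: float = 300.0,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 4000.0, 4000.0),
) -> pd.DataFrame:
    """Table-level simulator: draw covariates directly and y from the truth.

    Categories are drawn i.i.d. from ``category_probs`` (default: the
    surveillance frequencies — transportation .262, agriculture .252, natural
    .250, change .172, artificial .063), road distances uniformly on
    ``[0, dist_max]`` and coordinates uniformly on the extent. Returns a model
    table with columns ``tube_id, y, landuse5, road_dist, x, y_coord`` plus
    ``p_true``.
    """
    probs = dict(
        category_probs
        or {
            "transportation": 1814 / 6918,
            "agriculture": 1743 / 6918,
            "natural": 1730 / 6918,
            "change": 1193 / 6918,
            "artificial": 438 / 6918,
        }
    )
    rng = np.random.default_rng(seed)
    cats = rng.choice(list(probs), p=np.array(list(probs.values())), size=n)
    dist = rng.uniform(0.0, dist_max, n)
    xmin, ymin, xmax, ymax = extent
    x = rng.uniform(xmin, xmax, n)
    yc = rng.uniform(ymin, ymax, n)
    p = truth.probability(cats, dist, x, yc)
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "tube_id": [f"t{k:06d}" for k in range(n)],
            "y": y,
            "landuse5": cats,
            "road_dist": dist,
            "x": x,
            "y_coord": yc,
            "p_true": p,
        }
    )
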