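"""Model assembly, comparison, and the descriptive / mapping outputs.

Three risk models of the binary SIRH indicator are fitted on the tube-level
model table (columns ``y, landuse5, road_dist, x, y_coord``):

* ``GLM`` — fully parametric logit: land-use dummies + linear road distance
  + linear x, y and the bilinear x*y coordinate term.
* ``GAM1`` — land-use dummies + one penalized smooth of road distance + a
  tensor-product spatial smooth of (x, y).
* ``GAM2`` — as GAM1 but with a separate distance smooth per land-use
  category (factor-by smooths), so each category can have its own
  distance-risk curve.

The three are nested (the GLM's linear terms span the smooths' penalty null
spaces), so AIC and deviance ANOVA comparisons are meaningful.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import LANDUSE5_LEVELS, REFERENCE_LEVEL
from .gam import (
    Categorical,
    GAMResults,
    Linear,
    LogisticGAM,
    Smooth1D,
    SmoothTensor2D,
    anova_compare,
)
from .gridding import GridSpec, SIRH, USIRL
from .landscape import LandscapeBundle

MODEL_NAMES = ("GLM", "GAM1", "GAM2")


def round1(x: float) -> float:
    """Round half-up to one decimal (table formatting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Model assembly


def build_model(
    name: str,
    table: pd.DataFrame,
    k_dist: int = 10,
    k_spatial: int = 6,
    fit: bool = True,
    **fit_kwargs,
):
    """Assemble (and by default fit) one of the three risk models.

    ``table`` must contain every land-use level present in training later
    used for prediction; natural land cover is the dummy reference.
    Returns a :class:`GAMResults` (or the unfitted :class:`LogisticGAM` with
    ``fit=False``).
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model '{name}'; expected one of {MODEL_NAMES}")
    cats = set(table["landuse5"].astype(str))
    missing = set(LANDUSE5_LEVELS) - cats
    if missing:
        raise ValueError(f"land-use level(s) missing from data: {sorted(missing)}")

    terms = [Categorical("landuse5", REFERENCE_LEVEL, component="landuse")]
    if name == "GLM":
        terms.append(Linear(["road_dist"], component="distance"))
        terms.append(
            Linear(
                ["x", "y_coord"],
                product_pairs=[("x", "y_coord")],
                component="spatial",
            )
        )
    elif name == "GAM1":
        terms.append(Smooth1D("road_dist", k=k_dist, component="distance"))
        terms.append(SmoothTensor2D("x", "y_coord", k_marginal=k_spatial))
    else:  # GAM2: factor-by distance smooths, one per land-use category
        for level in LANDUSE5_LEVELS:
            terms.append(
                Smooth1D(
                    "road_dist", k=k_dist, by="landuse5", by_level=level,
                    component="distance",
                )
            )
        terms.append(SmoothTensor2D("x", "y_coord", k_marginal=k_spatial))

    model = LogisticGAM(table["y"].to_numpy(), table, terms)
    if not fit:
        return model
    return model.fit(**fit_kwargs)


def compare_models(fits: dict[str, GAMResults]) -> dict:
    """AIC table plus nested ANOVA chain GLM ⊂ GAM1 ⊂ GAM2.

    All fits must be on identical rows. The selected model is the AIC
    minimizer.
    """
    ns = {k: f.nobs for k, f in fits.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"fits are not on identical rows: n = {ns}")
    aic = {k: f.aic for k, f in fits.items()}
    report = {
        "aic": aic,
        "edf": {k: f.edf_total for k, f in fits.items()},
        "deviance": {k: f.deviance for k, f in fits.items()},
        "selected": min(aic, key=aic.get),
        "anova": {},
    }
    chain = [m for m in MODEL_NAMES if m in fits]
    for small, big in zip(chain[:-1], chain[1:]):
        try:
            report["anova"][f"{small}_vs_{big}"] = anova_compare(fits[small], fits[big])
        except ValueError as err:
            report["anova"][f"{small}_vs_{big}"] = {"error": str(err)}
    return report


# ---------------------------------------------------------------------------
# Descriptive statistics


def contingency_and_chi2(data) -> dict:
    """Label-by-category contingency table with row percentages and Pearson χ².

    ``data`` is either a labelled model table (columns ``y``/``label`` and
    ``landuse5``) or a mapping ``{category: (n_usirl, n_sirh)}`` of counts.
    Percentages are row percentages (within category), rounded half-up to one
    decimal. χ² is the plain Pearson statistic (no continuity correction).
    """
    if isinstance(data, pd.DataFrame):
        lab = data["label"] if "label" in data else np.where(data["y"] == 1, SIRH, USIRL)
        counts = {}
        for cat in pd.unique(data["landuse5"]):
            m = data["landuse5"] == cat
            counts[str(cat)] = (
                int(np.sum(np.asarray(lab)[m] == USIRL)),
                int(np.sum(np.asarray(lab)[m] == SIRH)),
            )
    else:
        counts = {k: (int(v[0]), int(v[1])) for k, v in data.items()}

    cats = [c for c in counts if sum(counts[c]) > 0]
    dropped = [c for c in counts if sum(counts[c]) == 0]
    obs = np.array([counts[c] for c in cats], dtype=float)  # rows: cat, cols: USIRL, SIRH
    row_tot = obs.sum(axis=1)
    pct = {
        c: {
            "n": int(row_tot[i]),
            "usirl_n": int(obs[i, 0]),
            "sirh_n": int(obs[i, 1]),
            "usirl_pct": round1(100 * obs[i, 0] / row_tot[i]),
            "sirh_pct": round1(100 * obs[i, 1] / row_tot[i]),
        }
        for i, c in enumerate(cats)
    }
    col_tot = obs.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (len(cats) - 1) * 1
    return {
        "table": pct,
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan"),
        "dropped_categories": dropped,
        "total_n": int(obs.sum()),
    }


def severity_summary(tubes) -> dict:
    """Per-scale tube counts and percentages for one survey wave.

    ``tubes`` is a DataFrame with a ``scale`` column or a mapping
    ``{scale: count}``. Percentages are of the wave total, half-up one
    decimal.
    """
    if isinstance(tubes, pd.DataFrame):
        counts = tubes["scale"].value_counts().to_dict()
    else:
        counts = dict(tubes)
    bad = set(counts) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"severity scale(s) outside 0-3: {sorted(bad)}")
    total = sum(counts.values())
    return {
        "n_total": int(total),
        "scales": {
            int(s): {"n": int(counts.get(s, 0)),
                     "pct": round1(100 * counts.get(s, 0) / total) if total else 0.0}
            for s in (0, 1, 2, 3)
        },
    }


def change_flow_summary(
    change_tubes: pd.DataFrame, bundle: LandscapeBundle
) -> dict:
    """Transition-pair percentages for tubes in the land-use-change category.

    Looks up each tube's year-A and year-B category and tabulates the
    percentage per ordered (A → B) pair; the "development-related" aggregate
    is the share converted out of natural land cover.
    """
    from .covariates import categories_at_points

    xs = change_tubes["x"].to_numpy(float)
    ys = (
        change_tubes["y_coord"] if "y_coord" in change_tubes else change_tubes["y"]
    ).to_numpy(float)
    ca = categories_at_points(xs, ys, bundle.landuse_a)
    cb = categories_at_points(xs, ys, bundle.landuse_b)
    if np.any(ca == cb):
        raise ValueError("input contains tubes whose category did not change")
    pairs = pd.Series([f"{a}->{b}" for a, b in zip(ca, cb)])
    pct = (100 * pairs.value_counts() / len(pairs)).round(1).to_dict()
    dev = float(100 * np.mean(ca == "natural"))
    return {
        "n": len(pairs),
        "transitions_pct": pct,
        "development_related_pct": round1(dev),
    }


# ---------------------------------------------------------------------------
# Distance-probability curves and risk surfaces


def distance_curve(
    fit: GAMResults,
    category: str,
    d_max: float = 600.0,
    step: float = 1.0,
    x: float | None = None,
    y: float | None = None,
) -> pd.DataFrame:
    """Fitted P(SIRH) vs distance-to-road for one land-use category.

    Other covariates are held fixed: the category at the requested level and
    the coordinates at the training means (unless given).
    """
    data = fit.model.data
    d = np.arange(0.0, d_max + step / 2, step)
    new = pd.DataFrame(
        {
            "road_dist": d,
            "landuse5": category,
            "x": x if x is not None else float(data["x"].mean()),
            "y_coord": y if y is not None else float(data["y_coord"].mean()),
        }
    )
    p = fit.predict(new, kind="response")
    return pd.DataFrame({"distance": d, "p": p})


def threshold_from_curve(curve: pd.DataFrame, p0: float) -> float:
    """Largest d* such that the curve stays ≥ p0 on the whole range [0, d*].

    Returns 0 (with the curve untouched) when the probability at distance 0
    is already below p0.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    p = curve["p"].to_numpy()
    d = curve["distance"].to_numpy()
    below = p < p0
    if below[0]:
        return 0.0
    if not below.any():
        return float(d[-1])
    return float(d[int(np.argmax(below)) - 1])


def distance_threshold(
    fit: GAMResults, category: str, p0: float, d_max: float = 600.0, step: float = 1.0
) -> tuple[float, pd.DataFrame]:
    """Maximum contiguous-from-zero road distance with P(SIRH) ≥ p0.

    Scans the fitted distance-probability curve for the category at ``step``
    resolution (default 1 m) from 0 to ``d_max``; returns (d*, curve).
    """
    curve = distance_curve(fit, category, d_max=d_max, step=step)
    return threshold_from_curve(curve, p0), curve


def risk_surface(
    fit: GAMResults, grid: GridSpec, bundle: LandscapeBundle
) -> pd.DataFrame:
    """Cell-center risk map with component-wise linear predictors.

    Covariates at each cell center come from the landscape (land-use overlay
    and nearest-road distance). Columns: ``i, j, x_center, y_center, p, lp0,
    lp_landuse, lp_dist, lp_spatial``; the four lp columns sum to the full
    linear predictor. Cells whose center falls outside the bundle extent are
    masked (dropped).
    """
    from .covariates import categories_at_points, nearest_road_distances

    ii, jj = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    xc = grid.origin_x + (jj + 0.5) * grid.cell_size
    yc = grid.origin_y + (ii + 0.5) * grid.cell_size
    xmin, ymin, xmax, ymax = bundle.extent
    inside = (xc >= xmin) & (xc <= xmax) & (yc >= ymin) & (yc <= ymax)
    ii, jj, xc, yc = ii[inside], jj[inside], xc[inside], yc[inside]

    ca = categories_at_points(xc, yc, bundle.landuse_a)
    cb = categories_at_points(xc, yc, bundle.landuse_b)
    lu5 = np.where(ca == cb, ca, "change")
    dist = nearest_road_distances(xc, yc, bundle.roads)
    new = pd.DataFrame({"landuse5": lu5, "road_dist": dist, "x": xc, "y_coord": yc})
    comps = fit.predict_components(new)
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "x_center": xc,
            "y_center": yc,
            "p": comps["p"],
            "lp0": comps.get("intercept", 0.0),
            "lp_landuse": comps.get("landuse", 0.0),
            "lp_dist": comps.get("distance", 0.0),
            "lp_spatial": comps.get("spatial", 0.0),
        }
    )
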