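"""Logistic additive models with penalized B-spline smooths.

statsmodels-style surface: build a :class:`LogisticGAM` from a data frame and
a list of terms, call :meth:`~LogisticGAM.fit` (penalized IRLS; smoothing
parameters fixed or selected by GCV), get a :class:`GAMResults` carrying
coefficients, covariance, per-term effective degrees of freedom, deviance,
AIC, odds-ratio and smooth-term test tables, prediction with component-wise
decomposition of the linear predictor, and a ``summary()`` report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .basis import (
    BSplineBasis,
    center_transform,
    difference_penalty,
    tensor_design,
    tensor_penalties,
)

logger = logging.getLogger(__name__)

_CLIP = 30.0


def _invlogit(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_CLIP, _CLIP)))


def _deviance(y, mu):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


# ---------------------------------------------------------------------------
# Terms


class Term:
    """One additive component of the linear predictor."""

    name: str
    component: str = "other"  # grouping label for prediction decomposition
    penalties: list  # list of (within-block penalty matrix)

    @property
    def n_cols(self) -> int:
        raise NotImplementedError

    def build_train(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def build(self, data: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    @property
    def is_smooth(self) -> bool:
        return bool(self.penalties)


class Intercept(Term):
    name = "(Intercept)"
    component = "intercept"
    penalties: list = []

    @property
    def n_cols(self) -> int:
        return 1

    def build_train(self, data):
        return np.ones((len(data), 1))

    build = build_train

    def labels(self):
        return [self.name]


class Linear(Term):
    """Linear columns, internally standardized for conditioning.

    ``product_pairs`` adds interaction columns (elementwise products of two
    named covariates), e.g. the bilinear x*y coordinate term of a GLM.
    """

    penalties: list = []

    def __init__(self, cols, name=None, component="other", product_pairs=()):
        self.cols = list(cols)
        self.product_pairs = [tuple(p) for p in product_pairs]
        self.name = name or "+".join(self.cols + ["*".join(p) for p in self.product_pairs])
        self.component = component
        self._mean = None
        self._scale = None

    @property
    def n_cols(self) -> int:
        return len(self.cols) + len(self.product_pairs)

    def _raw(self, data):
        mats = [np.asarray(data[c], float) for c in self.cols]
        mats += [
            np.asarray(data[a], float) * np.asarray(data[b], float)
            for a, b in self.product_pairs
        ]
        return np.column_stack(mats)

    def build_train(self, data):
        X = self._raw(data)
        self._mean = X.mean(axis=0)
        self._scale = X.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        return (X - self._mean) / self._scale

    def build(self, data):
        return (self._raw(data) - self._mean) / self._scale

    def labels(self):
        return self.cols + ["*".join(p) for p in self.product_pairs]


class Categorical(Term):
    """Treatment-coded dummies with an explicit reference level."""

    penalties: list = []

    def __init__(self, col, reference, name=None, component="landuse"):
        self.col = col
        self.reference = reference
        self.name = name or f"C({col})"
        self.component = component
        self.levels_: list[str] | None = None

    @property
    def n_cols(self) -> int:
        return len(self.levels_)

    def build_train(self, data):
        vals = data[self.col].astype(str)
        levels = sorted(set(vals))
        if self.reference not in levels:
            raise ValueError(
                f"reference level '{self.reference}' absent from column '{self.col}'"
            )
        self.levels_ = [l for l in levels if l != self.reference]
        return self.build(data, _train=True)

    def build(self, data, _train=False):
        vals = np.asarray(data[self.col].astype(str))
        unseen = set(vals) - set(self.levels_) - {self.reference}
        if unseen:
            raise ValueError(f"unseen category level(s) in '{self.col}': {sorted(unseen)}")
        return np.column_stack([(vals == l).astype(float) for l in self.levels_])

    def labels(self):
        return [f"{self.col}[{l}]" for l in self.levels_]


class Smooth1D(Term):
    """Centered cubic P-spline smooth of one covariate.

    With ``by``/``by_level`` the smooth applies only to rows of one level of a
    categorical covariate (factor-by smooth / varying-coefficient term): the
    basis rows are zeroed elsewhere and the sum-to-zero constraint is taken
    over the level's rows, so the term is identifiable alongside the level's
    parametric dummy.
    """

    def __init__(self, col, k=10, by=None, by_level=None, name=None, component="distance",
                 cap_quantile=0.995):
        self.col = col
        self.k = k
        self.by = by
        self.by_level = by_level
        self.cap_quantile = cap_quantile
        if name is None:
            name = f"f({col})" if by is None else f"f({col}):{by_level}"
        self.name = name
        self.component = component
        self.basis_: BSplineBasis | None = None
        self.Z_: np.ndarray | None = None
        self.penalties: list = []

    @property
    def n_cols(self) -> int:
        return self.k - 1

    def _mask(self, data):
        if self.by is None:
            return np.ones(len(data), bool)
        return np.asarray(data[self.by].astype(str)) == self.by_level

    def build_train(self, data):
        x = np.asarray(data[self.col], float)
        mask = self._mask(data)
        if mask.sum() < self.k:
            raise ValueError(
                f"smooth '{self.name}': only {int(mask.sum())} rows for basis dimension {self.k}"
            )
        self.basis_ = BSplineBasis.from_data(x[mask], self.k, self.cap_quantile)
        B = self.basis_.design(x)
        B[~mask] = 0.0
        self.Z_ = center_transform(B.sum(axis=0))
        self.penalties = [self.Z_.T @ self.basis_.penalty() @ self.Z_]
        return B @ self.Z_

    def build(self, data):
        B = self.basis_.design(np.asarray(data[self.col], float))
        B[~self._mask(data)] = 0.0
        return B @ self.Z_


class SmoothTensor2D(Term):
    """Centered tensor-product cubic P-spline surface of two covariates.

    Carries two penalties (roughness along each margin), each with its own
    smoothing parameter; the joint penalty null space after centering spans
    the bilinear surface x, y, x*y.
    """

    def __init__(self, xcol, ycol, k_marginal=6, name=None, component="spatial"):
        if k_marginal < 4:
            raise ValueError("marginal basis dimension must be >= 4")
        self.xcol = xcol
        self.ycol = ycol
        self.k_marginal = k_marginal
        self.name = name or f"f({xcol},{ycol})"
        self.component = component
        self.bx_: BSplineBasis | None = None
        self.by_: BSplineBasis | None = None
        self.Z_: np.ndarray | None = None
        self.penalties: list = []

    @property
    def n_cols(self) -> int:
        return self.k_marginal**2 - 1

    def build_train(self, data):
        x = np.asarray(data[self.xcol], float)
        y = np.asarray(data[self.ycol], float)
        self.bx_ = BSplineBasis.from_data(x, self.k_marginal, cap_quantile=1.0)
        self.by_ = BSplineBasis.from_data(y, self.k_marginal, cap_quantile=1.0)
        T = tensor_design(self.bx_.design(x), self.by_.design(y))
        self.Z_ = center_transform(T.sum(axis=0))
        Sx, Sy = tensor_penalties(self.k_marginal, self.k_marginal)
        self.penalties = [self.Z_.T @ Sx @ self.Z_, self.Z_.T @ Sy @ self.Z_]
        return T @ self.Z_

    def build(self, data):
        T = tensor_design(
            self.bx_.design(np.asarray(data[self.xcol], float)),
            self.by_.design(np.asarray(data[self.ycol], float)),
        )
        return T @ self.Z_


# ---------------------------------------------------------------------------
# Model


@dataclass
class _PenaltyBlock:
    term_index: int
    sl: slice
    S: np.ndarray  # within-block penalty


class LogisticGAM:
    """Binomial additive model with logit link.

    Parameters
    ----------
    y : array of 0/1
    data : DataFrame with every covariate the terms reference
    terms : list of Term (an Intercept is prepended if absent)
    """

    def __init__(self, y, data: pd.DataFrame, terms: list[Term]):
        y = np.asarray(y, float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if not any(isinstance(t, Intercept) for t in terms):
            terms = [Intercept()] + list(terms)
        self.y = y
        self.data = data.reset_index(drop=True)
        self.terms = terms
        blocks, slices = [], []
        start = 0
        self.penalty_blocks: list[_PenaltyBlock] = []
        for ti, t in enumerate(terms):
            Xt = t.build_train(self.data)
            blocks.append(Xt)
            sl = slice(start, start + Xt.shape[1])
            slices.append(sl)
            for S in t.penalties:
                self.penalty_blocks.append(_PenaltyBlock(ti, sl, S))
            start += Xt.shape[1]
        self.X = np.hstack(blocks)
        self.term_slices = slices
        self.n_obs, self.n_params = self.X.shape

    # -- fitting -----------------------------------------------------------

    def _S_total(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.n_params, self.n_params))
        for lb, pb in zip(lam, self.penalty_blocks):
            S[pb.sl, pb.sl] += lb * pb.S
        return S

    def _pirls(self, lam, start=None, maxiter=100, tol=1e-8):
        X, y = self.X, self.y
        S = self._S_total(lam)
        if start is None:
            beta = np.zeros(self.n_params)
            pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
            beta[0] = np.log(pbar / (1 - pbar))  # intercept column is first
        else:
            beta = start.copy()

        def pen_dev(b, eta=None):
            if eta is None:
                eta = X @ b
            return _deviance(y, _invlogit(eta)) + float(b @ S @ b), eta

        pdev, eta = pen_dev(beta)
        converged = False
        it = 0
        A = XtWX = None
        for it in range(1, maxiter + 1):
            mu = _invlogit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            A = XtWX + S
            try:
                cf = linalg.cho_factor(A)
            except linalg.LinAlgError:
                A = A + 1e-8 * np.mean(np.diag(A)) * np.eye(self.n_params)
                cf = linalg.cho_factor(A)
            beta_new = linalg.cho_solve(cf, Xw.T @ z)
            # step-halving: never accept a step that increases the penalized deviance
            step = beta_new - beta
            frac = 1.0
            for _ in range(30):
                cand = beta + frac * step
                pdev_new, eta_new = pen_dev(cand)
                if pdev_new <= pdev + 1e-12:
                    break
                frac /= 2.0
            else:
                converged = True  # no admissible step improves the objective
                break
            beta, eta = cand, eta_new
            if abs(pdev - pdev_new) < tol * (abs(pdev_new) + 0.1):
                pdev = pdev_new
                converged = True
                break
            pdev = pdev_new
        if not converged:
            logger.warning("PIRLS did not converge in %d iterations", maxiter)
        # final curvature at the accepted coefficients
        mu = _invlogit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + S
        try:
            cf = linalg.cho_factor(A)
        except linalg.LinAlgError:
            A = A + 1e-8 * np.mean(np.diag(A)) * np.eye(self.n_params)
            cf = linalg.cho_factor(A)
        Vb = linalg.cho_solve(cf, np.eye(self.n_params))
        edf_diag = np.diag(linalg.cho_solve(cf, XtWX)).copy()
        return {
            "beta": beta,
            "Vb": Vb,
            "edf_diag": edf_diag,
            "deviance": _deviance(y, mu),
            "mu": mu,
            "eta": eta,
            "converged": converged,
            "n_iter": it,
        }

    def fit(
        self,
        lam=None,
        select: str | None = None,
        lam_bounds=(-6.0, 6.0),
        sweeps: int = 2,
        search_tol: float = 0.1,
        maxiter: int = 100,
        tol: float = 1e-8,
        start=None,
    ) -> "GAMResults":
        """Fit the model.

        ``lam`` fixes the smoothing parameters (scalar or one per penalty);
        ``select='gcv'`` (the default whenever penalties exist and ``lam`` is
        not given) minimizes the GCV score ``n*D / (n - EDF)^2`` over
        ``log10 λ`` per penalty by coordinate-wise golden-section search on
        ``lam_bounds``, ``sweeps`` passes.
        """
        npen = len(self.penalty_blocks)
        if npen == 0:
            res = self._pirls(np.array([]), start=start, maxiter=maxiter, tol=tol)
            return GAMResults(self, np.array([]), res, gcv_trace=None)
        if lam is not None:
            lam = np.broadcast_to(np.asarray(lam, float), (npen,)).copy()
            res = self._pirls(lam, start=start, maxiter=maxiter, tol=tol)
            return GAMResults(self, lam, res, gcv_trace=None)
        if select is None:
            select = "gcv"
        if select != "gcv":
            raise ValueError(f"unknown smoothing selection method: {select}")
        return self._select_gcv(lam_bounds, sweeps, search_tol, maxiter, tol)

    def _select_gcv(self, bounds, sweeps, search_tol, maxiter, tol):
        npen = len(self.penalty_blocks)
        loglam = np.zeros(npen)
        warm = {"beta": None}
        trace: list[tuple[list[float], float]] = []

        def score(ll):
            res = self._pirls(10.0**ll, start=warm["beta"], maxiter=maxiter, tol=tol)
            warm["beta"] = res["beta"]
            n, edf = self.n_obs, float(res["edf_diag"].sum())
            g = n * res["deviance"] / (n - edf) ** 2
            trace.append((list(ll), g))
            return g, res

        best_g, best_res = score(loglam)
        best_ll = loglam.copy()
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(sweeps):
            for b in range(npen):
                a, c = bounds
                ll = best_ll.copy()

                def f(v):
                    ll[b] = v
                    g, res = score(ll)
                    return g, res

                x1 = c - phi * (c - a)
                x2 = a + phi * (c - a)
                f1, r1 = f(x1)
                f2, r2 = f(x2)
                seen = [f1, f2]
                while c - a > search_tol:
                    if f1 < f2:
                        c, x2, f2, r2 = x2, x1, f1, r1
                        x1 = c - phi * (c - a)
                        f1, r1 = f(x1)
                        seen.append(f1)
                    else:
                        a, x1, f1, r1 = x1, x2, f2, r2
                        x2 = a + phi * (c - a)
                        f2, r2 = f(x2)
                        seen.append(f2)
                if max(seen) - min(seen) <= 1e-10 * (abs(min(seen)) + 1.0):
                    # flat objective along this coordinate: prefer the
                    # smallest lambda in the search box (least smoothing)
                    logger.info(
                        "GCV flat in penalty %d; using smallest lambda in range", b
                    )
                    best_ll[b] = bounds[0]
                    continue
                v, g, res = (x1, f1, r1) if f1 < f2 else (x2, f2, r2)
                if g <= best_g:
                    best_g, best_res = g, res
                    best_ll[b] = v
        lam = 10.0**best_ll
        # refit at the selected lambdas from a cold start for reproducibility
        res = self._pirls(lam, maxiter=maxiter, tol=tol)
        return GAMResults(self, lam, res, gcv_trace=trace)


# ---------------------------------------------------------------------------
# Results


class GAMResults:
    """Fit results: estimates, uncertainty, diagnostics, prediction."""

    def __init__(self, model: LogisticGAM, lam, res: dict, gcv_trace=None):
        self.model = model
        self.lam = lam
        self.params = res["beta"]
        self.cov_params = res["Vb"]
        self.edf_diag = res["edf_diag"]
        self.deviance = res["deviance"]
        self.fittedvalues = res["mu"]
        self.linear_predictor = res["eta"]
        self.converged = res["converged"]
        self.n_iter = res["n_iter"]
        self.gcv_trace = gcv_trace

    # -- diagnostics -------------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.n_obs

    @property
    def edf_by_term(self) -> dict[str, float]:
        return {
            t.name: float(self.edf_diag[sl].sum())
            for t, sl in zip(self.model.terms, self.model.term_slices)
        }

    @property
    def edf_total(self) -> float:
        return float(self.edf_diag.sum())

    @property
    def aic(self) -> float:
        # Bernoulli saturated log-likelihood is 0, so AIC = deviance + 2*EDF
        return self.deviance + 2.0 * self.edf_total

    @property
    def gcv(self) -> float:
        n = self.nobs
        return n * self.deviance / (n - self.edf_total) ** 2

    @property
    def resid_deviance(self) -> np.ndarray:
        y, mu = self.model.y, np.clip(self.fittedvalues, 1e-12, 1 - 1e-12)
        d = -2.0 * (y * np.log(mu) + (1 - y) * np.log(1 - mu))
        return np.sign(y - mu) * np.sqrt(np.clip(d, 0, None))

    # -- inference ---------------------------------------------------------

    def or_table(self) -> pd.DataFrame:
        """Parametric part: odds ratios with delta-method SEs, z and p.

        OR = exp(β); the reported SE is on the OR scale, OR·SE(β), so
        z = β/SE(β) = log(OR)/(SE/OR).
        """
        rows = []
        for t, sl in zip(self.model.terms, self.model.term_slices):
            if t.is_smooth:
                continue
            labels = t.labels()
            for k, lab in zip(range(sl.start, sl.stop), labels):
                b = self.params[k]
                se = float(np.sqrt(self.cov_params[k, k]))
                z = b / se if se > 0 else np.nan
                rows.append(
                    {
                        "param": lab,
                        "odds_ratio": float(np.exp(b)),
                        "se_or": float(np.exp(b)) * se,
                        "z": z,
                        "p": 2 * stats.norm.sf(abs(z)),
                        "beta": b,
                        "se_beta": se,
                    }
                )
        return pd.DataFrame(rows)

    def smooth_tests(self) -> pd.DataFrame:
        """Nonparametric part: per-smooth EDF with truncated-rank Wald χ².

        χ² = βₜᵀ Vₜ⁻ βₜ with the covariance block's pseudo-inverse truncated
        at rank round(EDF); the reference distribution is χ² with that rank's
        degrees of freedom. Terms with EDF < 0.5 are skipped (NaN statistics).
        """
        rows = []
        for t, sl in zip(self.model.terms, self.model.term_slices):
            if not t.is_smooth:
                continue
            edf = float(self.edf_diag[sl].sum())
            if edf < 0.5:
                logger.info("smooth '%s' has EDF %.3f < 0.5; test skipped", t.name, edf)
                rows.append({"term": t.name, "edf": edf, "chi2": np.nan, "df": np.nan,
                             "p": np.nan})
                continue
            beta_t = self.params[sl]
            V = self.cov_params[sl, sl]
            r = max(1, int(round(edf)))
            w, U = np.linalg.eigh(V)
            idx = np.argsort(w)[::-1][:r]
            w_r, U_r = w[idx], U[:, idx]
            w_r = np.clip(w_r, 1e-12, None)
            chi2 = float(beta_t @ U_r @ np.diag(1.0 / w_r) @ U_r.T @ beta_t)
            rows.append(
                {"term": t.name, "edf": edf, "chi2": chi2, "df": r,
                 "p": float(stats.chi2.sf(chi2, r))}
            )
        return pd.DataFrame(rows)

    # -- prediction --------------------------------------------------------

    def predict(self, data: pd.DataFrame | None = None, component: str = "all",
                kind: str = "response"):
        """Predict at new covariate rows.

        ``component='all'`` gives the full linear predictor (``kind='link'``)
        or probability (``kind='response'``). Any component label used by the
        model's terms (``intercept``, ``landuse``, ``distance``, ``spatial``)
        gives that group's linear-predictor contribution; components sum
        exactly to the full linear predictor.
        """
        data = self.model.data if data is None else data.reset_index(drop=True)
        lp = np.zeros(len(data))
        labels = {t.component for t in self.model.terms}
        if component != "all" and component not in labels:
            raise ValueError(f"unknown component '{component}'; have {sorted(labels)}")
        for t, sl in zip(self.model.terms, self.model.term_slices):
            if component != "all" and t.component != component:
                continue
            lp += t.build(data) @ self.params[sl]
        if component != "all" or kind == "link":
            return lp if component != "all" else lp
        return _invlogit(lp)

    def predict_components(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Linear predictor split by component, plus total and probability."""
        data = self.model.data if data is None else data.reset_index(drop=True)
        comps = sorted({t.component for t in self.model.terms})
        out = {c: self.predict(data, component=c) for c in comps}
        total = np.sum(list(out.values()), axis=0)
        out["lp_total"] = total
        out["p"] = _invlogit(total)
        return pd.DataFrame(out)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = []
        lines.append("Penalized logistic additive model")
        lines.append(f"  n = {self.nobs}, deviance = {self.deviance:.3f}, "
                     f"AIC = {self.aic:.3f}, total EDF = {self.edf_total:.3f}")
        lines.append(f"  converged: {self.converged} in {self.n_iter} iterations")
        if len(self.lam):
            lines.append("  lambda: " + ", ".join(f"{l:.4g}" for l in self.lam))
        ortab = self.or_table()
        if len(ortab):
            lines.append("")
            lines.append("Parametric part")
            lines.append(f"  {'param':<28}{'OR':>8}{'SE(OR)':>9}{'z':>8}{'p':>8}")
            for r in ortab.itertuples():
                lines.append(
                    f"  {r.param:<28}{r.odds_ratio:>8.3f}{r.se_or:>9.3f}"
                    f"{r.z:>8.3f}{r.p:>8.3f}"
                )
        st = self.smooth_tests()
        if len(st):
            lines.append("")
            lines.append("Smooth terms (nonparametric part)")
            lines.append(f"  {'term':<28}{'edf':>8}{'chi2':>10}{'p':>8}")
            for r in st.itertuples():
                lines.append(f"  {r.term:<28}{r.edf:>8.3f}{r.chi2:>10.3f}{r.p:>8.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "n": self.nobs,
            "deviance": self.deviance,
            "aic": self.aic,
            "edf_total": self.edf_total,
            "edf_by_term": self.edf_by_term,
            "lambda": list(map(float, self.lam)),
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "or_table": self.or_table().to_dict(orient="records"),
            "smooth_tests": self.smooth_tests().replace({np.nan: None}).to_dict(
                orient="records"
            ),
        }


def anova_compare(fit_small: GAMResults, fit_big: GAMResults) -> dict:
    """Nested-model comparison by deviance.

    Returns Δdf = ΔEDF and both test variants: χ² = ΔD on Δdf degrees of
    freedom, and F = (ΔD/Δdf)/φ with the binomial scale φ = 1 (F reference
    with (Δdf, n − EDF_big) degrees of freedom).
    """
    if fit_small.nobs != fit_big.nobs:
        raise ValueError("fits must share identical rows")
    ddf = fit_big.edf_total - fit_small.edf_total
    if ddf <= 0:
        raise ValueError(
            f"models not a nested improvement: EDF difference {ddf:.3f} <= 0"
        )
    ddev = fit_small.deviance - fit_big.deviance
    chi2_stat = ddev
    F = (ddev / ddf) / 1.0
    df2 = fit_big.nobs - fit_big.edf_total
    return {
        "ddf": float(ddf),
        "ddeviance": float(ddev),
        "chi2": float(chi2_stat),
        "p_chi2": float(stats.chi2.sf(max(chi2_stat, 0.0), ddf)),
        "F": float(F),
        "p_F": float(stats.f.sf(max(F, 0.0), ddf, df2)),
    }
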