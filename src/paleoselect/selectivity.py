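"""Selectivity regressions: group-level OLS and genus-level logistic fits.

Two regression designs mirror the two selectivity questions:

* **Group-level OLS** of an outcome (extinction proportion or size
  reduction) on O2-carrying capacity, one point per clade or protein
  group, unweighted by default (weighted least squares available with
  group sizes as weights).

* **Genus-level multiple logistic regression** of binary extinction status
  on physiological and ecological covariates: O2-carrying capacity
  (continuous-ordinal, or 4-level categorical with diffusion as the
  reference), log10 geographic range, motility, physiological buffering, a
  carbonate-shell flag, and log10 occurrence count. Continuous covariates
  are z-scored so coefficients are comparable; genera with undefined
  boundary status are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data_model import DataError, GenusSummary

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ("o2_capacity", "geo_range", "n_occurrences")
BINARY_COVARIATES = ("motility", "buffered", "carbonate")
ALL_COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES

#: Dummy levels for categorical capacity; diffusion is the reference.
CAPACITY_LEVELS = ("hemerythrin", "hemocyanin", "hemoglobin")


@dataclass(frozen=True)
class OlsFit:
    """Simple/weighted linear regression summary."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    slope_se: float
    residuals: tuple[float, ...]
    label: str = ""


@dataclass(frozen=True)
class LogisticFit:
    """Multiple logistic regression summary (Wald inference)."""

    names: tuple[str, ...]
    params: tuple[float, ...] | None
    bse: tuple[float, ...] | None
    zvalues: tuple[float, ...] | None
    pvalues: tuple[float, ...] | None
    llf: float | None
    n: int
    converged: bool
    reference_levels: dict = field(default_factory=dict)
    label: str = ""

    def coef(self, name: str) -> float:
        if self.params is None:
            raise DataError("fit did not converge; coefficients withheld")
        return self.params[self.names.index(name)]

    def p(self, name: str) -> float:
        if self.pvalues is None:
            raise DataError("fit did not converge; p-values withheld")
        return self.pvalues[self.names.index(name)]


def ols_fit(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    label: str = "",
) -> OlsFit:
    """Least-squares line y ~ x with a two-sided t test on the slope (n-2 df)."""
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    if x_a.size != y_a.size:
        raise DataError("x and y must have equal length")
    if x_a.size < 3:
        raise DataError("OLS needs at least 3 points")
    if np.ptp(x_a) == 0:
        raise DataError("x is constant; slope undefined")
    X = sm.add_constant(x_a)
    if weights is None:
        res = sm.OLS(y_a, X).fit()
    else:
        res = sm.WLS(y_a, X, weights=np.asarray(weights, dtype=float)).fit()
    return OlsFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        n=int(x_a.size),
        slope_se=float(res.bse[1]),
        residuals=tuple(float(v) for v in res.resid),
        label=label,
    )


def _zscore(col: np.ndarray, name: str) -> np.ndarray:
    sd = col.std(ddof=0)
    if sd == 0:
        raise DataError(f"covariate {name} is constant after transform")
    return (col - col.mean()) / sd


def encode_design(
    summaries: Sequence[GenusSummary],
    covariates: Sequence[str] = ALL_COVARIATES,
    capacity_mode: str = "continuous",
    clade_effects: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the logistic design matrix and the 0/1 extinction outcome.

    Continuous covariates: ``o2_capacity`` (raw trait value), ``geo_range``
    (log10) and ``n_occurrences`` (log10(n+1)) are z-scored. Binary
    covariates (motile, buffered, carbonate shell) are coded 0/1. With
    ``capacity_mode="categorical"`` the capacity enters as three dummies
    against the diffusion reference. Covariates with a single observed
    level are dropped with a warning. Genera with undefined boundary
    status are excluded.
    """
    if capacity_mode not in ("continuous", "categorical"):
        raise DataError(f"capacity_mode must be continuous/categorical, got {capacity_mode!r}")
    unknown = set(covariates) - set(ALL_COVARIATES)
    if unknown:
        raise DataError(f"unknown covariates: {sorted(unknown)}")
    rows = [s for s in summaries if s.extinct_at_boundary is not None]
    if not rows:
        raise DataError("no genera with defined boundary status")
    for s in rows:
        if s.traits is None:
            raise DataError(f"genus {s.genus} has no trait annotation")
        if "geo_range" in covariates and s.geo_range is None:
            raise DataError(f"genus {s.genus} has no geographic range")

    y = pd.Series([int(s.extinct_at_boundary) for s in rows], name="extinct")
    cols: dict[str, np.ndarray] = {}
    reference: dict[str, str] = {}

    if "o2_capacity" in covariates:
        if capacity_mode == "continuous":
            cols["o2_capacity"] = np.array([s.traits.o2_capacity for s in rows])
        else:
            groups = [s.traits.protein_group for s in rows]
            reference["protein_group"] = "diffusion"
            for level in CAPACITY_LEVELS:
                cols[f"occ_{level}"] = np.array([1.0 if g == level else 0.0 for g in groups])
    if "geo_range" in covariates:
        cols["log10_geo_range"] = np.log10([s.geo_range for s in rows])
    if "n_occurrences" in covariates:
        cols["log10_occurrences"] = np.log10([s.n_occurrences + 1 for s in rows])
    if "motility" in covariates:
        cols["motile"] = np.array([1.0 if s.traits.is_motile else 0.0 for s in rows])
    if "buffered" in covariates:
        cols["buffered"] = np.array([1.0 if s.traits.is_buffered else 0.0 for s in rows])
    if "carbonate" in covariates:
        cols["carbonate"] = np.array([1.0 if s.traits.is_carbonate else 0.0 for s in rows])
    if clade_effects:
        clades = sorted({s.clade for s in rows})
        reference["clade"] = clades[0]
        for clade in clades[1:]:
            cols[f"clade_{clade}"] = np.array([1.0 if s.clade == clade else 0.0 for s in rows])

    zscored = {"o2_capacity", "log10_geo_range", "log10_occurrences"}
    X = pd.DataFrame(index=range(len(rows)))
    X["const"] = 1.0
    for name, col in cols.items():
        if np.ptp(col) == 0:
            logger.warning("covariate %s has a single level; dropped", name)
            continue
        candidate = _zscore(col, name) if name in zscored else np.asarray(col, float)
        # drop columns that are exact linear combinations of earlier ones
        # (clade-level covariates can coincide on a given clade set)
        trial = np.column_stack([X.to_numpy(), candidate])
        if np.linalg.matrix_rank(trial) <= np.linalg.matrix_rank(X.to_numpy()):
            logger.warning("covariate %s is collinear with earlier columns; dropped", name)
            continue
        X[name] = candidate
    X.attrs["reference_levels"] = reference
    return X, y


def logistic_fit(
    X: pd.DataFrame,
    y: pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
    label: str = "",
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton iterations).

    Standard errors come from the inverse observed information; Wald z and
    two-sided p are reported per coefficient. On non-convergence or
    (quasi-)separation the fit is returned flagged ``converged=False``
    with estimates withheld — never silently.
    """
    y_a = np.asarray(y, dtype=float)
    if not (0 < y_a.sum() < y_a.size):
        raise DataError("outcome needs at least one event and one non-event")
    names = tuple(X.columns)
    reference = dict(X.attrs.get("reference_levels", {}))
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and flagged below; silence the duplicate
            warnings.simplefilter("ignore")
            res = sm.Logit(y_a, np.asarray(X, dtype=float)).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=False, warn_convergence=False
            )
        converged = bool(res.mle_retvals.get("converged", False))
        bse = np.asarray(res.bse)
        if not np.all(np.isfinite(bse)) or np.max(np.abs(res.params)) > 50:
            converged = False  # quasi-separation: runaway coefficients
    except (np.linalg.LinAlgError, PerfectSeparationError, ValueError):
        converged = False
        res = None
    if not converged:
        logger.error("logistic fit %r failed to converge (possible separation)", label)
        return LogisticFit(
            names=names, params=None, bse=None, zvalues=None, pvalues=None,
            llf=None, n=int(y_a.size), converged=False,
            reference_levels=reference, label=label,
        )
    return LogisticFit(
        names=names,
        params=tuple(float(v) for v in res.params),
        bse=tuple(float(v) for v in res.bse),
        zvalues=tuple(float(v) for v in res.tvalues),
        pvalues=tuple(float(v) for v in res.pvalues),
        llf=float(res.llf),
        n=int(y_a.size),
        converged=True,
        reference_levels=reference,
        label=label,
    )


def significance_stars(p: float) -> str:
    """Significance convention: *** p<0.001, ** p<0.01, otherwise NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "NS"


def selectivity_report(fits: Sequence[OlsFit | LogisticFit]) -> pd.DataFrame:
    """Tidy coefficient table over a mix of OLS and logistic fits.

    One row per coefficient with its estimate, SE/z/p where available, and
    the significance star code. No multiple-testing correction is applied
    across coefficients (per-coefficient Wald p-values are reported as-is).
    """
    rows = []
    for f in fits:
        if isinstance(f, OlsFit):
            rows.append(
                {
                    "model": f.label or "ols",
                    "term": "slope",
                    "estimate": f.slope,
                    "se": f.slope_se,
                    "z": None,
                    "p": f.p_slope,
                    "stars": significance_stars(f.p_slope),
                    "r_squared": f.r_squared,
                    "n": f.n,
                    "converged": True,
                }
            )
        else:
            if not f.converged:
                rows.append(
                    {
                        "model": f.label or "logistic",
                        "term": "(not converged)",
                        "estimate": None, "se": None, "z": None, "p": None,
                        "stars": "", "r_squared": None, "n": f.n, "converged": False,
                    }
                )
                continue
            for name, b, se, z, p in zip(f.names, f.params, f.bse, f.zvalues, f.pvalues):
                rows.append(
                    {
                        "model": f.label or "logistic",
                        "term": name,
                        "estimate": b,
                        "se": se,
                        "z": z,
                        "p": p,
                        "stars": significance_stars(p),
                        "r_squared": None,
                        "n": f.n,
                        "converged": True,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["model", "term", "estimate", "se", "z", "p", "stars",
                 "r_squared", "n", "converged"],
    )
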