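"""Clonogenic survival-curve models and RBE at an isosurvival level.

The surviving fraction after a dose ``D`` (Gy) is described by the
linear-quadratic (LQ) model ``SF(D) = exp(-alpha*D - beta*D**2)`` or, for the
ion beams where the quadratic term is not statistically supported over the
clinical dose range, by the purely linear (L) model with ``beta = 0``.

Because ``ln SF`` is linear in ``(alpha, beta)``, fitting is a (weighted)
linear least-squares problem with the non-negativity constraints
``alpha >= 0`` and ``beta >= 0``.  The relative biological effectiveness at a
survival level ``S`` is the ratio of the reference (photon) dose to the test
dose producing that same level; its uncertainty is propagated to first order
from the full parameter covariance of both fits.

Usage follows the model/results convention::

    data = SurvivalData.from_dataframe(df, quality=BeamQuality("photon"))
    res = SurvivalCurveModel(data, model="lq").fit()
    print(res.summary())
    rbe = rbe_at_survival(res, res_ion, level=0.30)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from radioqc.beams import BeamQuality

__all__ = [
    "SurvivalData",
    "SurvivalCurveModel",
    "SurvivalCurveResults",
    "ModelSelection",
    "RBEResult",
    "fit_lq",
    "fit_linear",
    "select_model",
    "dose_at_survival",
    "rbe_at_survival",
]


class SurvivalData:
    """Dose / surviving-fraction observations for one radiation quality.

    Parameters
    ----------
    dose:
        Doses in Gy, one entry per observation (replicates appear as repeated
        doses).
    surviving_fraction:
        Surviving fractions, normalised to the unirradiated control.
    replicate:
        Optional replicate identifiers (defaults to 0..n-1).
    sem:
        Optional per-observation standard errors of ``surviving_fraction``
        (used as inverse-variance weights on the log scale when present).
    quality:
        Optional :class:`~radioqc.beams.BeamQuality` tag.
    """

    def __init__(
        self,
        dose: Sequence[float],
        surviving_fraction: Sequence[float],
        replicate: Sequence[int] | None = None,
        sem: Sequence[float] | None = None,
        quality: BeamQuality | None = None,
    ):
        dose = np.asarray(dose, dtype=float)
        sf = np.asarray(surviving_fraction, dtype=float)
        if dose.shape != sf.shape or dose.ndim != 1:
            raise ValueError("dose and surviving_fraction must be 1-d arrays of equal length")
        if dose.size == 0:
            raise ValueError("empty survival dataset")
        if not np.all(np.isfinite(dose)) or not np.all(np.isfinite(sf)):
            raise ValueError("doses and surviving fractions must be finite")
        if np.any(dose < 0):
            raise ValueError("doses must be >= 0")
        if np.any(sf <= 0):
            raise ValueError(
                "surviving fractions must be > 0; replace zero-colony wells "
                "before constructing SurvivalData (see generate_survival_table)"
            )
        if np.any(sf > 1.5):
            warnings.warn("surviving fractions > 1.5 present; check normalisation", stacklevel=2)
        self.dose = dose
        self.sf = sf
        self.replicate = (
            np.arange(dose.size) if replicate is None else np.asarray(replicate)
        )
        self.sem = None if sem is None else np.asarray(sem, dtype=float)
        if self.sem is not None and (self.sem.shape != dose.shape or np.any(self.sem < 0)):
            raise ValueError("sem must match dose shape and be >= 0")
        self.quality = quality

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, quality: BeamQuality | None = None) -> "SurvivalData":
        """Build from a table with columns ``dose_Gy``, ``surviving_fraction``
        and optionally ``replicate`` and ``sem``."""
        rep = df["replicate"].to_numpy() if "replicate" in df else None
        sem = df["sem"].to_numpy() if "sem" in df else None
        return cls(df["dose_Gy"].to_numpy(), df["surviving_fraction"].to_numpy(), rep, sem, quality)

    @classmethod
    def from_csv(cls, path, quality: BeamQuality | None = None) -> "SurvivalData":
        return cls.from_dataframe(pd.read_csv(path), quality)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"dose_Gy": self.dose, "replicate": self.replicate, "surviving_fraction": self.sf}
        )
        if self.sem is not None:
            out["sem"] = self.sem
        return out

    @property
    def n_distinct_nonzero_doses(self) -> int:
        return int(np.unique(self.dose[self.dose > 0]).size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = self.quality.species if self.quality else "untagged"
        return f"<SurvivalData {tag}: {self.dose.size} points, {self.n_distinct_nonzero_doses} doses>"


class SurvivalCurveModel:
    """Weighted least-squares fit of ``ln SF`` against ``-alpha*D - beta*D**2``.

    Parameters
    ----------
    data : SurvivalData
    model : {"lq", "linear"}
        ``"lq"`` fits alpha and beta (both constrained >= 0); ``"linear"``
        fixes beta to zero.
    intercept : {"auto", True, False}
        Whether to include a free normalisation intercept on the log scale.
        Surviving fractions are normalised to the 0 Gy controls, so the
        control counting noise shifts *every* observation of a dataset
        coherently; a free intercept absorbs that shared error and makes the
        parameter standard errors honest.  ``"auto"`` (default) uses an
        intercept exactly when the dataset contains 0 Gy observations (which
        carry the normalisation information); data without a 0 Gy condition
        are taken as exactly normalised.
    """

    def __init__(self, data: SurvivalData, model: str = "lq", intercept="auto"):
        if model not in ("lq", "linear"):
            raise ValueError("model must be 'lq' or 'linear'")
        min_doses = 3 if model == "lq" else 2
        if data.n_distinct_nonzero_doses < min_doses:
            raise ValueError(
                f"{model} fit needs >= {min_doses} distinct nonzero doses, "
                f"got {data.n_distinct_nonzero_doses}"
            )
        if np.allclose(data.sf, data.sf[0]) and not np.allclose(data.sf, 1.0):
            raise ValueError("degenerate dataset: all surviving fractions identical")
        self.data = data
        self.model = model
        if intercept == "auto":
            intercept = bool(np.any(data.dose == 0))
        self.intercept = bool(intercept)

    def fit(self) -> "SurvivalCurveResults":
        d = self.data.dose
        y = -np.log(self.data.sf)  # >= 0 in expectation
        cols = [d, d**2] if self.model == "lq" else [d]
        n_model = len(cols)
        lower = [0.0] * n_model
        upper = [np.inf] * n_model
        if self.intercept:
            cols.append(np.ones_like(d))
            lower.append(-np.inf)
            upper.append(np.inf)
        X = np.column_stack(cols)
        if self.data.sem is not None and np.all(self.data.sem > 0):
            # var(ln SF) ~ (sem/SF)^2 by the delta method
            w = self.data.sf / self.data.sem
        else:
            w = np.ones_like(d)
        Xw = X * w[:, None]
        yw = y * w
        sol = optimize.lsq_linear(Xw, yw, bounds=(np.array(lower), np.array(upper)))
        full_params = sol.x
        resid = yw - Xw @ full_params
        rss = float(resid @ resid)
        nobs, p = X.shape
        df_resid = nobs - p
        scale = rss / df_resid if df_resid > 0 else np.nan
        # Curvature-based covariance from the unconstrained normal equations;
        # a parameter pinned at the boundary is flagged rather than given a
        # one-sided error.
        xtx = Xw.T @ Xw
        try:
            cov_full = scale * np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            cov_full = np.full((p, p), np.nan)
        params = full_params[:n_model]
        cov = cov_full[:n_model, :n_model]
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        at_boundary = params <= 1e-12
        return SurvivalCurveResults(
            model="LQ" if self.model == "lq" else "L",
            params=params,
            bse=bse,
            cov_params=cov,
            nobs=nobs,
            df_resid=df_resid,
            rss=rss,
            scale=scale,
            at_boundary=at_boundary,
            intercept=float(full_params[n_model]) if self.intercept else 0.0,
            data=self.data,
        )


@dataclass
class SurvivalCurveResults:
    """Fitted survival-curve parameters with uncertainties and diagnostics."""

    model: str  # "LQ" or "L"
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    nobs: int
    df_resid: int
    rss: float
    scale: float
    at_boundary: np.ndarray
    intercept: float = 0.0
    data: SurvivalData | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return float(self.params[0])

    @property
    def alpha_se(self) -> float:
        return float(self.bse[0])

    @property
    def beta(self) -> float:
        return float(self.params[1]) if self.model == "LQ" else 0.0

    @property
    def beta_se(self) -> float:
        return float(self.bse[1]) if self.model == "LQ" else 0.0

    def predict(self, dose) -> np.ndarray:
        """Surviving fraction at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        return np.exp(-self.alpha * dose - self.beta * dose**2)

    def dose_at_survival(self, level: float) -> float:
        return dose_at_survival(self, level)

    def summary(self) -> str:
        tag = (
            self.data.quality.species
            if self.data is not None and self.data.quality is not None
            else "?"
        )
        lines = [
            "Survival curve fit",
            "=" * 46,
            f"quality: {tag:>12s}    model: {self.model}",
            f"nobs:    {self.nobs:>12d}    df_resid: {self.df_resid}",
            f"RSS (weighted log scale): {self.rss:.6g}",
            "-" * 46,
            f"alpha  {self.alpha:10.4f}  +/- {self.alpha_se:.4f}  Gy^-1",
        ]
        if self.model == "LQ":
            flag = "  (at boundary)" if self.at_boundary[1] else ""
            lines.append(f"beta   {self.beta:10.4f}  +/- {self.beta_se:.4f}  Gy^-2{flag}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot data points and the fitted curve on a log survival axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.data is not None:
            ax.plot(self.data.dose, self.data.sf, "o", **kwargs)
        dmax = self.data.dose.max() if self.data is not None else 8.0
        dd = np.linspace(0, dmax, 200)
        ax.plot(dd, self.predict(dd), "--")
        ax.set_yscale("log")
        ax.set_xlabel("dose [Gy]")
        ax.set_ylabel("surviving fraction")
        return ax


@dataclass
class ModelSelection:
    """Outcome of the nested LQ-vs-L comparison."""

    chosen: SurvivalCurveResults
    f_statistic: float
    p_value: float
    lq: SurvivalCurveResults | None
    linear: SurvivalCurveResults


def fit_lq(data: SurvivalData) -> SurvivalCurveResults:
    """Fit the linear-quadratic model (alpha, beta >= 0)."""
    return SurvivalCurveModel(data, model="lq").fit()


def fit_linear(data: SurvivalData) -> SurvivalCurveResults:
    """Fit the purely linear model (beta = 0)."""
    return SurvivalCurveModel(data, model="linear").fit()


def select_model(data: SurvivalData, alpha_level: float = 0.05) -> ModelSelection:
    """Choose L unless adding the quadratic term helps, by a nested F-test.

    The linear model is retained unless the LQ fit reduces the residual sum
    of squares significantly (F-test with 1 numerator df at ``alpha_level``).
    With only two distinct nonzero doses the LQ model is unfittable and the
    linear fit is returned with a warning.
    """
    lin = fit_linear(data)
    if data.n_distinct_nonzero_doses < 3:
        warnings.warn("only 2 distinct doses: LQ unfittable, returning linear fit", stacklevel=2)
        return ModelSelection(lin, np.nan, np.nan, None, lin)
    lq = fit_lq(data)
    if lq.df_resid <= 0 or lq.rss <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = max(0.0, (lin.rss - lq.rss) / (lq.rss / lq.df_resid))
        p = float(stats.f.sf(f_stat, 1, lq.df_resid))
    chosen = lq if (p < alpha_level and lq.beta > 0) else lin
    return ModelSelection(chosen, float(f_stat), float(p), lq, lin)


def dose_at_survival(fit: SurvivalCurveResults, level: float) -> float:
    """Dose (Gy) at which the fitted curve reaches the given survival level.

    For the LQ model this is the positive root of
    ``beta*D**2 + alpha*D + ln(level) = 0``; for the linear model
    ``D = -ln(level)/alpha``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("survival level must be in (0, 1)")
    alpha, beta = fit.alpha, fit.beta
    L = -np.log(level)  # > 0
    if beta > 0:
        # conjugate form of the quadratic root: no cancellation as beta -> 0
        return float(2.0 * L / (alpha + np.sqrt(alpha**2 + 4.0 * beta * L)))
    if alpha > 0:
        return float(L / alpha)
    raise ValueError("alpha = beta = 0: the survival curve never reaches the level")


def _dose_gradient(fit: SurvivalCurveResults, level: float) -> np.ndarray:
    """Analytic gradient of dose_at_survival w.r.t. the fitted parameters."""
    L = -np.log(level)
    a, b = fit.alpha, fit.beta
    if fit.model == "L" or b <= 0:
        return np.array([-L / a**2])
    s = np.sqrt(a**2 + 4.0 * b * L)
    dda = (-1.0 + a / s) / (2.0 * b)
    ddb = L / (b * s) - (-a + s) / (2.0 * b**2)
    return np.array([dda, ddb])


def _dose_variance(fit: SurvivalCurveResults, level: float) -> float:
    g = _dose_gradient(fit, level)
    cov = fit.cov_params[: g.size, : g.size]
    if not np.all(np.isfinite(cov)):
        return np.nan
    return float(g @ cov @ g)


@dataclass(frozen=True)
class RBEResult:
    """Relative biological effectiveness at an isosurvival level."""

    survival_level: float
    reference_dose: float
    test_dose: float
    rbe: float
    rbe_se: float

    def __post_init__(self):
        if self.rbe <= 0:
            raise ValueError("RBE must be positive")


def rbe_at_survival(
    reference: SurvivalCurveResults, test: SurvivalCurveResults, level: float = 0.30
) -> RBEResult:
    """RBE = reference dose / test dose at equal surviving fraction.

    The standard error combines both fits' parameter covariances to first
    order (delta method), treating the two fits as independent.
    """
    d_ref = dose_at_survival(reference, level)
    d_test = dose_at_survival(test, level)
    rbe = d_ref / d_test
    var_ref = _dose_variance(reference, level)
    var_test = _dose_variance(test, level)
    if np.isfinite(var_ref) and np.isfinite(var_test):
        se = rbe * np.sqrt(var_ref / d_ref**2 + var_test / d_test**2)
    else:
        se = np.nan
    return RBEResult(level, d_ref, d_test, rbe, float(se))
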