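"""Poisson statistics of primary-ion traversals per cell nucleus.

A nucleus of cross-sectional area ``A`` (um^2) exposed to a fluence ``phi``
(particles/cm^2) receives on average ``lambda = phi * A * 1e-8`` traversals
(1 um^2 = 1e-8 cm^2).  Over a sample of measured nuclear areas the hit count
follows an equal-weight mixture of Poisson laws,

    P(k) = (1/n) * sum_i Poisson(k; phi * A_i * 1e-8),

whose mean is ``phi * E[A] * 1e-8`` and whose variance is
``phi*E[A]*1e-8 + (phi*1e-8)**2 * Var(A)`` (law of total variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "UM2_PER_CM2",
    "expected_hits",
    "HitModel",
    "HitDistribution",
    "HitComparison",
    "compare_hit_histograms",
]

UM2_PER_CM2 = 1e-8  # cm^2 per um^2


def expected_hits(area_um2: float, fluence_per_cm2: float) -> float:
    """Expected traversals of a nucleus: fluence x area, unit-converted once."""
    area = np.asarray(area_um2, dtype=float)
    fluence = float(fluence_per_cm2)
    if np.any(area < 0) or fluence < 0:
        raise ValueError("area and fluence must be >= 0")
    out = fluence * area * UM2_PER_CM2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HitDistribution:
    """Analytic hit-count distribution P(k), k = 0..k_max."""

    k: np.ndarray
    pmf: np.ndarray
    mean: float
    var: float

    def sem(self, n_nuclei: int) -> float:
        """Standard error of the mean hit count for a sample of ``n_nuclei``."""
        if n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        return float(np.sqrt(self.var / n_nuclei))

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.k, self.pmf, width=0.8, **kwargs)
        ax.set_xlabel("particle hits per nucleus")
        ax.set_ylabel("probability")
        return ax


class HitModel:
    """Mixed-Poisson intranuclear hit model over a nuclear-area sample.

    Parameters
    ----------
    areas:
        Nuclear cross-sectional areas in um^2 (the measured or synthetic
        sample; each nucleus is an equally weighted mixture component).
    fluence:
        Particle fluence in particles/cm^2 (primaries plus projectile-like
        heavy fragments that are indistinguishable from the beam).
    """

    def __init__(self, areas, fluence: float):
        areas = np.asarray(areas, dtype=float)
        if areas.ndim != 1 or areas.size == 0:
            raise ValueError("areas must be a non-empty 1-d array")
        if np.any(areas < 0) or not np.all(np.isfinite(areas)):
            raise ValueError("areas must be finite and >= 0")
        if fluence < 0 or not np.isfinite(fluence):
            raise ValueError("fluence must be finite and >= 0")
        self.areas = areas
        self.fluence = float(fluence)
        self.lam = self.fluence * areas * UM2_PER_CM2

    @property
    def mean(self) -> float:
        """Analytic mean hits per nucleus, phi * E[A]."""
        return float(self.lam.mean())

    def auto_k_max(self, tail: float = 1e-9) -> int:
        """Smallest K whose Poisson tail mass under the largest rate < tail."""
        lam_max = float(self.lam.max())
        if lam_max == 0:
            return 0
        k = int(stats.poisson.isf(tail, lam_max))
        while stats.poisson.sf(k, lam_max) >= tail:
            k += 1
        return k

    def distribution(self, k_max: int | None = None) -> HitDistribution:
        """Analytic mixture pmf up to ``k_max`` (auto: mixture tail < 1e-9)."""
        if k_max is None:
            k_max = self.auto_k_max()
        k = np.arange(k_max + 1)
        # n_areas x n_k pmf matrix, averaged over mixture components
        pmf = stats.poisson.pmf(k[None, :], self.lam[:, None]).mean(axis=0)
        mean = self.mean
        var = mean + float(self.lam.var())
        return HitDistribution(k=k, pmf=pmf, mean=mean, var=var)

    def sample(self, seed=None) -> np.ndarray:
        """Draw one Poisson hit count per nucleus; reproducible given seed."""
        rng = np.random.default_rng(seed)
        return rng.poisson(self.lam)


@dataclass(frozen=True)
class HitComparison:
    """Observed-vs-model hit histogram summary (means +/- SEM, chi-square)."""

    observed_mean: float
    observed_sem: float
    model_mean: float
    model_sem: float
    chi2: float
    dof: int
    p_value: float


def compare_hit_histograms(observed, model: HitDistribution) -> HitComparison:
    """Compare an observed hit histogram with the analytic distribution.

    Parameters
    ----------
    observed:
        Histogram of observed hit counts: ``observed[k]`` nuclei with ``k``
        hits.
    model:
        Analytic :class:`HitDistribution` (its SEM is evaluated at the same
        nucleus count as the observation, for like-for-like reporting).

    Returns a chi-square goodness-of-fit over bins pooled so that every
    expected count is >= 5 (the last pooled bin absorbs the model tail).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size == 0 or np.any(obs < 0):
        raise ValueError("observed must be a 1-d non-negative histogram")
    n = obs.sum()
    if n < 1:
        raise ValueError("observed histogram is empty")
    k_obs = np.arange(obs.size)
    observed_mean = float((k_obs * obs).sum() / n)
    observed_var = float((obs * (k_obs - observed_mean) ** 2).sum() / max(n - 1, 1))
    observed_sem = float(np.sqrt(observed_var / n))

    # expected counts on the union support; final cell is the model tail
    k_len = max(obs.size, model.pmf.size)
    pmf = np.zeros(k_len + 1)
    pmf[: model.pmf.size] = model.pmf
    pmf[-1] = max(0.0, 1.0 - model.pmf.sum())
    obs_full = np.zeros(k_len + 1)
    obs_full[: obs.size] = obs
    expected = n * pmf

    # pool consecutive bins until each pooled expected count >= 5
    pooled_obs, pooled_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs_full, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    else:  # degenerate: everything in one bin
        pooled_obs, pooled_exp = [acc_o], [acc_e]
    pooled_obs = np.asarray(pooled_obs)
    pooled_exp = np.asarray(pooled_exp)
    # renormalise pooled expectations to the observed total (guards rounding)
    pooled_exp *= pooled_obs.sum() / pooled_exp.sum()
    chi2 = float(((pooled_obs - pooled_exp) ** 2 / pooled_exp).sum())
    dof = max(len(pooled_obs) - 1, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return HitComparison(
        observed_mean=observed_mean,
        observed_sem=observed_sem,
        model_mean=model.mean,
        model_sem=model.sem(int(n)),
        chi2=chi2,
        dof=dof,
        p_value=p,
    )
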