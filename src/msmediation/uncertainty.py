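"""E-value sensitivity statistics and BCa bootstrap confidence intervals."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import BootstrapError, DataError, MsmediationError


@dataclass
class EValueResult:
    """Minimum confounder association needed to explain away a risk ratio."""

    rr_input: float
    evalue_point: float
    evalue_ci: float | None = None

    def to_dict(self) -> dict:
        return {
            "rr_input": self.rr_input,
            "evalue_point": self.evalue_point,
            "evalue_ci": self.evalue_ci,
        }


def _evalue_scalar(rr: float) -> float:
    rr_star = max(rr, 1.0 / rr)
    return float(rr_star + np.sqrt(rr_star * (rr_star - 1.0)))


def evalue(rr: float, ci_limit: float | None = None) -> EValueResult:
    """E-value for a risk ratio: RR* + sqrt(RR* (RR* - 1)), RR* = max(RR, 1/RR).

    Protective ratios are inverted first.  The CI E-value uses the
    confidence limit nearer the null and is 1 when the interval crosses 1.
    """
    if rr <= 0:
        raise DataError(f"risk ratio must be > 0; got {rr}")
    point = _evalue_scalar(rr)
    ci_ev = None
    if ci_limit is not None:
        if ci_limit <= 0:
            raise DataError(f"CI limit must be > 0; got {ci_limit}")
        crosses = (rr >= 1.0 and ci_limit <= 1.0) or (rr < 1.0 and ci_limit >= 1.0)
        ci_ev = 1.0 if crosses else _evalue_scalar(ci_limit)
    return EValueResult(rr_input=float(rr), evalue_point=point, evalue_ci=ci_ev)


@dataclass
class BootstrapResult:
    point_estimate: float
    replicates: np.ndarray
    ci95_bca: tuple
    bias_correction_z0: float
    acceleration_a: float
    B: int
    n_failed: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "point_estimate": self.point_estimate,
            "ci95_bca": list(self.ci95_bca),
            "bias_correction_z0": self.bias_correction_z0,
            "acceleration_a": self.acceleration_a,
            "B": self.B,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }

    def replicates_to_csv(self, path) -> None:
        """Export the replicate vector for external audit or plotting."""
        pd.DataFrame({"replicate": self.replicates}).to_csv(path, index=False)


def bca_bootstrap(
    data: pd.DataFrame,
    statistic,
    B: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Bias-corrected and accelerated bootstrap over subjects.

    ``statistic`` receives a resampled copy of ``data`` (rows = subjects)
    and must return a scalar; the entire estimation pipeline should live
    inside it so the interval reflects every fitted model.  z0 comes from
    the fraction of replicates below the point estimate (ties counted half)
    and the acceleration from the jackknife skewness.  Replicates whose
    statistic raises a package error are dropped and counted; more than 5%
    failures warns, more than 50% aborts.
    """
    n = len(data)
    if n < 2:
        raise DataError("need at least two subjects to bootstrap")
    theta_hat = float(statistic(data))
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    failed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            reps[b] = float(statistic(sample))
        except MsmediationError:
            reps[b] = np.nan
            failed += 1
    ok = reps[~np.isnan(reps)]
    if len(ok) == 0 or failed > 0.5 * B:
        raise BootstrapError(f"{failed}/{B} bootstrap replicates failed")
    if failed > 0.05 * B:
        warnings.warn(
            f"{failed}/{B} bootstrap replicates failed; interval may be unstable",
            stacklevel=2,
        )

    # bias correction (midpoint convention for ties at the point estimate)
    frac_below = (np.sum(ok < theta_hat) + 0.5 * np.sum(ok == theta_hat)) / len(ok)
    frac_below = min(max(frac_below, 1.0 / (2 * len(ok))), 1.0 - 1.0 / (2 * len(ok)))
    z0 = float(norm.ppf(frac_below))

    # acceleration from the jackknife
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        try:
            jack[i] = float(statistic(data.iloc[keep].reset_index(drop=True)))
        except MsmediationError:
            jack[i] = np.nan
        keep[i] = True
    jack = jack[~np.isnan(jack)]
    if len(jack) < 2:
        a = 0.0
    else:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2) ** 1.5)
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0

    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    ci = []
    for z in (z_lo, z_hi):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        q = float(norm.cdf(adj))
        ci.append(float(np.percentile(ok, 100.0 * q, method="linear")))
    return BootstrapResult(
        point_estimate=theta_hat,
        replicates=ok,
        ci95_bca=(ci[0], ci[1]),
        bias_correction_z0=z0,
        acceleration_a=a,
        B=B,
        n_failed=failed,
        seed=seed,
    )
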