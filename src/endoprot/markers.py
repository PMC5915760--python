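"""Disease-marker calling by the two-group model on transition tests.

The procedure screens for proteins whose expression increases along the
presumed disease progression benign endometrium (END) -> endometriosis
(EMT) -> carcinoma (CC or EC, analyzed separately):

1. For each adjacent transition, a one-sided moderated t test of elevation
   in the later cohort, with the earlier (control) cohort's variance
   replaced by a conservative upper-confidence-bound estimate.
2. The one-sided p-values feed the two-group mixture model: test scores
   ``z = Phi^{-1}(1 - p)`` are viewed as a mixture of a null component
   (proportion ``pi0``, density ``f0``) and an alternative; the local false
   discovery rate is ``lfdr(z) = pi0 * f0(z) / f(z)`` with the marginal
   ``f`` estimated by Gaussian kernel smoothing.  The posterior probability
   of elevation is ``1 - lfdr`` on the right tail.
3. ``pi0`` is estimated by the right-boundary procedure: scanning the
   p-value histogram left to right, the first bin whose height drops to (or
   below) the tail estimator computed over everything to its right marks
   the tuning point ``lambda*``, and ``pi0 = #{p > lambda*} / (m (1 -
   lambda*))``.
4. Proteins are classified by which transition posteriors clear a
   threshold ``tau``: pattern A (both transitions elevated: progressive
   increase END -> EMT -> cancer), B (only END -> EMT), C (only EMT ->
   cancer); the disease-marker set is their union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ModeratedVariancePrior, moderated_t
from .errors import ValidationError
from .io_tables import SampleAnnotation, cohort_samples
from .preprocess import ExpressionMatrix


@dataclass
class TwoGroupFit:
    """Fitted two-group (null + alternative) mixture on z-scores."""

    pi0: float
    z: pd.Series
    grid: np.ndarray
    f_hat: np.ndarray  # marginal density on the grid
    f0_mean: float
    f0_sd: float
    lfdr: pd.Series
    posterior_elevated: pd.Series
    bandwidth: float


@dataclass
class TransitionPosteriors:
    """Posterior-of-elevation vectors for both progression transitions."""

    post_first: pd.Series  # END -> EMT
    post_second: pd.Series  # EMT -> cancer
    fit_first: TwoGroupFit
    fit_second: TwoGroupFit
    table_first: pd.DataFrame
    table_second: pd.DataFrame


def estimate_pi0_right_boundary(
    p: Sequence[float], grid: np.ndarray | None = None, bins: int = 20
) -> float:
    """True-null proportion by the right-boundary histogram rule.

    The tail estimator ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))``
    is evaluated at candidate boundaries (default 0.05, 0.10, ..., 0.95,
    the right edges of a 20-bin histogram).  Scanning bins left to right,
    the first bin whose density is <= the tail estimator to its right is
    selected; the returned value is the tail estimator at that boundary,
    clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size < 50:
        raise ValidationError(
            f"pi0 estimation needs >= 50 p-values, got {p.size}"
        )
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if grid is None:
        grid = np.linspace(0.0, 1.0, bins + 1)[1:-1]
    grid = np.asarray(grid, dtype=float)
    edges = np.concatenate(([0.0], grid))
    m = p.size
    for i, lam in enumerate(grid):
        width = lam - edges[i]
        density = np.sum((p > edges[i]) & (p <= lam)) / (m * width)
        tail = np.sum(p > lam) / (m * (1.0 - lam))
        if density <= tail:
            return float(np.clip(tail, 0.0, 1.0))
    lam = grid[-1]
    return float(np.clip(np.sum(p > lam) / (m * (1.0 - lam)), 0.0, 1.0))


def _silverman_bandwidth(z: np.ndarray) -> float:
    n = z.size
    sd = z.std(ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * n ** (-0.2)


def _kde_eval(z: np.ndarray, points: np.ndarray, h: float,
              chunk: int = 256) -> np.ndarray:
    """Gaussian KDE of sample ``z`` evaluated at ``points`` (chunked)."""
    out = np.empty(points.size)
    for start in range(0, points.size, chunk):
        block = points[start:start + chunk, None]
        out[start:start + chunk] = stats.norm.pdf(
            (block - z[None, :]) / h
        ).mean(axis=1) / h
    return out


def fit_two_group(
    p_one_sided: Sequence[float],
    pi0: float,
    null: str = "theoretical",
    grid_size: int = 512,
) -> TwoGroupFit:
    """Local-fdr fit of the two-group model to one-sided p-values.

    ``null='theoretical'`` uses the standard normal as ``f0``;
    ``null='empirical'`` fits a normal to the central half of the z sample
    (median location, IQR/1.349 scale).
    """
    p = np.asarray(p_one_sided, dtype=float)
    index = (
        p_one_sided.index if isinstance(p_one_sided, pd.Series)
        else pd.RangeIndex(p.size)
    )
    if not 0 <= pi0 <= 1:
        raise ValidationError("pi0 must lie in [0, 1]")
    m = p.size
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "p-values at 0 or 1 clamped to open interval", stacklevel=2
        )
        p = np.clip(p, 1.0 / (m + 1), m / (m + 1.0))
    z = stats.norm.isf(p)
    h = _silverman_bandwidth(z)
    grid = np.linspace(z.min() - 3 * h, z.max() + 3 * h, grid_size)
    f_hat_grid = _kde_eval(z, grid, h)
    f_at_z = _kde_eval(z, z, h)

    if null == "theoretical":
        mu0, sd0 = 0.0, 1.0
    elif null == "empirical":
        lo, hi = np.percentile(z, [25, 75])
        central = z[(z >= lo) & (z <= hi)]
        mu0 = float(np.median(z))
        sd0 = float((hi - lo) / 1.349) or 1.0
        if central.size == 0:
            mu0, sd0 = 0.0, 1.0
    else:
        raise ValidationError("null must be 'theoretical' or 'empirical'")

    f0_at_z = stats.norm.pdf(z, mu0, sd0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfdr = np.clip(pi0 * f0_at_z / f_at_z, 0.0, 1.0)
    lfdr = np.where(f_at_z <= 0, 1.0, lfdr)
    posterior = np.where(z > 0, 1.0 - lfdr, 0.0)
    return TwoGroupFit(
        pi0=float(pi0),
        z=pd.Series(z, index=index, name="z"),
        grid=grid,
        f_hat=f_hat_grid,
        f0_mean=mu0,
        f0_sd=sd0,
        lfdr=pd.Series(lfdr, index=index, name="lfdr"),
        posterior_elevated=pd.Series(posterior, index=index,
                                     name="posterior_elevated"),
        bandwidth=h,
    )


def conservative_control_fit(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    control_group: str,
    gamma: float = 0.25,
) -> pd.DataFrame:
    """Conservative per-protein normal model for a control cohort.

    The mean is the sample mean; the variance is inflated to the upper
    bound of the (1 - gamma) chi-square confidence interval,
    ``(n-1) s^2 / chi2_gamma(n-1)``, guaranteeing it is >= the sample
    variance for ``gamma <= 0.5``.  Constant proteins (s^2 = 0) keep
    variance 0 and are flagged degenerate.
    """
    if not 0 < gamma <= 0.5:
        raise ValidationError("gamma must lie in (0, 0.5]")
    samples = [s for s in cohort_samples(annotations, control_group)
               if s in m.samples]
    n = len(samples)
    if n < 2:
        raise ValidationError(
            f"control group {control_group!r} has {n} samples; need >= 2"
        )
    vals = m.values[samples]
    s2 = vals.var(axis=1, ddof=1)
    factor = (n - 1) / stats.chi2.ppf(gamma, n - 1)
    return pd.DataFrame(
        {
            "mean": vals.mean(axis=1),
            "s2": s2,
            "s2_conservative": s2 * factor,
            "degenerate": s2 == 0,
        }
    )


def transition_posteriors(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    ordered_groups: tuple[str, str, str] = ("END", "EMT", "CC"),
    prior: ModeratedVariancePrior | None = None,
    gamma: float = 0.25,
    null: str = "theoretical",
) -> TransitionPosteriors:
    """Posterior-of-elevation for both adjacent progression transitions.

    For each transition (earlier -> later): one-sided moderated test of
    elevation in the later cohort with the earlier cohort's variance
    replaced by its conservative estimate, then right-boundary pi0 and the
    two-group-model local fdr on the resulting p-values.
    """
    if len(ordered_groups) != 3:
        raise ValidationError("ordered_groups must name exactly 3 cohorts")
    results = []
    for g0, g1 in zip(ordered_groups[:-1], ordered_groups[1:]):
        cons = conservative_control_fit(m, annotations, g0, gamma=gamma)
        table = moderated_t(
            m, annotations, (g1, g0), prior=prior,
            control_variance=cons["s2_conservative"],
        )
        pi0 = estimate_pi0_right_boundary(table["p_one_sided"].to_numpy())
        fit = fit_two_group(table["p_one_sided"], pi0, null=null)
        results.append((fit, table))
    (fit1, table1), (fit2, table2) = results
    return TransitionPosteriors(
        post_first=fit1.posterior_elevated,
        post_second=fit2.posterior_elevated,
        fit_first=fit1,
        fit_second=fit2,
        table_first=table1,
        table_second=table2,
    )


def classify_patterns(
    post1: pd.Series, post2: pd.Series, tau: float = 0.9
) -> pd.DataFrame:
    """Progressive pattern labels from the two transition posteriors.

    A: both transitions elevated (posterior >= tau); B: only the first
    (END -> EMT); C: only the second (EMT -> cancer); none otherwise.
    The disease-marker set is A | B | C.
    """
    if not 0 < tau < 1:
        raise ValidationError("tau must lie in (0, 1)")
    if len(post1) != len(post2):
        raise ValidationError("posterior vectors must have equal length")
    post2 = post2.reindex(post1.index)
    hit1 = post1 >= tau
    hit2 = post2 >= tau
    pattern = np.select(
        [hit1 & hit2, hit1 & ~hit2, ~hit1 & hit2],
        ["A", "B", "C"],
        default="none",
    )
    return pd.DataFrame(
        {
            "post_first": post1,
            "post_second": post2,
            "pattern": pattern,
            "is_marker": pattern != "none",
        },
        index=post1.index,
    )
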