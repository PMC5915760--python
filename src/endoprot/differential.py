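"""Per-protein group comparisons.

Three layers:

* one-way fixed-effects ANOVA across cohorts with Benjamini–Hochberg
  control, used to enrich for the most cohort-variable proteins;
* empirical-Bayes moderated t-statistics: per-protein sample variances are
  shrunk toward a prior variance ``s0_sq`` with prior degrees of freedom
  ``d0``, both estimated from all proteins by the moment equations on log
  sample variances (digamma/trigamma matching); the moderated statistic is
  ``t = dmean / sqrt(s2_post * (1/n1 + 1/n2))`` with
  ``s2_post = (d0*s0_sq + d*s2) / (d0 + d)`` on ``d0 + d`` degrees of
  freedom;
* the S0-modified volcano significance rule
  ``t_s0 = dmean / (se + s0)``, which de-prioritizes small fold changes with
  tiny variance, followed by BH at the configured FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_tables import SampleAnnotation, cohort_samples
from .preprocess import ExpressionMatrix

#: degrees of freedom used in t tail computations when d0 is infinite
_DF_CAP = 1e7


@dataclass
class ModeratedVariancePrior:
    """Prior on per-protein residual variances: scaled inverse chi-square."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior (pooled) variance

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0 (inf allowed)")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be > 0")


@dataclass
class VolcanoParams:
    fdr: float = 0.05
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr must be in (0,1)")
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")


def _group_arrays(
    m: ExpressionMatrix, annotations: Sequence[SampleAnnotation],
    groups: Sequence[str], min_size: int = 2,
) -> dict[str, np.ndarray]:
    if not m.is_complete:
        raise ValidationError("differential tests require a complete matrix")
    out = {}
    for g in groups:
        samples = [s for s in cohort_samples(annotations, g) if s in m.samples]
        if len(samples) < min_size:
            raise ValidationError(
                f"group {g!r} has {len(samples)} samples; need >= {min_size}"
            )
        out[g] = m.values[samples].to_numpy(dtype=float)
    return out


def anova_scan(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    groups: Sequence[str],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """One-way fixed-effects F test per protein across the named cohorts.

    Returns a table with group means, F, raw p, BH-adjusted q and a
    significance flag at ``fdr``.  Proteins identical in every sample get
    F=0, p=1 by convention.
    """
    if len(groups) < 2:
        raise ValidationError("need >=2 groups for ANOVA")
    arrays = _group_arrays(m, annotations, groups)
    k = len(groups)
    ns = {g: a.shape[1] for g, a in arrays.items()}
    N = sum(ns.values())
    means = {g: a.mean(axis=1) for g, a in arrays.items()}
    grand = sum(ns[g] * means[g] for g in groups) / N
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ssw = sum(((arrays[g] - means[g][:, None]) ** 2).sum(axis=1) for g in groups)
    dfb, dfw = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(ssw == 0, np.where(ssb == 0, 1.0, 0.0), p)
    q, flags = bh_adjust(p, level=fdr)
    result = pd.DataFrame(index=m.values.index)
    for g in groups:
        result[f"mean_{g}"] = means[g]
    result["F"] = F
    result["p"] = p
    result["q"] = q
    result["significant"] = flags
    return result


def bh_adjust(p: Sequence[float], level: float = 0.05
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= level


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (rel. tol 1e-8)."""
    if y <= 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(
    sample_variances: Sequence[float], df: float
) -> ModeratedVariancePrior:
    """Estimate (d0, s0_sq) from per-protein residual variances.

    Moment matching on log variances: with ``z = log(s^2)`` and residual
    degrees of freedom ``d``, ``e = z - digamma(d/2) + log(d/2)`` has
    variance ``trigamma(d/2) + trigamma(d0/2)``; the excess dispersion over
    the sampling term identifies ``d0``, and the mean of ``e`` then
    identifies ``s0_sq``.  Zero or negative excess dispersion returns
    ``d0 = inf`` (all true variances equal).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise ValidationError(
            f"need >=10 positive variances to fit the prior, got {s2.size}"
        )
    half = df / 2.0
    e = np.log(s2) - special.digamma(half) + np.log(half)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, half)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModeratedVariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    contrast: tuple[str, str],
    prior: ModeratedVariancePrior | None = None,
    control_variance: pd.Series | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t test of ``contrast = (group, reference)``.

    ``control_variance``, when given, replaces the reference group's sample
    variance protein-by-protein (used for conservative control modelling).
    If ``prior`` is None it is fitted from this contrast's pooled variances.
    One-sided p-values test elevation in ``group`` over ``reference``.
    """
    group, reference = contrast
    arrays = _group_arrays(m, annotations, [group, reference])
    x1, x0 = arrays[group], arrays[reference]
    n1, n0 = x1.shape[1], x0.shape[1]
    mean1, mean0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    if control_variance is not None:
        v0 = control_variance.reindex(m.values.index).to_numpy(dtype=float)
        if np.any(~np.isfinite(v0)):
            raise ValidationError("control_variance missing for some proteins")
    d = n1 + n0 - 2
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / d
    if prior is None:
        prior = fit_variance_prior(s2, df=d)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = _DF_CAP
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean0) / se
    t = np.where(se == 0, np.where(mean1 == mean0, 0.0, np.inf * np.sign(mean1 - mean0)), t)
    p_two = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_one = stats.t.sf(t, df_total)
    return pd.DataFrame(
        {
            f"mean_{group}": mean1,
            f"mean_{reference}": mean0,
            "log2fc": mean1 - mean0,
            "s2_pooled": s2,
            "s2_post": s2_post,
            "se": se,
            "t": t,
            "df": df_total,
            "p": p_two,
            "p_one_sided": p_one,
        },
        index=m.values.index,
    )


def s0_significance(
    delta: Sequence[float],
    se: Sequence[float],
    df: float,
    params: VolcanoParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """S0-modified volcano significance.

    ``t_s0 = delta / (se + s0)``; p-values come from the t distribution on
    the unmodified degrees of freedom, then BH at ``params.fdr``.  Returns
    the per-protein table and the significance boundary curve (log2 fold
    change vs -log10 of the plain p-value) for plotting.
    """
    params = params or VolcanoParams()
    delta = np.asarray(delta, dtype=float)
    se = np.asarray(se, dtype=float)
    if delta.shape != se.shape:
        raise ValidationError("delta and se must have equal length")
    df_eff = df if np.isfinite(df) else _DF_CAP
    t_s0 = delta / (se + params.s0)
    p = 2.0 * stats.t.sf(np.abs(t_s0), df_eff)
    q, flags = bh_adjust(p, level=params.fdr)
    table = pd.DataFrame(
        {"delta": delta, "se": se, "t_s0": t_s0, "p": p, "q": q,
         "significant": flags}
    )
    curve = _s0_curve(table, df_eff, params)
    return table, curve


def _s0_curve(table: pd.DataFrame, df: float, params: VolcanoParams
              ) -> pd.DataFrame:
    """Boundary curve: for each |delta|, the plain -log10 p at the cutoff."""
    sig = table.loc[table["significant"], "t_s0"].abs()
    if sig.empty:
        return pd.DataFrame(columns=["delta", "neg_log10_p"])
    t_star = float(sig.min())
    deltas = np.linspace(params.s0 * t_star * 1.001,
                         max(2 * np.abs(table["delta"]).max(), 1.0), 200)
    se_b = deltas / t_star - params.s0
    valid = se_b > 0
    t_plain = deltas[valid] / se_b[valid]
    p_plain = 2.0 * stats.t.sf(np.abs(t_plain), df)
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(p_plain)
    return pd.DataFrame({"delta": deltas[valid], "neg_log10_p": neg_log10})
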