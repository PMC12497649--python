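"""Per-sgRNA differential abundance statistics.

The screen compares sgRNA abundances recovered from mouse brain episomes
(treatment) against the injected AAV input library (control). Counts are
median normalized across samples; guides with fewer than 100 raw reads
summed over control samples are excluded; a weighted least-squares line is
fit to log variance vs log mean over the control samples; each guide's
observed treatment abundance is then tested against a negative binomial
parameterized by its control mean and the fitted variance, giving
underabundance and overabundance tail p-values. The knockdown phenotype
phi_j is the log2 fold change of mean treatment over mean control
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from craave.counting import CountMatrix

#: multiplicative floor keeping the NB variance strictly above the mean
#: (continuity with the Poisson limit; NB undefined at var <= mean)
VARIANCE_FLOOR_EPS = 1e-6

DEFAULT_FILTER_THRESHOLD = 100
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class NormalizedMatrix:
    """Median-normalized abundances plus size factors and the filter mask."""

    values: pd.DataFrame
    size_factors: pd.Series
    samples: pd.DataFrame
    filter_mask: pd.Series  # True = retained
    filter_reason: pd.Series  # "" for retained guides

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "control"])

    @property
    def treatment_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "treatment"])

    def retained(self) -> pd.DataFrame:
        return self.values.loc[self.filter_mask]


@dataclass(frozen=True)
class MeanVarianceFit:
    """log-variance vs log-mean line fit on control samples.

    ``predict_variance`` floors the prediction at mean*(1+eps) so the NB
    parameterization is always defined (overdispersion floor).
    """

    intercept: float
    slope: float
    n_points: int
    weighted_r2: float
    floor_eps: float = VARIANCE_FLOOR_EPS

    def predict_variance(self, mean: np.ndarray | float) -> np.ndarray | float:
        mean = np.asarray(mean, dtype=float)
        fitted = np.exp(self.intercept + self.slope * np.log(mean))
        return np.maximum(fitted, mean * (1.0 + self.floor_eps))


def median_normalize(counts: CountMatrix, threshold: int | None = None) -> NormalizedMatrix:
    """Median-of-ratios normalization across samples.

    Per-sample size factor = median over reference guides of the ratio of
    the guide's count to its geometric mean across samples; only guides
    with nonzero counts in every sample qualify as reference guides (a
    single zero removes a guide from the median, not from the output).
    Size factors are rescaled to geometric mean 1, which makes the
    operation idempotent. Normalized value = count / size factor.

    Also applies the low-coverage filter (see :func:`filter_low_coverage`)
    when control samples are present, recording the mask and reason.
    """
    raw = counts.counts.to_numpy(dtype=float)
    if raw.shape[1] < 1:
        raise ValueError("need at least one sample")
    zero_samples = counts.counts.columns[(raw.sum(axis=0) == 0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    reference = (raw > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no guide has nonzero counts in every sample; median-of-ratios "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geomean = np.log(raw[reference]).mean(axis=1, keepdims=True)
    ratios = raw[reference] / np.exp(log_geomean)
    size_factors = np.median(ratios, axis=0)
    size_factors = size_factors / np.exp(np.mean(np.log(size_factors)))

    values = pd.DataFrame(
        raw / size_factors, index=counts.counts.index, columns=counts.counts.columns
    )
    if counts.control_samples:
        thr = DEFAULT_FILTER_THRESHOLD if threshold is None else threshold
        mask = filter_low_coverage(counts, threshold=thr)
    else:
        mask = pd.Series(True, index=counts.counts.index)
        thr = 0
    reason = pd.Series("", index=counts.counts.index)
    reason[~mask] = f"control_reads<{thr}"
    return NormalizedMatrix(
        values=values,
        size_factors=pd.Series(size_factors, index=counts.counts.columns),
        samples=counts.samples,
        filter_mask=mask,
        filter_reason=reason,
    )


def filter_low_coverage(
    counts: CountMatrix, threshold: int = DEFAULT_FILTER_THRESHOLD
) -> pd.Series:
    """Retain a guide iff its raw reads summed over control samples >= threshold.

    The AAV input (control) defines what was injected; guides the virus
    prep barely contains cannot be scored for depletion in mice.
    """
    controls = counts.control_samples
    if not controls:
        raise ValueError("low-coverage filter requires at least one control sample")
    control_sum = counts.counts[controls].sum(axis=1)
    return control_sum >= threshold


def fit_mean_variance(
    normalized: NormalizedMatrix, weighted: bool = True
) -> MeanVarianceFit:
    """Fit log variance = a + b * log mean over control samples by WLS.

    Uses retained guides only; guides with zero sample variance are
    excluded from the fit (log 0 undefined) but still receive predicted
    variances downstream. Weights are the control mean abundances (larger
    means give more precise log-variance estimates); pass
    ``weighted=False`` for ordinary least squares.
    """
    controls = normalized.control_samples
    if len(controls) < 2:
        raise ValueError(
            "mean-variance fit needs >= 2 control samples; with a single "
            "control use the Poisson fallback (variance = mean)"
        )
    vals = normalized.retained()[controls].to_numpy(dtype=float)
    means = vals.mean(axis=1)
    variances = vals.var(axis=1, ddof=1)
    ok = (means > 0) & (variances > 0)
    if ok.sum() < 2 or np.unique(means[ok]).size < 2:
        raise ValueError("degenerate mean-variance fit: need >= 2 distinct positive means")
    x = np.log(means[ok])
    y = np.log(variances[ok])
    w = means[ok] if weighted else np.ones_like(x)
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return MeanVarianceFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        n_points=int(ok.sum()),
        weighted_r2=float(model.rsquared),
    )


def _nb_params(mean: np.ndarray, variance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """scipy (n, p) parameterization from mean/variance with var > mean."""
    n = mean**2 / (variance - mean)
    p = n / (n + mean)
    return n, p


def nb_pvalues(
    observed: float | np.ndarray,
    control_mean: float | np.ndarray,
    fit: MeanVarianceFit | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial tail p-values for one observed abundance per guide.

    The NB is parameterized by mean = control_mean and variance =
    max(fitted variance, mean*(1+eps)); with ``fit=None`` the Poisson
    fallback variance = mean*(1+eps) is used (single-control case).
    Observed abundances are rounded half-up to the integer support.
    Returns ``(p_under, p_over)`` where p_under = P(X <= k) and
    p_over = P(X >= k); both tails include the observed point, so they are
    in (0, 1] and sum to >= 1.
    """
    observed = np.asarray(observed, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    if not (np.isfinite(observed).all() and np.isfinite(control_mean).all()):
        raise ValueError("nonfinite observed or control_mean")
    if (control_mean <= 0).any():
        raise ValueError("control_mean must be > 0 (guaranteed by the read filter)")
    k = np.floor(observed + 0.5)  # half-up: deterministic integer support
    if fit is None:
        variance = control_mean * (1.0 + VARIANCE_FLOOR_EPS)
    else:
        variance = fit.predict_variance(control_mean)
    n, p = _nb_params(control_mean, np.asarray(variance, dtype=float))
    p_under = stats.nbinom.cdf(k, n, p)
    p_over = stats.nbinom.sf(k - 1, n, p)
    tiny = np.finfo(float).tiny
    return np.clip(p_under, tiny, 1.0), np.clip(p_over, tiny, 1.0)


def guide_phenotypes(
    normalized: NormalizedMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Knockdown phenotype phi_j = log2 fold change, treatment vs control.

    phi_j = log2((mean treatment + pseudocount) / (mean control +
    pseudocount)); the pseudocount (default 0.5) keeps phi finite for
    fully depleted guides and is never applied to the p-value test.
    """
    controls = normalized.control_samples
    treatments = normalized.treatment_samples
    if not controls or not treatments:
        raise ValueError("phenotypes need >= 1 control and >= 1 treatment sample")
    mc = normalized.values[controls].mean(axis=1)
    mt = normalized.values[treatments].mean(axis=1)
    return np.log2((mt + pseudocount) / (mc + pseudocount)).rename("phi")


def screen_guides(
    counts: CountMatrix,
    filter_threshold: int = DEFAULT_FILTER_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    treatment_sample: str | None = None,
    weighted_fit: bool = True,
) -> pd.DataFrame:
    """Full per-sgRNA analysis: normalize, filter, fit, test, phenotype.

    In cohort mode (default) the rounded mean of the normalized treatment
    columns is tested against each guide's control-mean NB; passing
    ``treatment_sample`` tests that single mouse column alone (per-mouse
    mode). Returns a DataFrame over retained guides with columns
    ``guide_id`` (index), ``group``, ``gene``, ``is_ntc``, ``control_mean``,
    ``observed``, ``phi``, ``p_under``, ``p_over``.
    """
    counts.require_roles()
    normalized = median_normalize(counts, threshold=filter_threshold)
    controls = normalized.control_samples
    if treatment_sample is not None:
        if treatment_sample not in normalized.treatment_samples:
            raise ValueError(f"{treatment_sample!r} is not a treatment sample")
        treatments = [treatment_sample]
    else:
        treatments = normalized.treatment_samples

    if len(controls) >= 2:
        fit = fit_mean_variance(normalized, weighted=weighted_fit)
    else:
        fit = None  # Poisson fallback

    retained = normalized.filter_mask
    vals = normalized.values.loc[retained]
    control_mean = vals[controls].mean(axis=1)
    observed = vals[treatments].mean(axis=1)
    p_under, p_over = nb_pvalues(
        observed.to_numpy(), control_mean.to_numpy(), fit
    )

    sub = NormalizedMatrix(
        values=normalized.values[controls + treatments],
        size_factors=normalized.size_factors[controls + treatments],
        samples=normalized.samples.loc[controls + treatments],
        filter_mask=normalized.filter_mask,
        filter_reason=normalized.filter_reason,
    )
    phi = guide_phenotypes(sub, pseudocount=pseudocount).loc[retained]

    lib = counts.library.to_frame().set_index("guide_id").loc[retained[retained].index]
    return pd.DataFrame(
        {
            "group": lib["group"],
            "gene": lib["gene"],
            "is_ntc": lib["is_ntc"],
            "control_mean": control_mean,
            "observed": observed,
            "phi": phi,
            "p_under": p_under,
            "p_over": p_over,
        }
    )
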