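"""Two-group differential abundance for count matrices.

The model is the negative binomial with variance mu + phi*mu^2. Inference is
the classical conditional (exact) test: after library sizes are equalized by
quantile mapping to their geometric mean, each feature's group-A sum is
compared to its conditional law given the feature total; two-sided p-values
sum the probabilities of all splits no more probable than the observed one
(no doubling). Dispersion is estimated by conditional maximum likelihood,
common across features, with per-feature (tagwise) values shrunk toward the
common one through a prior-weighted conditional likelihood.

The reported effect size is log2 of the ratio of group-mean CPM, computed
independently of the test, so the results table mirrors the
mean-A / mean-B / log2FC / p / FDR layout used in small-RNA studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix, cpm

log = logging.getLogger(__name__)

PHI_MIN = 1e-6
PHI_MAX = 10.0
_POISSON_PHI = 1e-10  # below this, use the Poisson/binomial limit
_TIE_REL = 1e-8  # relative tolerance when comparing pmf values for two-sidedness


def _as_frame(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.counts if isinstance(matrix, CountMatrix) else matrix


def _split_groups(columns, groups: pd.Series, reference: str, comparison: str):
    a = [c for c in columns if groups.get(c) == reference]
    b = [c for c in columns if groups.get(c) == comparison]
    if not a or not b:
        raise ValueError(f"empty group: {reference!r} n={len(a)}, {comparison!r} n={len(b)}")
    return a, b


# ---------------------------------------------------------------------------
# effect size

def log2fc_from_means(mean_a, mean_b, pseudocount: float = 0.0) -> np.ndarray:
    """log2((mean_b + pc) / (mean_a + pc)); +/-inf when a mean is zero at pc=0."""
    a = np.asarray(mean_a, dtype=float) + pseudocount
    b = np.asarray(mean_b, dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(b) - np.log2(a)


def group_log2fc(
    matrix: CountMatrix | pd.DataFrame,
    groups: pd.Series,
    reference: str,
    comparison: str,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-feature group-mean CPM and log2 fold-change (comparison over reference).

    Means are arithmetic means of per-sample CPM within each group. With the
    default pseudocount of 0, features with a zero group mean get an infinite
    or undefined log2fc and are flagged (``finite`` column) rather than dropped.
    """
    counts = _as_frame(matrix)
    a, b = _split_groups(counts.columns, groups, reference, comparison)
    cpms = cpm(counts)
    mean_a = cpms[a].mean(axis=1)
    mean_b = cpms[b].mean(axis=1)
    lfc = log2fc_from_means(mean_a.values, mean_b.values, pseudocount)
    return pd.DataFrame(
        {
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "log2fc": lfc,
            "finite": np.isfinite(lfc),
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# library-size equalization

def _q2q(y: np.ndarray, mean_in: np.ndarray, mean_out: np.ndarray, phi: float) -> np.ndarray:
    """Quantile-map counts from NB(mean_in, phi) to NB(mean_out, phi).

    Classical continuous prescription: average of the normal and gamma
    quantile maps with matched mean/variance, clipped at zero.
    """
    var_in = mean_in * (1 + phi * mean_in)
    var_out = mean_out * (1 + phi * mean_out)
    z = (y - mean_in) / np.sqrt(var_in)
    out_norm = mean_out + z * np.sqrt(var_out)
    shape_in = mean_in**2 / var_in
    scale_in = var_in / mean_in
    shape_out = mean_out**2 / var_out
    scale_out = var_out / mean_out
    q = stats.gamma.cdf(y, a=shape_in, scale=scale_in)
    out_gamma = stats.gamma.ppf(np.clip(q, 0.0, 1.0 - 1e-16), a=shape_out, scale=scale_out)
    return np.clip(0.5 * (out_norm + out_gamma), 0.0, None)


def equalize_library_sizes(
    counts: pd.DataFrame, dispersion: float = 0.0
) -> tuple[pd.DataFrame, float]:
    """Map every sample's counts onto the geometric-mean library size.

    Returns (pseudo-counts, common library size). Equal library sizes are a
    fixed point: the mapping is then the exact identity.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size; drop empty samples first")
    common = float(np.exp(np.mean(np.log(lib))))
    if np.allclose(lib, common, rtol=1e-12, atol=0):
        return counts.astype(float), common
    totals = counts.sum(axis=1).astype(float)
    p = (totals / lib.sum()).values  # feature relative abundance
    pseudo = np.zeros(counts.shape, dtype=float)
    y = counts.values.astype(float)
    pos = p > 0
    for j, s in enumerate(counts.columns):
        mean_in = p[pos] * lib[s]
        mean_out = p[pos] * common
        pseudo[pos, j] = _q2q(y[pos, j], mean_in, mean_out, dispersion)
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


# ---------------------------------------------------------------------------
# dispersion

@dataclass
class DispersionEstimate:
    common_phi: float
    tagwise_phi: pd.Series  # per-feature, shrunk toward common


def _conditional_loglik(
    y: np.ndarray, group_cols: list[np.ndarray], phi_grid: np.ndarray
) -> np.ndarray:
    """Conditional NB log-likelihood per feature per grid dispersion.

    For one group with n samples, counts y_i and total z, dropping phi-free
    terms:  sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r)
    with r = 1/phi. Summed over groups.
    """
    F = y.shape[0]
    cl = np.zeros((F, len(phi_grid)))
    for g, cols in enumerate(group_cols):
        yg = y[:, cols]
        n = yg.shape[1]
        z = yg.sum(axis=1)
        for k, phi in enumerate(phi_grid):
            r = 1.0 / phi
            cl[:, k] += (
                gammaln(yg + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
    return cl


def _parabolic_argmax(log_grid: np.ndarray, values: np.ndarray) -> float:
    """Refine a grid argmax by parabolic interpolation in log-dispersion."""
    i = int(np.argmax(values))
    if i == 0 or i == len(log_grid) - 1:
        return float(np.exp(log_grid[i]))
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(np.exp(log_grid[i]))
    h = log_grid[i + 1] - log_grid[i]
    x = log_grid[i] + 0.5 * h * (y0 - y2) / denom
    return float(np.exp(x))


def estimate_dispersion(
    matrix: CountMatrix | pd.DataFrame,
    groups: pd.Series,
    reference: str,
    comparison: str,
    prior_df: float = 10.0,
    n_grid: int = 81,
) -> DispersionEstimate:
    """Common + tagwise NB dispersion by conditional maximum likelihood.

    Counts are first equalized to the geometric-mean library size (Poisson
    quantile map, dispersion being unknown at this point). The common value
    maximizes the pooled conditional likelihood on a log grid over
    [1e-6, 10] with parabolic refinement; tagwise values maximize
    CL_f + prior_df * mean_f(CL), collapsing to the common value as
    prior_df grows.
    """
    counts = _as_frame(matrix)
    if counts.values.sum() == 0:
        log.warning("all-zero matrix; dispersion set to 0")
        zero = pd.Series(0.0, index=counts.index)
        return DispersionEstimate(0.0, zero)
    a, b = _split_groups(counts.columns, groups, reference, comparison)
    pseudo, _ = equalize_library_sizes(counts, dispersion=0.0)
    y = pseudo.values
    idx = {c: j for j, c in enumerate(pseudo.columns)}
    group_cols = [np.array([idx[c] for c in a]), np.array([idx[c] for c in b])]
    log_grid = np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), n_grid)
    cl = _conditional_loglik(y, group_cols, np.exp(log_grid))
    common = _parabolic_argmax(log_grid, cl.sum(axis=0))
    weighted = cl + prior_df * cl.mean(axis=0)
    tagwise = pd.Series(
        [_parabolic_argmax(log_grid, weighted[f]) for f in range(cl.shape[0])],
        index=counts.index,
    )
    return DispersionEstimate(common, tagwise)


# ---------------------------------------------------------------------------
# exact test

def _exact_p(total: int, a_obs: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional p for an observed group-A sum.

    Under H0 with equal per-sample means and equalized libraries, the group-A
    sum given the total follows the NB convolution ratio law, which reduces to
    Binomial(total, n_a/(n_a+n_b)) as phi -> 0. All splits with probability
    <= the observed one (within a 1e-8 relative tie tolerance) are summed.
    """
    if total <= 0:
        return 1.0
    k = np.arange(total + 1)
    if phi < _POISSON_PHI:
        p_a = n_a / (n_a + n_b)
        logpmf = (
            gammaln(total + 1)
            - gammaln(k + 1)
            - gammaln(total - k + 1)
            + k * np.log(p_a)
            + (total - k) * np.log1p(-p_a)
        )
    else:
        r = 1.0 / phi
        ra, rb = n_a * r, n_b * r
        logpmf = (
            gammaln(k + ra)
            - gammaln(k + 1)
            + gammaln(total - k + rb)
            - gammaln(total - k + 1)
        )
    norm = logsumexp(logpmf)
    keep = logpmf <= logpmf[a_obs] + np.log1p(_TIE_REL)
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]) - norm)))


def exact_test(
    matrix: CountMatrix | pd.DataFrame,
    groups: pd.Series,
    dispersion: DispersionEstimate | float,
    reference: str,
    comparison: str,
) -> pd.Series:
    """Per-feature two-sided conditional NB p-values.

    Library sizes are equalized with the common dispersion, group sums rounded
    to integers to restore a discrete support, and each feature tested at its
    tagwise dispersion (or the given scalar).
    """
    counts = _as_frame(matrix)
    a, b = _split_groups(counts.columns, groups, reference, comparison)
    if isinstance(dispersion, DispersionEstimate):
        common = dispersion.common_phi
        phis = dispersion.tagwise_phi.reindex(counts.index).values
    else:
        common = float(dispersion)
        phis = np.full(len(counts.index), common)
    pseudo, _ = equalize_library_sizes(counts, dispersion=common)
    sum_a = np.rint(pseudo[a].sum(axis=1).values).astype(np.int64)
    sum_b = np.rint(pseudo[b].sum(axis=1).values).astype(np.int64)
    pvals = np.ones(len(counts.index))
    for i in range(len(pvals)):
        pvals[i] = _exact_p(int(sum_a[i] + sum_b[i]), int(sum_a[i]), len(a), len(b), float(phis[i]))
    return pd.Series(pvals, index=counts.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# pipeline-facing wrappers

def cpm_filter(
    matrix: CountMatrix | pd.DataFrame, min_mean_cpm: float = 10.0
) -> list[str]:
    """Features with mean CPM across ALL samples >= the floor (default 10)."""
    mean_cpm = cpm(_as_frame(matrix)).mean(axis=1)
    return list(mean_cpm.index[mean_cpm >= min_mean_cpm])


def differential_expression(
    matrix: CountMatrix | pd.DataFrame,
    groups: pd.Series,
    reference: str,
    comparison: str,
    min_mean_cpm: float = 10.0,
    prior_df: float = 10.0,
    fdr_threshold: float = 0.1,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """CPM floor -> dispersion -> exact test -> BH -> flags, in one table."""
    counts = _as_frame(matrix)
    kept = cpm_filter(counts, min_mean_cpm)
    counts = counts.loc[kept]
    fc = group_log2fc(counts, groups, reference, comparison)
    disp = estimate_dispersion(counts, groups, reference, comparison, prior_df=prior_df)
    p = exact_test(counts, groups, disp, reference, comparison)
    out = fc.copy()
    out["p_value"] = p
    out["fdr_bh"] = bh_adjust(p.values)
    out["significant"] = out["fdr_bh"] < fdr_threshold
    out["strong"] = np.abs(out["log2fc"]) > lfc_threshold
    out["dispersion"] = disp.tagwise_phi.reindex(out.index)
    return out


def select_strong(
    results: pd.DataFrame,
    lfc_threshold: float = 2.0,
    fdr_threshold: float = 0.1,
    min_mean_cpm: float = 10.0,
    group_sizes: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Strongly modulated features: |log2fc| strictly above the threshold.

    When ``group_sizes`` is given, the all-sample mean CPM floor is re-applied
    from the group means ((nA*meanA + nB*meanB)/(nA+nB) >= min_mean_cpm);
    otherwise the input is assumed pre-filtered. Non-finite log2fc rows are
    excluded from ranking. Sorted by log2fc descending; ``significant`` flags
    FDR below the threshold when a p/FDR column is present.
    """
    res = results.copy()
    if group_sizes is not None:
        n_a, n_b = group_sizes
        overall = (n_a * res["mean_cpm_a"] + n_b * res["mean_cpm_b"]) / (n_a + n_b)
        res = res[overall >= min_mean_cpm]
    res = res[np.isfinite(res["log2fc"])]
    res = res[np.abs(res["log2fc"]) > lfc_threshold]
    res = res.sort_values("log2fc", ascending=False, kind="mergesort")
    if "fdr_bh" in res.columns:
        res["significant"] = res["fdr_bh"] < fdr_threshold
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    return res


# ---------------------------------------------------------------------------
# cross-cohort concordance

CONCORDANCE_CATEGORIES = ("not_expressed", "no_difference", "confirmed", "opposite")


def classify_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    expressed_in_validation: set[str],
    lfc_min: float = 0.5,
) -> pd.DataFrame:
    """Assign each discovery feature one validation category.

    not_expressed: below the validation expression threshold; no_difference:
    |validation log2fc| < lfc_min; confirmed: sign agrees with discovery;
    opposite: sign disagrees.
    """
    if discovery.index.duplicated().any() or validation.index.duplicated().any():
        raise ValueError("duplicate feature ids")
    rows = []
    for feat in discovery.index:
        d_lfc = float(discovery.loc[feat, "log2fc"])
        if feat not in expressed_in_validation:
            cat, v_lfc = "not_expressed", np.nan
        else:
            v_lfc = float(validation.loc[feat, "log2fc"])
            if abs(v_lfc) < lfc_min:
                cat = "no_difference"
            elif np.sign(v_lfc) == np.sign(d_lfc):
                cat = "confirmed"
            else:
                cat = "opposite"
        rows.append(
            {"feature": feat, "discovery_log2fc": d_lfc,
             "validation_log2fc": v_lfc, "category": cat}
        )
    return pd.DataFrame(rows).set_index("feature")
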