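"""Negative-binomial differential-expression testing for 3-vs-3 contrasts.

The model is the standard NB generalized linear model for counts with
log link and library-size offsets: for gene g in library l,

    y_gl ~ NB(mu_gl, phi_g),   var = mu + phi mu^2,
    log mu_gl = beta_{g,group(l)} + log s_l,

where s_l is a relative effective-size factor (median-of-ratios or TMM,
rescaled to geometric mean 1).  Gene-wise NB dispersions are estimated by
maximizing the Cox-Reid adjusted profile likelihood (APL) on a dispersion
grid, smoothed into a mean-dependent trend and squeezed toward it by
weighted-likelihood empirical Bayes.

Pairwise testing uses a moderated quasi-likelihood F statistic: residual
deviances from the full (two group means) fit give gene-wise quasi
dispersions, which are squeezed toward a common value by fitting a scaled
F distribution to their sampling spread (the limma squeezeVar scheme); the
drop in deviance between the intercept-only and the group-means model,
scaled by the squeezed quasi-dispersion, is referred to an F distribution
with augmented denominator degrees of freedom.  An exact conditional NB
test is available as a fallback for very small problems.

Family-wise error control is Bonferroni: p_adj = min(1, p * m) with m the
number of genes passing the detection filter in that comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DesignError, ParameterError, ValidationError
from .spike_calibration import DetectionFilterResult
from .synthetic_data import CountMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
_PHI_GRID = np.concatenate([[1e-6], np.geomspace(1e-4, 5.0, 48)])


@dataclass(frozen=True)
class NormalizationFactors:
    """Relative effective-size factors, geometric mean 1."""

    per_library: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        vals = np.array(list(self.per_library.values()))
        if (vals <= 0).any():
            raise ValidationError("size factors must be > 0")
        if abs(np.log(vals).mean()) > 1e-8:
            raise ValidationError("size factors must have geometric mean 1")

    def series(self, library_ids: list[str] | None = None) -> pd.Series:
        s = pd.Series(self.per_library, dtype=float)
        return s if library_ids is None else s.reindex(library_ids)


@dataclass(frozen=True)
class DispersionEstimates:
    """Raw, trended and empirical-Bayes-shrunk NB dispersions per gene."""

    per_gene: pd.DataFrame  # index gene_id: raw, trended, shrunk, mean_count
    common: float
    prior_n: float
    trend_description: str

    def dispersion_for(self, gene_ids: list[str], kind: str = "trended") -> np.ndarray:
        if kind not in ("raw", "trended", "shrunk"):
            raise ParameterError(f"unknown dispersion kind {kind!r}")
        out = self.per_gene[kind].reindex(gene_ids).to_numpy(dtype=float)
        return np.where(np.isfinite(out), out, self.common)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-gene DE statistics for one pairwise contrast (mutant over WT)."""

    comparison_id: str
    table: pd.DataFrame  # index gene_id: mean_count, log2fc, p_raw, p_bonferroni, significant, detected
    n_tested: int
    alpha: float

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])


# --------------------------------------------------------------------------
# normalization

def _geomean_rescale(factors: pd.Series) -> pd.Series:
    return factors / np.exp(np.log(factors).mean())


def estimate_size_factors(
    matrix: CountMatrix, method: str = "median_of_ratios"
) -> NormalizationFactors:
    """Estimate relative effective library sizes from endogenous genes.

    ``median_of_ratios`` is the DESeq estimator: per library, the median
    ratio of counts to the per-gene geometric mean over genes nonzero in
    every library.  ``tmm`` is the trimmed mean of M-values against a
    reference library, multiplied by the raw library size.  Both are
    rescaled to geometric mean 1.  When no gene is nonzero in all
    libraries, total-count ratios are used with a warning.
    """
    endo = matrix.endogenous()
    if endo.shape[1] < 2:
        raise DesignError("need at least 2 libraries")
    counts = endo.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if method == "median_of_ratios":
        if not all_pos.any():
            logger.warning(
                "no gene nonzero in all libraries; falling back to total-count ratios"
            )
            totals = endo.sum(axis=0).astype(float)
            factors = _geomean_rescale(totals)
        else:
            logc = np.log(counts[all_pos])
            log_geomean = logc.mean(axis=1, keepdims=True)
            factors = pd.Series(
                np.exp(np.median(logc - log_geomean, axis=0)), index=endo.columns
            )
            factors = _geomean_rescale(factors)
    elif method == "tmm":
        factors = _geomean_rescale(_tmm_effective_sizes(endo))
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    return NormalizationFactors(per_library=factors.to_dict(), method=method)


def _tmm_factor(y: np.ndarray, yr: np.ndarray, n: float, nr: float) -> float:
    """TMM factor of library y against reference yr (edgeR conventions)."""
    pos = (y > 0) & (yr > 0)
    y, yr = y[pos], yr[pos]
    if y.size == 0:
        return 1.0
    m = np.log2((y / n) / (yr / nr))
    a = 0.5 * np.log2((y / n) * (yr / nr))
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    k = m.size
    lo_m, lo_a = int(np.floor(k * 0.3)) + 1, int(np.floor(k * 0.05)) + 1
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (
        (rank_m >= lo_m)
        & (rank_m <= k + 1 - lo_m)
        & (rank_a >= lo_a)
        & (rank_a <= k + 1 - lo_a)
    )
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f) if np.isfinite(f) else 1.0


def _tmm_effective_sizes(endo: pd.DataFrame) -> pd.Series:
    counts = endo.to_numpy(dtype=float)
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes == 0).any():
        raise ValidationError("library with zero total count")
    q75 = np.array(
        [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_factor(counts[:, j], counts[:, ref], lib_sizes[j], lib_sizes[ref])
            for j in range(counts.shape[1])
        ]
    )
    return pd.Series(lib_sizes * factors, index=endo.columns)


# --------------------------------------------------------------------------
# NB likelihood machinery (vectorized over genes)

def _fit_log_means(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, max_iter: int = 60
) -> np.ndarray:
    """MLE of a common log-mean per gene across libraries, NB with offsets.

    Solves sum_l (y - mu) / (1 + phi mu) = 0 with mu_l = exp(beta) * s_l by
    Newton iteration; y is (G, n), s is (n,), phi is (G,).  Returns beta (G,).
    """
    y = np.asarray(y, dtype=float)
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / s.sum())
    phi = phi[:, None]
    for _ in range(max_iter):
        mu = np.exp(beta)[:, None] * s[None, :]
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + phi * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.where(tot > 0, beta, np.log(1e-8))


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB residual deviance (Poisson limit for tiny phi)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[..., None], y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    small = phi < 1e-8
    phi_safe = np.maximum(phi, 1e-8)
    nb_term = np.where(
        small,
        y - mu,
        (y + 1.0 / phi_safe) * np.log1p(phi_safe * (y - mu) / (1.0 + phi_safe * mu)),
    )
    return 2.0 * (ylogy - nb_term).sum(axis=-1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over libraries; phi scalar."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    if phi < 1e-8:
        return (y * np.log(mu) - mu - special.gammaln(y + 1.0)).sum(axis=-1)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    ).sum(axis=-1)


def _group_indices(
    library_ids: list[str], groups: dict[str, str]
) -> dict[str, np.ndarray]:
    by_group: dict[str, list[int]] = {}
    for j, lib in enumerate(library_ids):
        if lib not in groups:
            raise DesignError(f"library {lib!r} missing from group map")
        by_group.setdefault(groups[lib], []).append(j)
    return {g: np.array(idx) for g, idx in by_group.items()}


def _apl_profile(
    y: np.ndarray, s: np.ndarray, group_idx: dict[str, np.ndarray], phi_grid: np.ndarray
) -> np.ndarray:
    """Cox-Reid APL for every gene at every grid dispersion: (G, K).

    For the one-way layout the CR adjustment is
    -0.5 * sum_groups log(sum_l w_l) with working weights w = mu/(1+phi mu).
    """
    G = y.shape[0]
    apl = np.empty((G, phi_grid.size))
    for k, phi in enumerate(phi_grid):
        phi_vec = np.full(G, phi)
        ll = np.zeros(G)
        cr = np.zeros(G)
        for idx in group_idx.values():
            beta = _fit_log_means(y[:, idx], s[idx], phi_vec)
            mu = np.exp(beta)[:, None] * s[idx][None, :]
            ll += _nb_loglik(y[:, idx], mu, phi)
            w = mu / (1.0 + phi * mu)
            cr += 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-300))
        apl[:, k] = ll - cr
    return apl


def estimate_dispersions(
    matrix: CountMatrix,
    groups: dict[str, str],
    norm: NormalizationFactors,
    prior_n: float = 10.0,
    n_bins: int = 10,
    gene_ids: list[str] | None = None,
) -> DispersionEstimates:
    """Estimate NB dispersions by grid APL with empirical-Bayes shrinkage.

    Raw gene-wise dispersions maximize the Cox-Reid APL on a fixed grid.
    The trend is the per-bin (by mean normalized count) maximizer of the
    summed APL, interpolated in log-mean; shrunk dispersions maximize
    APL_g + prior_n * (bin-average APL), pulling noisy gene-wise values
    toward the local trend with prior weight ``prior_n`` pseudo-genes.
    """
    endo = matrix.endogenous()
    if gene_ids is not None:
        endo = endo.loc[[g for g in endo.index if g in set(gene_ids)]]
    libs = list(endo.columns)
    group_idx = _group_indices(libs, groups)
    for g, idx in group_idx.items():
        if idx.size < 2:
            raise DesignError(f"group {g!r} has fewer than 2 libraries")
    y = endo.to_numpy(dtype=float)
    s = norm.series(libs).to_numpy(dtype=float)
    mean_count = (y / s[None, :]).mean(axis=1)

    apl = _apl_profile(y, s, group_idx, _PHI_GRID)
    raw = _PHI_GRID[np.argmax(apl, axis=1)]
    common = float(_PHI_GRID[np.argmax(apl.sum(axis=0))])

    # bin genes by abundance; per-bin common dispersion defines the trend
    order = np.argsort(mean_count)
    bins = np.array_split(order, max(1, min(n_bins, y.shape[0] // 50) or 1))
    trended = np.full(y.shape[0], common)
    shrunk = np.empty(y.shape[0])
    for b in bins:
        if b.size == 0:
            continue
        bin_profile = apl[b].mean(axis=0)
        trended[b] = _PHI_GRID[np.argmax(bin_profile)]
        weighted = apl[b] + prior_n * bin_profile[None, :]
        shrunk[b] = _PHI_GRID[np.argmax(weighted, axis=1)]

    per_gene = pd.DataFrame(
        {"raw": raw, "trended": trended, "shrunk": shrunk, "mean_count": mean_count},
        index=endo.index,
    )
    return DispersionEstimates(
        per_gene=per_gene,
        common=common,
        prior_n=float(prior_n),
        trend_description=f"binned APL maximizer over {len(bins)} abundance bins",
    )


# --------------------------------------------------------------------------
# moderation of quasi-dispersions (limma squeezeVar scheme)

def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-fit s2 ~ s2_0 * F(df1, df2); returns (df2, s2_0)."""
    ok = s2 > 0
    if ok.sum() < 3:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean, evar = e.mean(), e.var(ddof=1)
    evar -= special.polygamma(1, df1 / 2.0)
    if evar > 0:
        df2 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(df2 / 2.0) - np.log(df2 / 2.0))
    else:
        df2, s20 = np.inf, np.exp(emean)
    return float(df2), float(s20)


def squeeze_quasi_dispersions(
    s2: np.ndarray, df_residual: float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes squeeze of quasi-dispersions toward a common value.

    Returns (squeezed values, prior df, prior value).
    """
    df_prior, s2_prior = _fit_f_dist(s2, df_residual)
    if np.isinf(df_prior):
        return np.full_like(s2, s2_prior), df_prior, s2_prior
    post = (df_prior * s2_prior + df_residual * s2) / (df_prior + df_residual)
    return post, df_prior, s2_prior


# --------------------------------------------------------------------------
# pairwise testing

def bonferroni_adjust(p_values: np.ndarray | list[float], m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ParameterError("m must be >= number of p-values")
    return np.minimum(1.0, np.maximum(p, P_FLOOR) * m)


def _exact_nb_pvalues(
    yA: np.ndarray, yB: np.ndarray, sA: np.ndarray, sB: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Conditional NB exact test on group sums (equal-size approximation).

    Group sums are treated as NB with size n_g/phi and means proportional
    to the summed size factors; the two-sided p sums the conditional
    probabilities not exceeding that of the observed split.  Intended for
    small fixtures; the QL F test is the default for real runs.
    """
    SA, SB = sA.sum(), sB.sum()
    nA, nB = len(sA), len(sB)
    totA, totB = yA.sum(axis=1), yB.sum(axis=1)
    pvals = np.empty(totA.size)
    for g in range(totA.size):
        t = int(totA[g] + totB[g])
        if t == 0:
            pvals[g] = 1.0
            continue
        mu0 = t / (SA + SB)
        a = np.arange(t + 1)
        if phi[g] < 1e-8:
            la = stats.poisson.logpmf(a, mu0 * SA)
            lb = stats.poisson.logpmf(t - a, mu0 * SB)
        else:
            ra, rb = nA / phi[g], nB / phi[g]
            la = stats.nbinom.logpmf(a, ra, ra / (ra + mu0 * SA))
            lb = stats.nbinom.logpmf(t - a, rb, rb / (rb + mu0 * SB))
        joint = la + lb
        joint -= special.logsumexp(joint)
        obs = joint[int(totA[g])]
        pvals[g] = float(np.exp(special.logsumexp(joint[joint <= obs + 1e-12])))
    return np.minimum(pvals, 1.0)


def test_pairwise(
    matrix: CountMatrix,
    group_mutant: list[str],
    group_wt: list[str],
    norm: NormalizationFactors,
    disp: DispersionEstimates,
    detection: DetectionFilterResult,
    alpha: float = 0.05,
    test: str = "qlf",
    pseudocount: float = 0.5,
    dispersion_kind: str = "trended",
    comparison_id: str | None = None,
) -> ComparisonResult:
    """Test one pairwise contrast (mutant vs WT) on detection-filtered genes.

    log2 fold changes are log2((m_mut + c0)/(m_wt + c0)) on mean normalized
    counts with pseudocount c0, oriented mutant-over-WT.  p-values come
    from the moderated quasi-likelihood F test (default) or the exact
    conditional NB test; Bonferroni m equals the number of analyzable genes
    in this comparison.
    """
    if set(group_mutant) & set(group_wt):
        raise DesignError("mutant and WT groups overlap")
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    if test not in ("qlf", "exact"):
        raise ParameterError(f"unknown test {test!r}")
    libs = group_mutant + group_wt
    if set(libs) - set(matrix.counts.columns):
        raise LookupError("comparison libraries missing from matrix")

    endo = matrix.endogenous()
    genes = [g for g in endo.index if g in detection.analyzable_genes]
    y = endo.loc[genes, libs].to_numpy(dtype=float)
    s = norm.series(libs).to_numpy(dtype=float)
    nA = len(group_mutant)
    idxA, idxB = np.arange(nA), np.arange(nA, len(libs))
    phi = disp.dispersion_for(genes, kind=dispersion_kind)

    norm_counts = y / s[None, :]
    mA = norm_counts[:, idxA].mean(axis=1)
    mB = norm_counts[:, idxB].mean(axis=1)
    log2fc = np.log2((mA + pseudocount) / (mB + pseudocount))
    mean_count = norm_counts.mean(axis=1)

    if test == "qlf":
        betaA = _fit_log_means(y[:, idxA], s[idxA], phi)
        betaB = _fit_log_means(y[:, idxB], s[idxB], phi)
        beta0 = _fit_log_means(y, s, phi)
        mu_full = np.empty_like(y)
        mu_full[:, idxA] = np.exp(betaA)[:, None] * s[idxA][None, :]
        mu_full[:, idxB] = np.exp(betaB)[:, None] * s[idxB][None, :]
        mu_red = np.exp(beta0)[:, None] * s[None, :]
        dev_full = nb_deviance(y, mu_full, phi)
        dev_red = nb_deviance(y, mu_red, phi)
        df_res = float(len(libs) - 2)
        s2 = np.maximum(dev_full, 0.0) / df_res
        s2_post, df_prior, _ = squeeze_quasi_dispersions(s2, df_res)
        drop = np.maximum(dev_red - dev_full, 0.0)
        f_stat = drop / np.maximum(s2_post, 1e-12)
        df_total = df_res + min(df_prior, 1e6)
        p_raw = stats.f.sf(f_stat, 1.0, df_total)
    else:
        p_raw = _exact_nb_pvalues(y[:, idxA], y[:, idxB], s[idxA], s[idxB], phi)

    n_tested = len(genes)
    p_bonf = bonferroni_adjust(p_raw, n_tested) if n_tested else np.array([])
    table = pd.DataFrame(
        {
            "mean_count": mean_count,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha if n_tested else [],
            "detected": True,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    cid = comparison_id or detection.comparison_id or "comparison"
    return ComparisonResult(comparison_id=cid, table=table, n_tested=n_tested, alpha=alpha)
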