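"""Count-based differential abundance and community-level statistics.

The stack used on the genus and gene-family count tables:

* a counts-per-million abundance filter (default: CPM >= 4 in >= 4 samples),
* TMM (trimmed mean of M-values) normalization factors,
* negative-binomial dispersion estimation by quantile-adjusted conditional
  maximum likelihood (qCML), with optional tagwise empirical-Bayes
  shrinkage toward the common value,
* a conditional two-sided NB exact test on group sums of
  quantile-adjusted counts,
* a quasi-Poisson log-link GLM (IRLS) with an exposure offset for
  RPKG-scale gene tables,
* Benjamini-Hochberg FDR adjustment,
* Bray-Curtis distances, PERMANOVA (exhaustive or sampled permutations)
  and a betadisper-style test of multivariate dispersion homogeneity.

All functions take feature x sample pandas DataFrames.  Where a test
contrasts two groups, group levels are taken in order of first appearance
in the ``groups`` mapping and effects are reported as second level versus
first.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson
from scipy.stats import t as t_dist

_PHI_MIN, _PHI_MAX = 1e-6, 10.0


@dataclass
class DesignInfo:
    """Sample-to-group assignment for a two-treatment design."""

    groups: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def levels(self) -> list[str]:
        return list(dict.fromkeys(self.groups.values()))


@dataclass
class DispersionEstimate:
    """NB dispersion: a common value and optional per-feature values."""

    common_phi: float
    tagwise_phi: pd.Series | None = None
    prior_df: float = 10.0


def _levels_and_indices(
    samples: Sequence[str], groups: Mapping[str, str]
) -> tuple[list[str], list[np.ndarray]]:
    levels = list(dict.fromkeys(groups[s] for s in samples))
    idx = [
        np.array([j for j, s in enumerate(samples) if groups[s] == lev])
        for lev in levels
    ]
    return levels, idx


def _as_lib_sizes(counts: pd.DataFrame, library_sizes: pd.Series | None) -> np.ndarray:
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = library_sizes.reindex(counts.columns).astype(float)
    arr = lib.to_numpy()
    if (arr <= 0).any() or np.isnan(arr).any():
        raise ValueError("library sizes must be positive for all samples")
    return arr


# -- abundance filter ----------------------------------------------------


def cpm_filter(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    min_cpm: float = 4.0,
    min_samples: int = 4,
) -> tuple[pd.DataFrame, int]:
    """Keep features with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    CPM is count / library size x 1e6; both thresholds are inclusive.
    Returns the kept table and the number of removed features.
    """
    lib = _as_lib_sizes(counts, library_sizes)
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep], int((~keep).sum())


# -- TMM normalization ---------------------------------------------------


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference is the sample whose 75th-percentile count proportion is
    closest to the mean over samples.  For each sample, features with a
    zero in either sample are excluded; M-values (log2 proportion ratios)
    are doubly trimmed (``trim_m`` on M, ``trim_a`` on A) and averaged
    with inverse-asymptotic-variance weights; the factor is 2 to that
    mean.  Factors are rescaled to geometric mean 1.
    """
    lib = _as_lib_sizes(counts, library_sizes)
    y = counts.to_numpy(dtype=float)
    n_samples = y.shape[1]
    if n_samples == 1:
        return pd.Series([1.0], index=counts.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        q75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _tmm_pair(yk, nk, yr, nr, trim_m, trim_a) -> float:
    use = (yk > 0) & (yr > 0)
    yk, yr = yk[use], yr[use]
    if yk.size == 0:
        return 1.0
    pk, pr = yk / nk, yr / nr
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    w = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    if np.max(np.abs(m)) < 1e-10:  # identical composition: factor exactly 1
        return 1.0
    n = m.size
    # rank-based double trimming
    rank_m = m.argsort().argsort()
    rank_a = a.argsort().argsort()
    lo_m, hi_m = math.floor(n * trim_m), n - math.floor(n * trim_m) - 1
    lo_a, hi_a = math.floor(n * trim_a), n - math.floor(n * trim_a) - 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    wsum = w[keep].sum()
    if wsum <= 0:
        return float(2 ** np.mean(m[keep]))
    return float(2 ** (np.sum(w[keep] * m[keep]) / wsum))


# -- qCML dispersion -----------------------------------------------------


def _equalize_library_sizes(
    counts: np.ndarray,
    lib: np.ndarray,
    group_idx: list[np.ndarray],
    phi: float,
) -> tuple[np.ndarray, float]:
    """Quantile-adjust counts to the geometric-mean library size.

    Each count's NB (or Poisson, phi = 0) mid-p quantile under its own
    library size is mapped to the common size; with equal library sizes
    the adjustment is the identity.
    """
    target = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.array(counts, dtype=float)
    for idx in group_idx:
        sub = counts[:, idx]
        pi = sub.sum(axis=1) / lib[idx].sum()  # per-feature group proportion
        for j in idx:
            mu_in = pi * lib[j]
            mu_out = pi * target
            pseudo[:, j] = _quantile_map(counts[:, j], mu_in, mu_out, phi)
    return pseudo, target


def _quantile_map(y, mu_in, mu_out, phi) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    out = np.zeros_like(y)
    ok = mu_in > 0
    if not ok.any():
        return out
    yi, mi, mo = y[ok], mu_in[ok], mu_out[ok]
    if phi < 1e-12:
        q = poisson.cdf(yi, mi) - 0.5 * poisson.pmf(yi, mi)
        mapped = poisson.ppf(np.clip(q, 1e-300, 1.0), mo)
    else:
        r = 1.0 / phi
        q = nbinom.cdf(yi, r, r / (r + mi)) - 0.5 * nbinom.pmf(yi, r, r / (r + mi))
        mapped = nbinom.ppf(np.clip(q, 1e-300, 1.0), r, r / (r + mo))
    # far in the upper tail the cdf saturates at 1.0 in floats and ppf
    # degenerates; fall back to plain mean-ratio scaling there
    bad = ~np.isfinite(mapped) | (q >= 1.0)
    if bad.any():
        mapped = np.where(bad, yi * mo / mi, mapped)
    out[ok] = mapped
    return out


def _cond_loglik_per_feature(
    pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float
) -> np.ndarray:
    """Per-feature NB log-likelihood conditional on group sums, summed over
    groups with >= 2 replicates (equal library sizes assumed)."""
    phi = max(phi, _PHI_MIN)
    r = 1.0 / phi
    total = np.zeros(pseudo.shape[0])
    for idx in group_idx:
        n = len(idx)
        if n < 2:
            continue
        y = pseudo[:, idx]
        z = y.sum(axis=1)
        total += (
            gammaln(y + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
    return total


def _maximize_phi(objective) -> float:
    """Grid search on log-spaced phi then bounded refinement."""
    grid = np.logspace(np.log10(_PHI_MIN), np.log10(_PHI_MAX), 31)
    vals = np.array([objective(p) for p in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:
        return float(grid[i])
    res = minimize_scalar(
        lambda lp: -objective(10.0**lp),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best = 10.0**res.x
    return float(best if objective(best) >= vals[i] else grid[i])


def estimate_dispersion_qcml(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    library_sizes: pd.Series | None = None,
    tagwise: bool = False,
    prior_df: float = 10.0,
) -> DispersionEstimate:
    """qCML estimate of the NB dispersion phi.

    Counts are quantile-adjusted to a common (geometric-mean) library
    size, and the common phi maximizes the summed conditional
    log-likelihood (grid on [1e-6, 10], then bounded refinement); the
    adjustment and estimate are iterated once.  Tagwise values maximize
    the per-feature conditional likelihood plus ``prior_df`` times the
    mean per-feature likelihood, shrinking noisy features toward the
    common value.
    """
    samples = list(counts.columns)
    _, group_idx = _levels_and_indices(samples, groups)
    if max(len(i) for i in group_idx) < 2:
        raise ValueError("dispersion is unidentifiable without >= 2 replicates in some group")
    lib = _as_lib_sizes(counts, library_sizes)
    y = counts.to_numpy(dtype=float)
    phi = 0.0
    for _ in range(2):
        pseudo, _ = _equalize_library_sizes(y, lib, group_idx, phi)
        phi = _maximize_phi(
            lambda p: _cond_loglik_per_feature(pseudo, group_idx, p).sum()
        )
    tagwise_phi = None
    if tagwise:
        shared = lambda p: _cond_loglik_per_feature(pseudo, group_idx, p).mean()
        values = []
        for g in range(y.shape[0]):
            row = pseudo[g : g + 1]
            obj = lambda p: float(
                _cond_loglik_per_feature(row, group_idx, p)[0] + prior_df * shared(p)
            )
            values.append(_maximize_phi(obj))
        tagwise_phi = pd.Series(values, index=counts.index)
    return DispersionEstimate(common_phi=phi, tagwise_phi=tagwise_phi, prior_df=prior_df)


# -- NB exact test -------------------------------------------------------


def _exact_nb_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Conditional two-sided exact p: total probability of all splits of
    z1 + z2 between the two groups that are no more likely than the
    observed one, under the NB convolution with dispersion ``phi``."""
    total = z1 + z2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    a = np.arange(total + 1)
    if phi < 1e-12:
        lp = poisson.logpmf(a, n1 * mu) + poisson.logpmf(total - a, n2 * mu)
    else:
        r1, r2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        lp = nbinom.logpmf(a, r1, r1 / (r1 + m1)) + nbinom.logpmf(
            total - a, r2, r2 / (r2 + m2)
        )
    obs = lp[z1]
    keep = lp <= obs + 1e-8  # relative tolerance to catch symmetric ties
    p = float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))
    return min(p, 1.0)


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    dispersion: DispersionEstimate | float,
    library_sizes: pd.Series | None = None,
    pseudo_count: float = 0.125,
) -> pd.DataFrame:
    """Per-feature NB exact test of the two-group contrast.

    Counts are quantile-adjusted to a common library size, summed within
    groups, and the conditional two-sided exact p-value computed under
    NB(phi) (tagwise phi when available).  The log2 fold change is taken
    from normalized group means with a ``pseudo_count`` offset, second
    group level versus first.  Returns a DataFrame with columns
    ``log2_fold_change`` and ``p_value`` (FDR is a separate step:
    :func:`bh_adjust`).
    """
    samples = list(counts.columns)
    levels, group_idx = _levels_and_indices(samples, groups)
    if len(levels) != 2:
        raise ValueError(f"exact test needs exactly 2 group levels, got {levels}")
    if isinstance(dispersion, DispersionEstimate):
        common = dispersion.common_phi
        tag = dispersion.tagwise_phi
    else:
        common, tag = float(dispersion), None
    lib = _as_lib_sizes(counts, library_sizes)
    y = counts.to_numpy(dtype=float)
    pseudo, _ = _equalize_library_sizes(y, lib, group_idx, common)
    n1, n2 = len(group_idx[0]), len(group_idx[1])
    z1 = np.rint(pseudo[:, group_idx[0]].sum(axis=1)).astype(int)
    z2 = np.rint(pseudo[:, group_idx[1]].sum(axis=1)).astype(int)
    pvals = np.empty(y.shape[0])
    for g in range(y.shape[0]):
        phi_g = float(tag.iloc[g]) if tag is not None else common
        pvals[g] = _exact_nb_pvalue(int(z1[g]), int(z2[g]), n1, n2, phi_g)
    log2fc = np.log2((z2 / n2 + pseudo_count) / (z1 / n1 + pseudo_count))
    return pd.DataFrame(
        {"log2_fold_change": log2fc, "p_value": pvals}, index=counts.index
    )


# -- quasi-Poisson GLM ---------------------------------------------------


def quasi_poisson_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    offsets: pd.Series | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Quasi-Poisson log-link GLM per feature: intercept + treatment.

    ``offsets`` are per-sample log exposures (e.g. log(model kb x genome
    equivalents)) so the treatment coefficient acts on the RPKG scale.
    The dispersion is the Pearson X^2 / (n - 2); the two-sided p comes
    from a t-statistic on the treatment coefficient with n - 2 degrees of
    freedom.  Non-convergence after ``max_iter`` IRLS steps yields
    ``p_value = NaN`` with ``converged = False``.
    """
    samples = list(counts.columns)
    levels, group_idx = _levels_and_indices(samples, groups)
    if len(levels) != 2:
        raise ValueError(f"quasi-Poisson test needs exactly 2 group levels, got {levels}")
    if offsets is None:
        off = np.zeros(len(samples))
    else:
        off = offsets.reindex(samples).astype(float).to_numpy()
    t_ind = np.zeros(len(samples))
    t_ind[group_idx[1]] = 1.0
    X = np.column_stack([np.ones(len(samples)), t_ind])
    n, k = X.shape
    rows = []
    for fid in counts.index:
        y = counts.loc[fid].to_numpy(dtype=float)
        rows.append(_qp_fit_one(y, X, off, n, k, max_iter, tol))
    return pd.DataFrame(rows, index=counts.index)


def _qp_fit_one(y, X, off, n, k, max_iter, tol) -> dict:
    if y.sum() == 0:
        return {
            "log2_fold_change": 0.0, "p_value": 1.0, "t_statistic": 0.0,
            "dispersion": 0.0, "converged": True,
        }
    beta = np.array([math.log(y.mean() + 0.5) - np.mean(off), 0.0])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = np.exp(np.clip(eta, -700, 700))
        W = mu
        z = (eta - off) + (y - mu) / mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    eta = X @ beta + off
    mu = np.exp(np.clip(eta, -700, 700))
    if not converged:
        return {
            "log2_fold_change": beta[1] / math.log(2), "p_value": float("nan"),
            "t_statistic": float("nan"), "dispersion": float("nan"),
            "converged": False,
        }
    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - k)
    cov = np.linalg.inv((X.T * mu) @ X)
    se = math.sqrt(max(dispersion, 1e-300) * cov[1, 1])
    if se == 0:
        tstat, p = 0.0, 1.0
    else:
        tstat = beta[1] / se
        p = float(2 * t_dist.sf(abs(tstat), n - k))
    return {
        "log2_fold_change": beta[1] / math.log(2), "p_value": p,
        "t_statistic": tstat, "dispersion": dispersion, "converged": True,
    }


# -- multiple testing ----------------------------------------------------


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


# -- community-level statistics ------------------------------------------


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distances between samples, on relative abundances.

    ``d(u, v) = sum |u - v| / sum (u + v)`` with columns first scaled to
    sum 1; d(u, u) = 0 and d in [0, 1].
    """
    y = counts.to_numpy(dtype=float)
    colsum = y.sum(axis=0)
    rel = np.divide(y, colsum, out=np.zeros_like(y), where=colsum > 0)
    n = rel.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (rel[:, i] + rel[:, j]).sum()
            if denom > 0:
                d[i, j] = d[j, i] = np.abs(rel[:, i] - rel[:, j]).sum() / denom
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _permanova_f(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    n = d2.shape[0]
    g = len(group_idx)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for idx in group_idx:
        sub = d2[np.ix_(idx, idx)]
        iu_g = np.triu_indices(len(idx), k=1)
        ss_within += sub[iu_g].sum() / len(idx)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return math.inf if ss_between > 1e-12 else 0.0
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _multiset_permutations(items: list):
    counts = Counter(items)
    keys = sorted(counts)
    n = len(items)
    perm: list = []

    def rec():
        if len(perm) == n:
            yield tuple(perm)
            return
        for key in keys:
            if counts[key] > 0:
                counts[key] -= 1
                perm.append(key)
                yield from rec()
                perm.pop()
                counts[key] += 1

    yield from rec()


def _group_indices_from_labels(labels: Sequence) -> list[np.ndarray]:
    levels = list(dict.fromkeys(labels))
    return [np.array([i for i, l in enumerate(labels) if l == lev]) for lev in levels]


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 9999,
    exhaustive_limit: int = 10000,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F contrasts between- and within-group sums of squared
    distances.  When the number of distinct relabelings is at most
    ``exhaustive_limit`` they are all enumerated and the p-value is the
    exact fraction with F >= F_observed (the observed labeling is among
    them); otherwise ``n_perm`` random relabelings are drawn and
    ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
    """
    labels = list(groups)
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != len(labels):
        raise ValueError("distance matrix and group labels disagree in size")
    level_counts = Counter(labels)
    if any(c < 2 for c in level_counts.values()):
        raise ValueError("every group needs at least 2 samples")
    d2 = d**2
    f_obs = _permanova_f(d2, _group_indices_from_labels(labels))
    n_distinct = math.factorial(len(labels))
    for c in level_counts.values():
        n_distinct //= math.factorial(c)
    if n_distinct <= exhaustive_limit:
        count = 0
        for relab in _multiset_permutations(labels):
            f = _permanova_f(d2, _group_indices_from_labels(relab))
            if f >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(f_obs, count / n_distinct, n_distinct, True)
    rng = np.random.default_rng(seed)
    arr = np.array(labels, dtype=object)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(arr)
        if _permanova_f(d2, _group_indices_from_labels(perm)) >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(f_obs, (count + 1) / (n_perm + 1), n_perm, False)


@dataclass
class BetadisperResult:
    f_statistic: float
    p_value: float


def _anova_f(z: np.ndarray, group_idx: list[np.ndarray]) -> float:
    n = z.size
    g = len(group_idx)
    grand = z.mean()
    ssb = sum(len(i) * (z[i].mean() - grand) ** 2 for i in group_idx)
    ssw = sum(((z[i] - z[i].mean()) ** 2).sum() for i in group_idx)
    scale = max(float((z**2).sum()), 1e-300)
    if ssb + ssw <= 1e-12 * scale:  # all distances equal: no dispersion signal
        return 0.0
    if ssw <= 1e-300:
        return math.inf
    return (ssb / (g - 1)) / (ssw / (n - g))


def dispersion_homogeneity(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
) -> BetadisperResult:
    """Test homogeneity of multivariate dispersion (betadisper-style).

    Samples are embedded by principal-coordinate analysis (negative
    eigenvalues truncated at zero); each sample's distance to its own
    group centroid is computed, and a permutation F-test compares those
    distances between groups.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    labels = list(groups)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    gmat = j @ a @ j
    w, v = np.linalg.eigh((gmat + gmat.T) / 2)
    w = np.clip(w, 0.0, None)
    coords = v * np.sqrt(w)
    group_idx = _group_indices_from_labels(labels)
    z = np.empty(n)
    for idx in group_idx:
        centroid = coords[idx].mean(axis=0)
        z[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    f_obs = _anova_f(z, group_idx)
    rng = np.random.default_rng(seed)
    arr = np.array(labels, dtype=object)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(arr)
        if _anova_f(z, _group_indices_from_labels(perm)) >= f_obs - 1e-12:
            count += 1
    return BetadisperResult(f_obs, (count + 1) / (n_perm + 1))


# -- convenience pipeline step -------------------------------------------


def differential_abundance(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    library_sizes: pd.Series | None = None,
    min_cpm: float = 4.0,
    min_samples: int = 4,
    tagwise: bool = False,
    prior_df: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Filter, TMM-normalize, estimate dispersion, exact-test and BH-adjust.

    Effective library sizes (library size x TMM factor) act as the
    normalization offsets throughout.  Returns one row per kept feature
    with ``log2_fold_change``, ``p_value``, ``fdr`` and ``significant``.
    """
    lib = pd.Series(_as_lib_sizes(counts, library_sizes), index=counts.columns)
    kept, _ = cpm_filter(counts, lib, min_cpm=min_cpm, min_samples=min_samples)
    if kept.empty:
        return pd.DataFrame(
            columns=["log2_fold_change", "p_value", "fdr", "significant"]
        )
    factors = tmm_factors(kept, lib)
    eff_lib = lib * factors
    disp = estimate_dispersion_qcml(
        kept, groups, library_sizes=eff_lib, tagwise=tagwise, prior_df=prior_df
    )
    res = nb_exact_test(kept, groups, disp, library_sizes=eff_lib)
    res["fdr"] = bh_adjust(res["p_value"])
    res["significant"] = res["fdr"] < alpha
    return res
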