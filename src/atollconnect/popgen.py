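"""Per-individual and per-population genetic statistics.

Implements the multilocus Weir & Cockerham (1984) theta estimator of F_ST
with a percentile bootstrap over loci, the unadjusted Yang et al. genomic
relationship statistic (Ajk), observed/expected heterozygosity and F_IS with
an allele-permutation significance test, a method-of-moments individual
inbreeding coefficient with bootstrap CIs, Kruskal-Wallis/Dunn group
comparisons of heterozygosity, and a reduced Bayesian F_ST-outlier scan in
the Beaumont-Balding logistic decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PairwiseFstResult",
    "PopDiversity",
    "OutlierScanResult",
    "relative_heterozygosity",
    "pop_diversity",
    "pairwise_fst",
    "relatedness_ajk",
    "individual_inbreeding",
    "group_heterozygosity_test",
    "outlier_scan",
]

SIGNIFICANCE_FLOOR = 0.001  # lower-CI threshold for "significant" differentiation


# ----------------------------------------------------------------------
# per-locus summaries
# ----------------------------------------------------------------------

def _pop_locus_summaries(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) per locus for one population's genotype block."""
    present = g != MISSING
    n = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(present, g, 0).sum(axis=0) / (2.0 * n), np.nan)
        h = np.where(n > 0, (present & (g == 1)).sum(axis=0) / n, np.nan)
    return n, p, h


def weir_cockerham_components(
    blocks: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for r populations.

    Returns ``(a, b, c, valid)`` arrays over loci; ``valid`` marks loci where
    the components are defined (every population has data, mean sample size
    above 1, and a positive n_c).
    """
    r = len(blocks)
    if r < 2:
        raise ValueError("need at least two populations")
    summ = [_pop_locus_summaries(g) for g in blocks]
    n = np.stack([s[0] for s in summ])  # (r, L)
    p = np.stack([s[1] for s in summ])
    h = np.stack([s[2] for s in summ])

    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    valid = (n >= 1).all(axis=0) & (nbar > 1) & (nc > 0)
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


@dataclass
class PairwiseFstResult:
    pop_a: str
    pop_b: str
    fst: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool
    n_loci_used: int = 0


def _theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    denom = (a + b + c).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


def pairwise_fst(
    matrix: GenotypeMatrix,
    grouping: str | np.ndarray = "deme",
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PairwiseFstResult]:
    """Multilocus WC84 theta for every population pair with bootstrap CIs.

    Theta is the ratio of summed among-population components to summed total
    components over loci; the CI is a percentile bootstrap resampling loci
    with replacement.  A pair is flagged significantly differentiated when
    the lower CI bound does not cross :data:`SIGNIFICANCE_FLOOR` (0.001).
    """
    rng = np.random.default_rng(seed)
    if isinstance(grouping, str):
        groups = matrix.groups(by=grouping)
    else:
        labels = np.asarray(grouping, dtype=str)
        groups = {l: np.flatnonzero(labels == l) for l in pd.unique(labels)}
    names = list(groups)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ga = matrix.genotypes[groups[names[i]]]
            gb = matrix.genotypes[groups[names[j]]]
            if min(len(ga), len(gb)) < 2:
                raise ValueError("each group needs n >= 2")
            a, b, c, valid = weir_cockerham_components([ga, gb])
            a, b, c = a[valid], b[valid], c[valid]
            L = a.size
            if L < 2:
                raise ValueError("need >= 2 usable loci")
            theta = _theta_from_components(a, b, c)
            tot = a + b + c
            boots = np.empty(n_boot)
            chunk = max(1, int(2e6 // L))
            for start in range(0, n_boot, chunk):
                m = min(chunk, n_boot - start)
                idx = rng.integers(0, L, size=(m, L))
                num = a[idx].sum(axis=1)
                den = tot[idx].sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    boots[start : start + m] = np.where(den != 0, num / den, np.nan)
            lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            results.append(
                PairwiseFstResult(
                    pop_a=names[i],
                    pop_b=names[j],
                    fst=theta,
                    ci_low=float(lo),
                    ci_high=float(hi),
                    n_boot=n_boot,
                    significant=bool(lo >= SIGNIFICANCE_FLOOR),
                    n_loci_used=L,
                )
            )
    return results


def fst_table(results: list[PairwiseFstResult]) -> pd.DataFrame:
    """Square table: point estimates in the lower triangle, CI text above."""
    names = sorted({r.pop_a for r in results} | {r.pop_b for r in results})
    tab = pd.DataFrame("", index=names, columns=names)
    for r in results:
        i, j = sorted([r.pop_a, r.pop_b])
        est = f"{max(r.fst, 0.0):.4f}" + ("*" if r.significant else "")
        tab.loc[j, i] = est
        tab.loc[i, j] = f"{max(r.ci_low, 0):.4f}-{max(r.ci_high, 0):.4f}"
    return tab


# ----------------------------------------------------------------------
# heterozygosity / diversity
# ----------------------------------------------------------------------

def relative_heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Heterozygous calls per individual over the matrix's polymorphic-locus count."""
    poly = matrix.polymorphic_mask()
    n_poly = int(poly.sum())
    if n_poly == 0:
        raise ValueError("no polymorphic loci in matrix")
    het = ((matrix.genotypes == 1) & poly[None, :]).sum(axis=1)
    return pd.Series(het / n_poly, index=matrix.individual_meta["id"].to_numpy())


@dataclass
class PopDiversity:
    pop: str
    n: int
    ho: float
    he: float
    fis: float
    fis_pvalue: float
    significant: bool


def _group_ho_he(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p, h = _pop_locus_summaries(g)
    with np.errstate(invalid="ignore"):
        he = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
    usable = (n >= 2) & np.isfinite(he) & (he > 0)
    return h, he, usable


def _permuted_fis(
    g: np.ndarray, he_mean: float, usable: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """F_IS under random re-pairing of alleles within each locus.

    Missing genotypes are first completed by frequency draws so that the
    allele pool can be permuted as a dense array (negligible at the
    missingness levels this package simulates; exact with imputed input).
    """
    g = g[:, usable].astype(np.int16)
    miss = g == MISSING
    if miss.any():
        n, p, _ = _pop_locus_summaries(g)
        fill = rng.binomial(2, np.broadcast_to(np.nan_to_num(p, nan=0.5), g.shape)[miss])
        g = g.copy()
        g[miss] = fill.astype(np.int16)
    n_ind, L = g.shape
    alleles = np.empty((2 * n_ind, L), dtype=np.int8)
    alleles[0::2] = g >= 1
    alleles[1::2] = g == 2
    out = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permuted(alleles, axis=0)
        het = perm[0::2] != perm[1::2]
        ho_mean = het.mean(axis=0).mean()
        out[k] = 1.0 - ho_mean / he_mean
    return out


def pop_diversity(
    matrix: GenotypeMatrix,
    grouping: str | np.ndarray = "deme",
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PopDiversity]:
    """Observed/expected heterozygosity and F_IS per group.

    He carries the 2n/(2n-1) small-sample correction; F_IS = 1 - Ho/He with
    means taken over loci polymorphic within the group.  The p-value is a
    two-sided permutation test shuffling alleles among the group's
    individuals within each locus.
    """
    rng = np.random.default_rng(seed)
    if isinstance(grouping, str):
        groups = matrix.groups(by=grouping)
    else:
        labels = np.asarray(grouping, dtype=str)
        groups = {l: np.flatnonzero(labels == l) for l in pd.unique(labels)}
    out = []
    for name, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {name} has n < 2")
        g = matrix.genotypes[idx]
        h, he, usable = _group_ho_he(g)
        if not usable.any():
            raise ValueError(f"group {name} is monomorphic at every locus")
        ho_mean = float(np.nanmean(h[usable]))
        he_mean = float(np.nanmean(he[usable]))
        fis = 1.0 - ho_mean / he_mean
        null = _permuted_fis(g, he_mean, usable, n_perm, rng)
        ge = int((null >= fis).sum())
        le = int((null <= fis).sum())
        p = min(1.0, 2.0 * (min(ge, le) + 1) / (n_perm + 1))
        out.append(
            PopDiversity(
                pop=str(name),
                n=len(idx),
                ho=ho_mean,
                he=he_mean,
                fis=fis,
                fis_pvalue=p,
                significant=bool(p < alpha),
            )
        )
    return out


# ----------------------------------------------------------------------
# relatedness (Yang et al. unadjusted Ajk)
# ----------------------------------------------------------------------

def relatedness_ajk(
    matrix: GenotypeMatrix, freq_source: GenotypeMatrix | np.ndarray | None = None
) -> pd.DataFrame:
    """Unadjusted Yang et al. genomic relationship matrix.

    Off-diagonal ``A_jk = mean_i (x_j - 2p)(x_k - 2p) / (2p(1-p))`` and
    diagonal ``A_jj = 1 + mean_i (x_j^2 - (1+2p)x_j + 2p^2) / (2p(1-p))``
    with ``x`` the alternate-allele count and ``p`` taken from
    ``freq_source`` (default: the matrix itself).  Loci fixed in the
    frequency reference are excluded; missing genotypes are excluded
    pairwise.  Expected near 0 for unrelated pairs and near 1 on the
    diagonal.
    """
    if freq_source is None:
        p = matrix.allele_frequencies()
    elif isinstance(freq_source, GenotypeMatrix):
        p = freq_source.allele_frequencies()
    else:
        p = np.asarray(freq_source, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no usable loci (all fixed or missing)")
    p = p[usable]
    x = matrix.genotypes[:, usable].astype(float)
    present = x != MISSING
    x = np.where(present, x, 0.0)
    denom = 2 * p * (1 - p)

    w = np.where(present, (x - 2 * p) / np.sqrt(denom), 0.0)
    m = present.astype(float)
    pair_counts = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ajk = (w @ w.T) / pair_counts

    diag_terms = np.where(present, (x**2 - (1 + 2 * p) * x + 2 * p**2) / denom, 0.0)
    counts = present.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = 1.0 + diag_terms.sum(axis=1) / counts
    np.fill_diagonal(ajk, diag)
    ids = matrix.individual_meta["id"].to_numpy()
    return pd.DataFrame(ajk, index=ids, columns=ids)


def mean_offdiagonal(ajk: pd.DataFrame) -> float:
    a = ajk.to_numpy()
    n = a.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.nanmean(a[mask]))


# ----------------------------------------------------------------------
# individual inbreeding
# ----------------------------------------------------------------------

def individual_inbreeding(
    matrix: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    freq_source: GenotypeMatrix | np.ndarray | None = None,
) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per individual with 95% CIs.

    ``F_hat = 1 - observed het count / sum 2p(1-p)`` over used (polymorphic,
    non-missing) loci; the CI is a percentile bootstrap over loci (default
    1000 draws).
    """
    import warnings as _w

    if freq_source is None:
        p = matrix.allele_frequencies()
    elif isinstance(freq_source, GenotypeMatrix):
        p = freq_source.allele_frequencies()
    else:
        p = np.asarray(freq_source, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    L = int(usable.sum())
    if L == 0:
        raise ValueError("no usable loci")
    if L < 50:
        _w.warn(f"only {L} usable loci; inbreeding estimates will be noisy")
    p = p[usable]
    g = matrix.genotypes[:, usable]
    present = g != MISSING
    het = (g == 1) & present
    e_locus = 2 * p * (1 - p)

    def _fhat(h: np.ndarray, pres: np.ndarray) -> np.ndarray:
        e = (pres * e_locus).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 1.0 - h.sum(axis=1) / e

    rng = np.random.default_rng(seed)
    fhat = _fhat(het, present)
    boots = np.empty((n_boot, matrix.n_individuals))
    for b in range(n_boot):
        idx = rng.integers(0, L, size=L)
        boots[b] = _fhat(het[:, idx], present[:, idx])
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "id": matrix.individual_meta["id"].to_numpy(),
            "fhat": fhat,
            "ci_low": lo,
            "ci_high": hi,
        }
    )


# ----------------------------------------------------------------------
# Kruskal-Wallis + Dunn post hoc
# ----------------------------------------------------------------------

def group_heterozygosity_test(
    values: np.ndarray | pd.Series,
    grouping: np.ndarray | pd.Series,
    adjust: str = "fdr_bh",
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus test with Dunn pairwise post-hoc z statistics.

    Returns ``(omnibus_p, posthoc)`` where the post-hoc table has columns
    ``group_a, group_b, z, p, p_adj`` (Benjamini-Hochberg by default).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(grouping, dtype=str)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[labels == g] for g in names]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if np.all(values == values[0]):
        return 1.0, pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_adj"])
    _, omnibus_p = stats.kruskal(*samples)

    # Dunn z statistics with tie correction
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {g: ranks[labels == g].mean() for g in names}
    ns = {g: (labels == g).sum() for g in names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / ns[a] + 1.0 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z, "p": 2 * stats.norm.sf(abs(z))})
    posthoc = pd.DataFrame(rows)
    posthoc["p_adj"] = multipletests(posthoc["p"], method=adjust)[1]
    return float(omnibus_p), posthoc


# ----------------------------------------------------------------------
# F_ST outlier scan (reduced Beaumont-Balding decomposition)
# ----------------------------------------------------------------------

@dataclass
class OutlierScanResult:
    alpha: np.ndarray  # posterior mean locus effect (log-odds scale)
    beta: np.ndarray  # posterior mean population effect
    posterior_inclusion: np.ndarray
    flagged: np.ndarray
    threshold: float
    converged: bool
    notes: list[str] = field(default_factory=list)

    def neutral_loci(self) -> np.ndarray:
        return np.flatnonzero(~self.flagged)


def _beta_binom_loglik(
    y: np.ndarray, n: np.ndarray, p: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """Log beta-binomial likelihood (constants dropped), elementwise (L, J)."""
    theta = (1.0 - f) / f
    a = theta * p
    b = theta * (1.0 - p)
    return (
        gammaln(y + a)
        + gammaln(n - y + b)
        - gammaln(n + a + b)
        - gammaln(a)
        - gammaln(b)
        + gammaln(a + b)
    )


def outlier_scan(
    matrix: GenotypeMatrix,
    grouping: str | np.ndarray = "deme",
    prior_odds: float = 10000.0,
    n_burn: int = 5000,
    n_iter: int = 10000,
    thin: int = 10,
    seed: int = 0,
    inclusion_threshold: float = 0.76,
) -> OutlierScanResult:
    """Reversible-jump scan for loci with atypical differentiation.

    The locus/population F_ST decomposition ``logit(F_ij) = alpha_i + beta_j``
    is fit by MCMC with a beta-binomial likelihood on alternate-allele
    counts.  The locus effect ``alpha_i`` is included or excluded by a
    reversible-jump move with prior odds ``prior_odds`` for the neutral
    (excluded) model; loci are flagged when their posterior inclusion
    probability reaches ``inclusion_threshold``.  This is a reduced
    desk-scale reimplementation, not a parity port of any released scanner.
    """
    rng = np.random.default_rng(seed)
    if isinstance(grouping, str):
        groups = matrix.groups(by=grouping)
    else:
        labels = np.asarray(grouping, dtype=str)
        groups = {l: np.flatnonzero(labels == l) for l in pd.unique(labels)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")

    blocks = [matrix.genotypes[idx] for idx in groups.values()]
    y = np.stack(
        [np.where(g != MISSING, g, 0).sum(axis=0) for g in blocks], axis=1
    ).astype(float)
    n = np.stack([2.0 * (g != MISSING).sum(axis=0) for g in blocks], axis=1)
    L, J = y.shape

    # initial state
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.clip(y.sum(axis=1) / np.maximum(n.sum(axis=1), 1), 0.02, 0.98)
    alpha = np.zeros(L)
    included = np.zeros(L, dtype=bool)
    beta = np.full(J, -2.0)

    sd_alpha_prior, mu_beta_prior, sd_beta_prior = 1.0, -2.0, 1.8

    def _fmat(al: np.ndarray, be: np.ndarray) -> np.ndarray:
        return np.clip(expit(al[:, None] + be[None, :]), 1e-6, 1 - 1e-6)

    def _ll_rows(pp: np.ndarray, al: np.ndarray, be: np.ndarray) -> np.ndarray:
        return _beta_binom_loglik(y, n, pp[:, None], _fmat(al, be)).sum(axis=1)

    ll = _ll_rows(p, alpha, beta)
    incl_sum = np.zeros(L)
    incl_sum_first = np.zeros(L)
    alpha_sum = np.zeros(L)
    beta_sum = np.zeros(J)
    n_kept = 0
    n_kept_first = 0

    total = n_burn + n_iter
    for it in range(total):
        # p update (logit random walk, uniform prior -> Jacobian term)
        logit_p = np.log(p / (1 - p))
        prop = expit(logit_p + rng.normal(0, 0.3, size=L))
        prop = np.clip(prop, 1e-4, 1 - 1e-4)
        ll_prop = _ll_rows(prop, alpha, beta)
        log_acc = (
            ll_prop
            - ll
            + np.log(prop * (1 - prop))
            - np.log(p * (1 - p))
        )
        acc = np.log(rng.random(L)) < log_acc
        p[acc] = prop[acc]
        ll[acc] = ll_prop[acc]

        # alpha update for included loci
        if included.any():
            prop_a = alpha + rng.normal(0, 0.4, size=L)
            ll_prop = _ll_rows(p, np.where(included, prop_a, alpha), beta)
            log_acc = (
                ll_prop
                - ll
                - 0.5 * (prop_a / sd_alpha_prior) ** 2
                + 0.5 * (alpha / sd_alpha_prior) ** 2
            )
            acc = included & (np.log(rng.random(L)) < log_acc)
            alpha[acc] = prop_a[acc]
            ll[acc] = ll_prop[acc]

        # reversible jump: toggle inclusion, independent proposal from prior
        prop_a = rng.normal(0, sd_alpha_prior, size=L)
        new_alpha = np.where(included, 0.0, prop_a)
        ll_prop = _ll_rows(p, new_alpha, beta)
        log_acc = np.where(
            included,
            ll_prop - ll + np.log(prior_odds),
            ll_prop - ll - np.log(prior_odds),
        )
        acc = np.log(rng.random(L)) < log_acc
        alpha[acc] = new_alpha[acc]
        included[acc] = ~included[acc]
        ll[acc] = ll_prop[acc]

        # beta updates, one population at a time
        for j in range(J):
            bj = beta[j] + rng.normal(0, 0.2)
            f_old = np.clip(expit(alpha + beta[j]), 1e-6, 1 - 1e-6)
            f_new = np.clip(expit(alpha + bj), 1e-6, 1 - 1e-6)
            ll_old = _beta_binom_loglik(y[:, j], n[:, j], p, f_old).sum()
            ll_new = _beta_binom_loglik(y[:, j], n[:, j], p, f_new).sum()
            log_acc = (
                ll_new
                - ll_old
                - 0.5 * ((bj - mu_beta_prior) / sd_beta_prior) ** 2
                + 0.5 * ((beta[j] - mu_beta_prior) / sd_beta_prior) ** 2
            )
            if np.log(rng.random()) < log_acc:
                beta[j] = bj
        ll = _ll_rows(p, alpha, beta)

        if it >= n_burn and (it - n_burn) % thin == 0:
            incl_sum += included
            alpha_sum += np.where(included, alpha, 0.0)
            beta_sum += beta
            n_kept += 1
            if it - n_burn < n_iter // 2:
                incl_sum_first += included
                n_kept_first += 1

    inclusion = incl_sum / max(n_kept, 1)
    notes = []
    converged = True
    if n_kept_first and n_kept > n_kept_first:
        first = incl_sum_first / n_kept_first
        second = (incl_sum - incl_sum_first) / (n_kept - n_kept_first)
        if np.max(np.abs(first - second)) > 0.3:
            converged = False
            notes.append("split-chain inclusion probabilities disagree (> 0.3)")
    flagged = inclusion >= inclusion_threshold
    return OutlierScanResult(
        alpha=alpha_sum / max(n_kept, 1),
        beta=beta_sum / max(n_kept, 1),
        posterior_inclusion=inclusion,
        flagged=flagged,
        threshold=inclusion_threshold,
        converged=converged,
        notes=notes,
    )
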