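"""The lambda_meta statistic: pairwise detection of sample overlap and
heterogeneity from summary statistics.

For a SNP i reported by two cohorts with harmonised effects b1, b2 and
standard errors s1, s2, the statistic

    T_i = (b1 - b2)^2 / (s1^2 + s2^2)

follows a chi-square(1) distribution when the cohorts are independent and
estimate the same effects.  lambda_meta is the median of the T values over
~30 000 markers in linkage equilibrium divided by the chi-square(1) median
(0.4549...).  Overlapping samples correlate the two effect estimates and
deflate lambda_meta below 1; heterogeneity of true effects inflates it above
1.  For quantitative traits the deflation can be inverted into an estimate
of the summary-statistic correlation gamma and of the effective number of
overlapping individuals n_o:

    E[lambda] = 1 - gamma * 2 sqrt(n1 n2) / (n1 + n2),   gamma = n_o / sqrt(n1 n2)

A frequency-based variant replaces effect differences by allele-frequency
differences with their binomial sampling variances.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import AlignedPair, CohortSummary, harmonize_pair, prune_independent

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class LambdaResult:
    """lambda_meta for one cohort pair plus its test against 1 and the
    derived overlap quantities."""

    cohort1_id: str
    cohort2_id: str
    lambda_meta: float
    m_snps: int
    theoretical_se: float
    z_vs_1: float
    p_vs_1: float
    gamma_hat: float
    n_o_hat: float  # NaN when lambda >= 1 (no overlap implied)
    mode: str = "effect_size"
    gc_adjusted_input: bool = False


@dataclass
class PairwiseScanResult:
    """All-pairs lambda_meta scan: symmetric matrix and long-format table."""

    matrix: pd.DataFrame
    pairs: pd.DataFrame
    mode: str
    target_m: int
    n_flagged_bonferroni: int


def t_stats(beta1, se1, beta2, se2) -> np.ndarray:
    """Per-SNP T = (b1 - b2)^2 / (se1^2 + se2^2) on harmonised arrays."""
    beta1, se1, beta2, se2 = map(lambda a: np.asarray(a, float), (beta1, se1, beta2, se2))
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    return (beta1 - beta2) ** 2 / (se1**2 + se2**2)


def compute_lambda(t: np.ndarray) -> float:
    """median(T) / median(chi-square 1 df)."""
    t = np.asarray(t, float)
    if t.size == 0:
        raise ValueError("empty T vector")
    return float(np.median(t) / CHI2_1_MEDIAN)


def lambda_gc(chi2: np.ndarray) -> float:
    """Genomic-control inflation factor: median association chi-square over
    the chi-square(1) median."""
    chi2 = np.asarray(chi2, float)
    if np.any(chi2 < 0):
        raise ValueError("chi-square statistics must be non-negative")
    return compute_lambda(chi2)


def lambda_af(freq1, n1, freq2, n2) -> tuple[float, int]:
    """Frequency-mode lambda_meta.

    T_i = (p1 - p2)^2 / (p1(1-p1)/(2 n1) + p2(1-p2)/(2 n2)) with diploid
    sample sizes.  Markers monomorphic in both cohorts carry no information
    and are excluded; returns (lambda, number of excluded SNPs).
    """
    p1, p2 = np.asarray(freq1, float), np.asarray(freq2, float)
    n1 = np.broadcast_to(np.asarray(n1, float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, float), p2.shape)
    var = p1 * (1 - p1) / (2 * n1) + p2 * (1 - p2) / (2 * n2)
    ok = var > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all SNPs monomorphic in both cohorts")
    t = (p1[ok] - p2[ok]) ** 2 / var[ok]
    return compute_lambda(t), n_excluded


def lambda_theoretical_se(m: int) -> float:
    """Asymptotic SE of lambda_meta from m independent null T values.

    The sample median of m iid draws has asymptotic variance
    1 / (4 m f(q)^2) with f the chi-square(1) density at its median q;
    dividing by the median rescales to the lambda scale.  At m = 30 000 this
    gives ~0.0135.
    """
    q = CHI2_1_MEDIAN
    f = stats.chi2.pdf(q, df=1)
    return float(np.sqrt(1.0 / (4.0 * m * f**2)) / q)


def gamma_from_lambda(lam: float, n1: float, n2: float) -> tuple[float, float]:
    """Invert lambda_meta into (gamma_hat, n_o_hat).

    Under pure sample overlap the reported effects have correlation
    gamma = n_o / sqrt(n1 n2), so Var(b1 - b2) = s1^2 + s2^2 - 2 gamma s1 s2
    and, with sampling variance proportional to 1/n,
    E[lambda] = 1 - gamma 2 sqrt(n1 n2) / (n1 + n2).  Hence

        gamma_hat = (1 - lambda) (n1 + n2) / (2 sqrt(n1 n2))
        n_o_hat   = gamma_hat sqrt(n1 n2) = (1 - lambda)(n1 + n2)/2

    A negative gamma_hat (lambda > 1) signals heterogeneity rather than
    overlap; n_o_hat is then reported as NaN.
    """
    gamma = (1.0 - lam) * (n1 + n2) / (2.0 * np.sqrt(n1 * n2))
    n_o = gamma * np.sqrt(n1 * n2) if gamma >= 0 else float("nan")
    return float(gamma), float(n_o)


def pair_lambda(
    aligned: AlignedPair,
    mode: str = "effect_size",
    gc_adjusted_input: bool = False,
) -> LambdaResult:
    """lambda_meta with its z test against 1 for one harmonised pair."""
    if mode == "effect_size":
        ok = (
            np.isfinite(aligned.beta1)
            & np.isfinite(aligned.beta2)
            & (aligned.se1 > 0)
            & (aligned.se2 > 0)
        )
        t = t_stats(aligned.beta1[ok], aligned.se1[ok], aligned.beta2[ok], aligned.se2[ok])
        lam = compute_lambda(t)
        m = int(ok.sum())
    elif mode == "allele_frequency":
        ok = np.isfinite(aligned.freq1) & np.isfinite(aligned.freq2)
        lam, n_excl = lambda_af(
            aligned.freq1[ok], aligned.n1[ok], aligned.freq2[ok], aligned.n2[ok]
        )
        m = int(ok.sum()) - n_excl
    else:
        raise ValueError("mode must be 'effect_size' or 'allele_frequency'")
    se = lambda_theoretical_se(m)
    z = (lam - 1.0) / se
    p = 2.0 * stats.norm.sf(abs(z))
    n1 = float(np.median(aligned.n1))
    n2 = float(np.median(aligned.n2))
    gamma, n_o = gamma_from_lambda(lam, n1, n2)
    if gc_adjusted_input:
        logger.warning(
            "pair %s-%s: input SEs declared genomic-control adjusted; "
            "lambda_meta is deflated relative to unadjusted input",
            aligned.cohort1_id, aligned.cohort2_id,
        )
    return LambdaResult(
        cohort1_id=aligned.cohort1_id,
        cohort2_id=aligned.cohort2_id,
        lambda_meta=lam,
        m_snps=m,
        theoretical_se=se,
        z_vs_1=float(z),
        p_vs_1=float(p),
        gamma_hat=gamma,
        n_o_hat=n_o,
        mode=mode,
        gc_adjusted_input=gc_adjusted_input,
    )


def t_quantile_table(aligned: AlignedPair, n_quantiles: int = 200) -> pd.DataFrame:
    """Observed vs expected T quantiles for a QQ-style per-pair plot."""
    ok = (
        np.isfinite(aligned.beta1)
        & np.isfinite(aligned.beta2)
        & (aligned.se1 > 0)
        & (aligned.se2 > 0)
    )
    t = np.sort(t_stats(aligned.beta1[ok], aligned.se1[ok], aligned.beta2[ok], aligned.se2[ok]))
    probs = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    return pd.DataFrame(
        {
            "prob": probs,
            "expected_chi2_1": stats.chi2.ppf(probs, df=1),
            "observed_T": np.quantile(t, probs),
        }
    )


def pairwise_scan(
    cohorts: list[CohortSummary],
    mode: str = "effect_size",
    target_m: int = 30_000,
    min_gap_bp: int = 100_000,
    seed: int = 2016,
    min_shared: int = 100,
    drop_ambiguous: bool = True,
    gc_adjusted_input: bool = False,
) -> PairwiseScanResult:
    """lambda_meta for every unordered cohort pair.

    Each pair is harmonised, thinned to ``target_m`` well-spaced markers
    (seeded, so the scan is reproducible), and tested against 1 using both
    the theoretical SE and a z score standardised by the across-pair
    empirical mean and SD.  Flags use Bonferroni correction over the number
    of pairs.  Pairs sharing fewer than ``min_shared`` thinned markers are
    skipped with a warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    ids = [c.cohort_id for c in cohorts]
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    np.fill_diagonal(mat.values, np.nan)
    rows = []
    for (i, c1), (j, c2) in itertools.combinations(enumerate(cohorts), 2):
        aligned = harmonize_pair(c1, c2, drop_ambiguous=drop_ambiguous)
        shared = CohortSummary(
            cohort_id=f"{c1.cohort_id}*{c2.cohort_id}",
            table=pd.DataFrame(
                {
                    "snp_id": aligned.snp_id,
                    "chrom": aligned.chrom,
                    "bp": aligned.bp,
                    "a1": "A",
                    "a2": "C",
                    "freq_a1": aligned.freq1,
                    "beta": aligned.beta1,
                    "se": aligned.se1,
                    "n": aligned.n1,
                }
            ),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = prune_independent(shared, target_m=target_m,
                                     min_gap_bp=min_gap_bp, seed=seed)
        sub = aligned.subset(keep)
        if len(sub) < min_shared:
            warnings.warn(
                f"pair {c1.cohort_id}-{c2.cohort_id}: only {len(sub)} thinned "
                f"markers (< {min_shared}); skipped",
                stacklevel=2,
            )
            continue
        res = pair_lambda(sub, mode=mode, gc_adjusted_input=gc_adjusted_input)
        mat.loc[c1.cohort_id, c2.cohort_id] = res.lambda_meta
        mat.loc[c2.cohort_id, c1.cohort_id] = res.lambda_meta
        rows.append(res)

    table = pd.DataFrame(
        {
            "cohort1": [r.cohort1_id for r in rows],
            "cohort2": [r.cohort2_id for r in rows],
            "lambda_meta": [r.lambda_meta for r in rows],
            "m_snps": [r.m_snps for r in rows],
            "se_theoretical": [r.theoretical_se for r in rows],
            "z_theoretical": [r.z_vs_1 for r in rows],
            "p_theoretical": [r.p_vs_1 for r in rows],
            "gamma_hat": [r.gamma_hat for r in rows],
            "n_o_hat": [r.n_o_hat for r in rows],
        }
    )
    lam = table["lambda_meta"].to_numpy(float)
    if len(lam) >= 2 and lam.std(ddof=1) > 0:
        z_emp = (lam - lam.mean()) / lam.std(ddof=1)
    else:
        z_emp = np.zeros(len(lam))
    table["z_empirical"] = z_emp
    table["p_empirical"] = 2.0 * stats.norm.sf(np.abs(z_emp))
    n_pairs = max(len(table), 1)
    table["significant_bonferroni"] = table["p_theoretical"] < 0.05 / n_pairs
    return PairwiseScanResult(
        matrix=mat,
        pairs=table,
        mode=mode,
        target_m=target_m,
        n_flagged_bonferroni=int(table["significant_bonferroni"].sum()),
    )
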