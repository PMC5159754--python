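"""Pseudo profile score regression (PPSR): pinpointing overlapping and
related individuals across cohorts without sharing genotypes.

A central hub draws K random weight vectors (iid standard normal over M
pre-agreed, non-palindromic SNPs).  Each cohort standardises its genotypes
with hub-supplied reference frequencies, computes K weighted sums (pseudo
profile scores) per individual, and returns only those scores.  For a pair
of individuals from two cohorts, regressing one score vector on the other
across the K scores estimates their genome-wide genetic relationship:
~1 for the same person, ~0.5 for first-degree relatives, ~0 otherwise.

The module also provides the design calculation for the minimum K achieving
a given experiment-wise error rate and power, and a decoding-risk analysis
quantifying how much genotype information the scores leak to an analyst who
knows the weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import is_palindromic

logger = logging.getLogger(__name__)

#: regression-coefficient thresholds for classification
DUPLICATE_THRESHOLD = 0.95
FIRST_DEGREE_THRESHOLD = 0.45


@dataclass
class WeightSet:
    """Hub-generated random SNP weights plus standardisation frequencies.

    ``weights`` is M x K with iid N(0, 1) entries under ``seed``; ``p_ref``
    are the reference allele frequencies used by every cohort to centre and
    scale genotypes, so scores are comparable across cohorts.
    """

    snps: pd.DataFrame  # snp_id, a1, a2
    weights: np.ndarray
    p_ref: np.ndarray
    seed: int

    def __post_init__(self):
        if self.weights.shape[0] != len(self.snps) or len(self.p_ref) != len(self.snps):
            raise ValueError("weights/p_ref rows must match the SNP list")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def k(self) -> int:
        return self.weights.shape[1]

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} M={self.m} K={self.k}\n")
            out = self.snps.copy()
            out["P_REF"] = self.p_ref
            for j in range(self.k):
                out[f"w{j + 1}"] = self.weights[:, j]
            out.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "WeightSet":
        seed = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("seed="):
                        seed = int(tok[5:])
        df = pd.read_csv(path, sep="\t", comment="#")
        wcols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
        return cls(
            snps=df[["snp_id", "a1", "a2"]],
            weights=df[wcols].to_numpy(float),
            p_ref=df["P_REF"].to_numpy(float),
            seed=seed,
        )


@dataclass
class ScoreMatrix:
    """Per-individual pseudo profile scores for one cohort (n x K)."""

    cohort_id: str
    ids: list
    scores: np.ndarray

    def __post_init__(self):
        if self.scores.shape[0] != len(self.ids):
            raise ValueError("one score row per individual required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# cohort={self.cohort_id} K={self.scores.shape[1]}\n")
            out = pd.DataFrame(
                self.scores, columns=[f"pps{j + 1}" for j in range(self.scores.shape[1])]
            )
            out.insert(0, "IID", self.ids)
            out.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, cohort_id: str | None = None) -> "ScoreMatrix":
        cid = cohort_id
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and cid is None:
                for tok in first[1:].split():
                    if tok.startswith("cohort="):
                        cid = tok[7:]
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = [c for c in df.columns if c.startswith("pps")]
        return cls(
            cohort_id=cid or "cohort",
            ids=df["IID"].astype(str).tolist(),
            scores=df[cols].to_numpy(float),
        )


@dataclass
class MatchResult:
    """Cross-cohort pair classifications from the all-pairs regression."""

    cohort_a: str
    cohort_b: str
    matches: pd.DataFrame  # id_a, id_b, b, classification
    n_tests: int
    duplicate_threshold: float = DUPLICATE_THRESHOLD
    first_degree_threshold: float = FIRST_DEGREE_THRESHOLD
    n_skipped_zero_variance: int = 0
    coefficients: np.ndarray | None = None


@dataclass
class PpsrDesign:
    """Inputs and result of the minimum-K design calculation."""

    n_tests: int
    experimentwise_alpha: float
    beta: float
    rho_threshold: float
    k_required: int
    per_test_alpha: float = field(init=False)

    def __post_init__(self):
        self.per_test_alpha = self.experimentwise_alpha / self.n_tests


def generate_weights(snps: pd.DataFrame, k: int, seed: int, p_ref) -> WeightSet:
    """Draw the reproducible M x K standard-normal weight matrix.

    ``snps`` must carry snp_id/a1/a2; palindromic (A/T, C/G) markers are
    rejected because cohorts could not verify their strand orientation
    before scoring.
    """
    if len(snps) < 1 or k < 1:
        raise ValueError("need at least one SNP and one score")
    pal = is_palindromic(snps["a1"].to_numpy(object), snps["a2"].to_numpy(object))
    if pal.any():
        bad = snps["snp_id"].to_numpy(object)[pal][:5]
        raise ValueError(
            f"{int(pal.sum())} palindromic SNPs in the candidate list "
            f"(e.g. {list(bad)}); supply non-palindromic markers only"
        )
    p_ref = np.asarray(p_ref, float)
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((len(snps), k))
    return WeightSet(snps=snps.reset_index(drop=True), weights=w, p_ref=p_ref, seed=seed)


def compute_scores(
    genotypes: np.ndarray, w: WeightSet, ids=None, cohort_id: str = "cohort"
) -> ScoreMatrix:
    """Pseudo profile scores from an n x M dosage matrix.

    Genotypes are standardised to (g - 2p) / sqrt(2 p (1 - p)) with the
    hub's reference frequency p; missing dosages (NaN or negative) become 0
    after centring (mean imputation), so a 1% missing rate shifts scores
    only marginally.  Scores are x @ W / sqrt(M), making regression
    coefficients comparable across choices of M.
    """
    g = np.asarray(genotypes, float)
    if g.ndim != 2 or g.shape[1] != w.m:
        raise ValueError(
            f"genotype matrix must be n x {w.m} and allele-aligned to the weight set"
        )
    p = w.p_ref
    denom = np.sqrt(2 * p * (1 - p))
    if np.any(denom == 0):
        raise ValueError("monomorphic reference frequency in weight set")
    x = (g - 2 * p) / denom
    x[~np.isfinite(x) | (g < 0)] = 0.0
    scores = x @ w.weights / np.sqrt(w.m)
    if ids is None:
        ids = [f"{cohort_id}_ind{i}" for i in range(g.shape[0])]
    return ScoreMatrix(cohort_id=cohort_id, ids=list(ids), scores=scores)


def match_pairs(
    a: ScoreMatrix,
    b: ScoreMatrix,
    duplicate_threshold: float = DUPLICATE_THRESHOLD,
    first_degree_threshold: float = FIRST_DEGREE_THRESHOLD,
    return_coefficients: bool = False,
) -> MatchResult:
    """All-pairs score regression between two cohorts.

    For individuals i (cohort a) and j (cohort b), b_ij is the slope of
    regressing j's K scores on i's: cov(s_i, s_j) / var(s_i).  Both
    directions are computed as a single matrix product of row-centred score
    matrices, and classification uses max(b_ij, b_ji), which is robust to
    one-sided missingness deflating one of the variances.  Rows with zero
    score variance are skipped and counted.
    """
    if a.scores.shape[1] != b.scores.shape[1]:
        raise ValueError("score matrices must come from the same weight set")
    ac = a.scores - a.scores.mean(axis=1, keepdims=True)
    bc = b.scores - b.scores.mean(axis=1, keepdims=True)
    ssa = (ac**2).sum(axis=1)
    ssb = (bc**2).sum(axis=1)
    ok_a = ssa > 0
    ok_b = ssb > 0
    n_skip = int((~ok_a).sum() + (~ok_b).sum())
    cross = ac @ bc.T
    with np.errstate(divide="ignore", invalid="ignore"):
        b_on_a = cross / ssa[:, None]
        a_on_b = cross / ssb[None, :]
    coef = np.fmax(b_on_a, a_on_b)
    coef[~ok_a, :] = np.nan
    coef[:, ~ok_b] = np.nan

    hit = np.nan_to_num(coef, nan=-np.inf) >= first_degree_threshold
    ii, jj = np.nonzero(hit)
    bvals = coef[ii, jj]
    classification = np.where(
        bvals >= duplicate_threshold, "duplicate", "first_degree"
    )
    matches = pd.DataFrame(
        {
            "id_a": np.asarray(a.ids, dtype=object)[ii],
            "id_b": np.asarray(b.ids, dtype=object)[jj],
            "b": bvals,
            "classification": classification,
        }
    ).sort_values("b", ascending=False).reset_index(drop=True)
    return MatchResult(
        cohort_a=a.cohort_id,
        cohort_b=b.cohort_id,
        matches=matches,
        n_tests=int(ok_a.sum()) * int(ok_b.sum()),
        duplicate_threshold=duplicate_threshold,
        first_degree_threshold=first_degree_threshold,
        n_skipped_zero_variance=n_skip,
        coefficients=coef if return_coefficients else None,
    )


def required_scores(
    n_tests: int,
    alpha_exp: float = 0.01,
    beta: float = 0.05,
    rho_threshold: float = 0.95,
) -> PpsrDesign:
    """Minimum number of scores K for the all-pairs detection experiment.

    The regression coefficient for an unrelated pair is approximately
    N(0, 1/K); for a truly related pair with relationship rho it is
    approximately N(rho, (1 - rho^2)/K).  With Bonferroni per-test level
    alpha = alpha_exp / n_tests and a one-sided normal test, power 1 - beta
    at the detection threshold rho requires

        K >= ((z_{1-alpha} + z_{1-beta} sqrt(1 - rho^2)) / rho)^2

    rounded up to the next integer.
    """
    if not (0 < alpha_exp < 1 and 0 < beta < 1 and 0 < rho_threshold <= 1):
        raise ValueError("alpha_exp, beta in (0,1); rho_threshold in (0,1]")
    alpha = alpha_exp / n_tests
    z_a = stats.norm.isf(alpha)
    z_b = stats.norm.isf(beta)
    k = int(np.ceil(((z_a + z_b * np.sqrt(1 - rho_threshold**2)) / rho_threshold) ** 2))
    return PpsrDesign(
        n_tests=n_tests,
        experimentwise_alpha=alpha_exp,
        beta=beta,
        rho_threshold=rho_threshold,
        k_required=max(k, 1),
    )


def decode_risk(
    w: WeightSet,
    scores: ScoreMatrix,
    true_genotypes: np.ndarray | None = None,
    maf_bin_edges: tuple = (0.1, 0.3),
) -> pd.DataFrame:
    """How much genotype information the scores leak to the hub.

    An analyst knowing the weight matrix can least-squares decode the
    standardised genotypes from each individual's K scores; with K < M the
    minimum-norm solution recovers only the projection of the genotype
    vector onto the K-dimensional weight span, so accuracy grows with K/M
    and reaches ~1 at K >= M.  When true genotypes are supplied the result
    reports, per minor-allele-frequency bin, the mean squared correlation
    between decoded and true dosages across SNPs (otherwise R2 is NaN and
    only the decoded matrix dimensions are summarised).
    """
    if w.k < 2:
        raise ValueError("decoding analysis needs K >= 2")
    x_hat = np.sqrt(w.m) * scores.scores @ np.linalg.pinv(w.weights)
    maf = np.minimum(w.p_ref, 1 - w.p_ref)
    edges = (0.0, *maf_bin_edges, 0.5 + 1e-12)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    bins = np.digitize(maf, edges[1:-1])

    r2 = np.full(w.m, np.nan)
    if true_genotypes is not None:
        g = np.asarray(true_genotypes, float)
        if g.shape != x_hat.shape:
            raise ValueError("true genotype matrix must be n x M")
        gc = g - g.mean(axis=0)
        xc = x_hat - x_hat.mean(axis=0)
        num = (gc * xc).sum(axis=0)
        den = np.sqrt((gc**2).sum(axis=0) * (xc**2).sum(axis=0))
        ok = den > 0
        r2[ok] = (num[ok] / den[ok]) ** 2
    rows = []
    for bin_idx, label in enumerate(labels):
        sel = bins == bin_idx
        rows.append(
            {
                "maf_bin": label,
                "n_snps": int(sel.sum()),
                "mean_r2": float(np.nanmean(r2[sel])) if sel.any() else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["k_over_m"] = w.k / w.m
    out.attrs["mean_r2_overall"] = float(np.nanmean(r2)) if np.isfinite(r2).any() else np.nan
    return out


def read_dosage_matrix(path) -> tuple[list, np.ndarray, list]:
    """Read a delimited 0/1/2 dosage matrix: first column IID, then one
    column per SNP (header row carries SNP ids).  Missing values may be NA
    or negative.  Returns (ids, n x M float array, snp ids)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    iid_col = df.columns[0]
    snp_cols = list(df.columns[1:])
    g = df[snp_cols].to_numpy(float)
    return df[iid_col].astype(str).tolist(), g, snp_cols


def write_dosage_matrix(path, ids, genotypes, snp_ids, comment: str | None = None):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        out = pd.DataFrame(np.asarray(genotypes), columns=list(snp_ids))
        out.insert(0, "IID", list(ids))
        out.to_csv(fh, sep="\t", index=False)
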