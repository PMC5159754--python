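"""Meta-PCA: principal component analysis over cohorts using reported
allele frequencies.

Each cohort is treated as one observation and each SNP's effect-allele
frequency as one feature, so a study of 120 cohorts is decomposed like a
sample of 120 individuals.  The leading components recover the ancestral
background of each cohort, complementing the Fst-based placement with a
method that needs no reference panel (though reference populations can be
included as extra rows for orientation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst_geography import RefPanel
from .sumstats_io import CohortSummary, is_palindromic

logger = logging.getLogger(__name__)


@dataclass
class FreqMatrix:
    """Cohorts x SNPs allele-frequency matrix, harmonised to one orientation.

    Rows may include reference populations.  Columns with any missing value
    are removed before decomposition; ``n_dropped_missing`` counts them.
    """

    cohort_ids: list
    snp_ids: np.ndarray
    values: np.ndarray
    n_dropped_missing: int = 0
    n_dropped_maf: int = 0

    def __post_init__(self):
        if self.values.shape != (len(self.cohort_ids), len(self.snp_ids)):
            raise ValueError("matrix shape does not match labels")


@dataclass
class MetaPcaResult:
    """Cohort coordinates on the leading meta-PC axes."""

    coords: pd.DataFrame  # cohort_id, mPC1..mPCk
    eigenvalues: np.ndarray
    prop_var: np.ndarray
    scale_mode: str


def build_freq_matrix(
    cohorts: list[CohortSummary],
    refs: RefPanel | None = None,
    min_maf: float = 0.01,
    drop_ambiguous: bool = True,
) -> FreqMatrix:
    """Assemble the cohorts-x-SNPs frequency matrix on the common SNP set.

    The first cohort's allele orientation is the reference; other cohorts'
    frequencies are flipped to ``1 - p`` where they report the swapped
    allele pair.  SNPs missing a frequency in any cohort are dropped, as are
    SNPs whose pooled minor-allele frequency falls below ``min_maf``.
    """
    if len(cohorts) + (len(refs.pops) if refs else 0) < 3:
        raise ValueError("meta-PCA needs at least 3 rows (cohorts + references)")
    anchor = cohorts[0].table[["snp_id", "a1", "a2"]]
    if drop_ambiguous:
        pal = is_palindromic(
            anchor["a1"].to_numpy(object), anchor["a2"].to_numpy(object)
        )
        anchor = anchor[~pal]

    columns = {}
    ids = []
    frames = []
    for c in cohorts:
        merged = anchor.merge(c.table, on="snp_id", suffixes=("", "_c"))
        same = (merged["a1_c"] == merged["a1"]) & (merged["a2_c"] == merged["a2"])
        swapped = (merged["a1_c"] == merged["a2"]) & (merged["a2_c"] == merged["a1"])
        freq = merged["freq_a1"].to_numpy(float).copy()
        freq[swapped.to_numpy(bool)] = 1.0 - freq[swapped.to_numpy(bool)]
        freq[~(same | swapped).to_numpy(bool)] = np.nan
        frames.append(pd.Series(freq, index=merged["snp_id"], name=c.cohort_id))
        ids.append(c.cohort_id)
    if refs is not None:
        panel = anchor.merge(
            pd.concat([refs.snps, refs.freqs], axis=1), on="snp_id", suffixes=("", "_r")
        )
        same = (panel["a1_r"] == panel["a1"]) & (panel["a2_r"] == panel["a2"])
        swapped = (panel["a1_r"] == panel["a2"]) & (panel["a2_r"] == panel["a1"])
        for pop in refs.pops:
            freq = panel[pop].to_numpy(float).copy()
            freq[swapped.to_numpy(bool)] = 1.0 - freq[swapped.to_numpy(bool)]
            freq[~(same | swapped).to_numpy(bool)] = np.nan
            frames.append(pd.Series(freq, index=panel["snp_id"], name=pop))
            ids.append(pop)

    mat = pd.concat(frames, axis=1, join="inner").T
    if mat.shape[1] == 0:
        raise ValueError("no SNPs shared by all cohorts")
    complete = ~mat.isna().any(axis=0)
    n_missing = int((~complete).sum())
    mat = mat.loc[:, complete]
    pooled = mat.to_numpy(float).mean(axis=0)
    maf = np.minimum(pooled, 1 - pooled)
    keep = maf >= min_maf
    n_maf = int((~keep).sum())
    mat = mat.loc[:, keep]
    if mat.shape[1] == 0:
        raise ValueError("no SNPs left after missingness/MAF filtering")
    if n_missing or n_maf:
        logger.info(
            "build_freq_matrix: dropped %d SNPs with missing frequencies, "
            "%d below MAF %.3g", n_missing, n_maf, min_maf,
        )
    return FreqMatrix(
        cohort_ids=ids,
        snp_ids=mat.columns.to_numpy(object),
        values=np.ascontiguousarray(mat.to_numpy(float)),
        n_dropped_missing=n_missing,
        n_dropped_maf=n_maf,
    )


def run_meta_pca(
    m: FreqMatrix, k: int = 2, scale_mode: str = "center_scale"
) -> MetaPcaResult:
    """SVD of the (centred, optionally scaled) frequency matrix.

    ``center`` subtracts the column mean; ``center_scale`` additionally
    divides each column by ``sqrt(pbar (1 - pbar))`` with ``pbar`` the column
    mean, the frequency analogue of genotype standardisation.  Coordinates
    are left singular vectors scaled by singular values.  Sign convention:
    each component's largest-magnitude SNP loading is positive, which makes
    results reproducible across BLAS implementations.
    """
    if scale_mode not in ("center", "center_scale"):
        raise ValueError("scale_mode must be 'center' or 'center_scale'")
    x = m.values.astype(float)
    n_rows = x.shape[0]
    if n_rows < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} components")
    pbar = x.mean(axis=0)
    x = x - pbar
    if scale_mode == "center_scale":
        denom = np.sqrt(pbar * (1 - pbar))
        ok = denom > 0
        x = x[:, ok] / denom[ok]
    if not np.any(x != 0):
        raise ValueError("zero-variance frequency matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for comp in range(min(k, len(s))):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] = -vt[comp]
            u[:, comp] = -u[:, comp]
    coords = u[:, :k] * s[:k]
    eigenvalues = s**2 / max(n_rows - 1, 1)
    prop = eigenvalues / eigenvalues.sum()
    df = pd.DataFrame(coords, columns=[f"mPC{i + 1}" for i in range(coords.shape[1])])
    df.insert(0, "cohort_id", m.cohort_ids)
    return MetaPcaResult(
        coords=df,
        eigenvalues=eigenvalues[:k],
        prop_var=prop[:k],
        scale_mode=scale_mode,
    )
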