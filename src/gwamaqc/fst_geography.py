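"""Fst genetic distances between cohorts and reference populations, and the
2-D "Fst cartographer" projection.

A cohort that reports allele frequencies can be compared with reference
panels (e.g. 1000 Genomes populations) through Hudson-type Fst computed from
frequencies alone.  Cohorts whose genome-wide distance spectrum disagrees
with their declared ancestry, or whose distance to a pooled reference exceeds
a threshold, are flagged as outliers.

The cartographer embeds three reference populations in a plane by classical
metric MDS, treating Fst as a squared Euclidean distance, and then places
each cohort at the least-squares trilateration point given its three Fst
values to the references.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import CohortSummary, is_palindromic

logger = logging.getLogger(__name__)


class MonomorphicInputError(ValueError):
    """Fst is undefined: the between-population heterozygosity is zero."""


class DegenerateGeometryError(ValueError):
    """Reference vertices are collinear; trilateration is ill-posed."""


@dataclass
class RefPanel:
    """Allele frequencies of reference populations on a shared SNP list.

    ``snps`` carries snp_id/chrom/bp/a1/a2 (frequencies refer to a1);
    ``freqs`` has one column per population aligned row-wise with ``snps``;
    ``n`` maps population id to its diploid sample count.
    """

    snps: pd.DataFrame
    freqs: pd.DataFrame
    n: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.snps) != len(self.freqs):
            raise ValueError("snps and freqs must have the same number of rows")
        vals = self.freqs.to_numpy(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("reference frequencies must lie in [0, 1]")
        self.snps = self.snps.reset_index(drop=True)
        self.freqs = self.freqs.reset_index(drop=True)

    @property
    def pops(self) -> list[str]:
        return list(self.freqs.columns)

    @classmethod
    def from_genotypes(cls, snps: pd.DataFrame, genotypes: dict) -> "RefPanel":
        """Build a panel from 0/1/2 dosage matrices (individuals x SNPs)."""
        freqs = {}
        n = {}
        for pop, g in genotypes.items():
            g = np.asarray(g, float)
            freqs[pop] = np.nanmean(g, axis=0) / 2.0
            n[pop] = g.shape[0]
        return cls(snps=snps, freqs=pd.DataFrame(freqs), n=n)

    def pooled(self, pops: list[str] | None = None, pop_id: str = "POOLED") -> "RefPanel":
        """Sample-size weighted pooled frequencies over ``pops``."""
        pops = pops or self.pops
        w = np.array([self.n.get(p, 1) for p in pops], float)
        mat = self.freqs[pops].to_numpy(float)
        pooled = mat @ (w / w.sum())
        return RefPanel(
            snps=self.snps.copy(),
            freqs=pd.DataFrame({pop_id: pooled}),
            n={pop_id: int(w.sum())},
        )

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("# " + " ".join(f"N_{p}={self.n.get(p, 'NA')}" for p in self.pops) + "\n")
            pd.concat([self.snps, self.freqs], axis=1).to_csv(
                fh, sep="\t", index=False, float_format="%.17g"
            )

    @classmethod
    def read_tsv(cls, path) -> "RefPanel":
        n = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("N_") and "=" in tok:
                        key, val = tok[2:].split("=", 1)
                        if val != "NA":
                            n[key] = int(val)
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str, "chrom": str})
        df.columns = [c.lower() if c.lower() in ("snp", "chr", "bp", "a1", "a2") else c for c in df.columns]
        df = df.rename(columns={"snp": "snp_id", "chr": "chrom"})
        meta_cols = ["snp_id", "chrom", "bp", "a1", "a2"]
        pop_cols = [c for c in df.columns if c not in meta_cols]
        return cls(snps=df[meta_cols], freqs=df[pop_cols], n={p: n.get(p, 1) for p in pop_cols})


@dataclass
class FstProfile:
    """One cohort's Fst to each reference population, on a shared SNP set."""

    cohort_id: str
    fst: dict
    n_snps: int


@dataclass
class FpcProjection:
    """2-D reference vertices plus per-cohort trilaterated coordinates.

    Convention: squared Euclidean distance in this plane equals Fst, so the
    reference vertices reproduce the reference-pair Fst values exactly
    whenever the Fst matrix is Euclidean-embeddable in two dimensions.
    """

    ref_pops: list
    ref_coords: np.ndarray  # 3 x 2
    coords: pd.DataFrame  # cohort_id, fpc1, fpc2, residual
    eigenvalues: np.ndarray


def fst_pair(p1, n1, p2, n2, clamp: bool = True) -> float:
    """Hudson-type Fst between two populations from allele frequencies.

    Combined across SNPs as a ratio of averages with finite-sample
    correction::

        N_i = (p1-p2)^2 - p1(1-p1)/(2 n1 - 1) - p2(1-p2)/(2 n2 - 1)
        D_i = p1(1-p2) + p2(1-p1)
        Fst = sum(N) / sum(D)

    ``n1``/``n2`` are diploid sample counts (scalar or per-SNP arrays).  The
    per-SNP numerators may be negative; only the final ratio is clamped to
    [0, 1] (set ``clamp=False`` to inspect the raw value, which is slightly
    negative in expectation when the two samples come from one population).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if p1.shape != p2.shape or p1.size < 1:
        raise ValueError("frequency vectors must be equal-length and non-empty")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("sample sizes must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    total_den = den.sum()
    if total_den == 0:
        raise MonomorphicInputError("all SNPs monomorphic in both populations")
    fst = float(num.sum() / total_den)
    if clamp:
        fst = min(max(fst, 0.0), 1.0)
    return fst


def _align_cohort_to_panel(cohort: CohortSummary, refs: RefPanel,
                           drop_ambiguous: bool = True):
    """Match cohort records to panel SNPs, flipping frequency where the
    cohort reports the other allele.  Returns (cohort freqs, cohort n,
    panel row index) for usable SNPs."""
    tab = cohort.table[cohort.table["freq_a1"].notna()]
    panel = refs.snps.reset_index().rename(columns={"index": "_row"})
    merged = tab.merge(panel, on="snp_id", suffixes=("", "_r"))
    if merged.empty:
        return np.array([]), np.array([]), np.array([], dtype=int)
    a1 = merged["a1"].to_numpy(object)
    a2 = merged["a2"].to_numpy(object)
    r1 = merged["a1_r"].to_numpy(object)
    r2 = merged["a2_r"].to_numpy(object)
    same = (a1 == r1) & (a2 == r2)
    swapped = (a1 == r2) & (a2 == r1)
    usable = same | swapped
    if drop_ambiguous:
        usable &= ~is_palindromic(a1, a2)
    freq = merged["freq_a1"].to_numpy(float).copy()
    freq[swapped] = 1.0 - freq[swapped]
    return (
        freq[usable],
        merged["n"].to_numpy(float)[usable],
        merged["_row"].to_numpy(int)[usable],
    )


def fst_profile(
    cohort: CohortSummary,
    refs: RefPanel,
    snp_subset=None,
    min_snps_warn: int = 1000,
) -> FstProfile:
    """Fst from one cohort to every panel population, on one shared SNP set."""
    c = cohort if snp_subset is None else cohort.subset(snp_subset)
    freq, n_c, rows = _align_cohort_to_panel(c, refs)
    if len(rows) < 10:
        raise ValueError(
            f"cohort {cohort.cohort_id}: only {len(rows)} SNPs shared with the panel"
        )
    if len(rows) < min_snps_warn:
        warnings.warn(
            f"cohort {cohort.cohort_id}: only {len(rows)} shared SNPs for Fst",
            stacklevel=2,
        )
    out = {}
    for pop in refs.pops:
        p_ref = refs.freqs[pop].to_numpy(float)[rows]
        out[pop] = fst_pair(freq, n_c, p_ref, refs.n.get(pop, 100))
    return FstProfile(cohort_id=cohort.cohort_id, fst=out, n_snps=len(rows))


def embed_references(ref_fst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric MDS of the reference populations in 2-D.

    ``ref_fst`` (symmetric, zero diagonal) is interpreted as a matrix of
    squared Euclidean distances.  Returns (vertices k x 2, eigenvalues);
    negative eigenvalues are clipped to zero.
    """
    d2 = np.asarray(ref_fst, float)
    if d2.shape[0] != d2.shape[1]:
        raise ValueError("ref_fst must be square")
    if not np.allclose(d2, d2.T) or not np.allclose(np.diag(d2), 0):
        raise ValueError("ref_fst must be symmetric with a zero diagonal")
    k = d2.shape[0]
    j = np.eye(k) - np.full((k, k), 1.0 / k)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    coords = evecs[:, :2] * np.sqrt(evals[:2])
    return coords, evals


def trilaterate(vertices: np.ndarray, sq_dists: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares position given squared distances to 3 anchor vertices.

    Solves the standard linearisation (subtracting the first anchor's circle
    equation) and reports the residual of the quadratic objective
    ``sum_k (|x - v_k|^2 - d2_k)^2``.
    """
    v = np.asarray(vertices, float)
    d2 = np.asarray(sq_dists, float)
    if v.shape != (3, 2) or d2.shape != (3,):
        raise ValueError("expected 3 anchors in 2-D and 3 squared distances")
    a = 2.0 * (v[1:] - v[0])
    if abs(np.linalg.det(a)) < 1e-12 * max(1.0, np.abs(a).max()) ** 2:
        raise DegenerateGeometryError("reference vertices are collinear")
    norms = (v**2).sum(axis=1)
    b = (d2[0] - d2[1:]) + (norms[1:] - norms[0])
    x = np.linalg.solve(a, b)
    resid = float((((x - v) ** 2).sum(axis=1) - d2).__pow__(2).sum())
    return x, resid


def fpc_project(
    profiles: list[FstProfile],
    ref_fst: np.ndarray,
    ref_pops: list[str],
) -> FpcProjection:
    """Project cohorts into the 2-D plane spanned by three reference
    populations, with squared distance proportional to Fst."""
    if len(ref_pops) != 3:
        raise ValueError("the cartographer uses exactly 3 reference populations")
    coords_ref, evals = embed_references(ref_fst)
    rows = []
    for prof in profiles:
        d2 = np.array([prof.fst[p] for p in ref_pops], float)
        x, resid = trilaterate(coords_ref, d2)
        rows.append((prof.cohort_id, x[0], x[1], resid))
    coords = pd.DataFrame(rows, columns=["cohort_id", "fpc1", "fpc2", "residual"])
    return FpcProjection(
        ref_pops=list(ref_pops),
        ref_coords=coords_ref,
        coords=coords,
        eigenvalues=evals,
    )


def ref_fst_matrix(refs: RefPanel, pops: list[str] | None = None) -> np.ndarray:
    """Pairwise Hudson Fst among panel populations (symmetric, zero diag)."""
    pops = pops or refs.pops
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = fst_pair(
                refs.freqs[pops[i]].to_numpy(float),
                refs.n.get(pops[i], 100),
                refs.freqs[pops[j]].to_numpy(float),
                refs.n.get(pops[j], 100),
            )
            out[i, j] = out[j, i] = f
    return out


def outlier_scan(
    profiles: list[FstProfile],
    pooled_pop: str,
    flag_threshold: float = 0.005,
) -> pd.DataFrame:
    """Flag cohorts whose Fst to the pooled reference exceeds the threshold.

    Returns the flagged cohorts sorted by descending Fst.
    """
    rows = [
        (p.cohort_id, p.fst[pooled_pop], p.n_snps)
        for p in profiles
        if p.fst[pooled_pop] > flag_threshold
    ]
    out = pd.DataFrame(rows, columns=["cohort_id", "fst", "n_snps"])
    return out.sort_values("fst", ascending=False).reset_index(drop=True)
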