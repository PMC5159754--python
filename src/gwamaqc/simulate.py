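"""Synthetic multi-cohort GWAS generator.

Produces everything the QC metrics consume — reference-panel frequencies,
cohort genotype matrices, quantitative phenotypes, per-SNP least-squares
summary statistics — with known ground truth for overlapping samples,
first-degree relatives and shared control pools.

Population allele frequencies follow the Balding-Nichols model: an
ancestral frequency p drawn uniformly on the MAF range, and a population
frequency Beta(p (1-F)/F, (1-p)(1-F)/F) realising a target Fst of F.
Markers are unlinked (genotypes are independent Binomial(2, p) draws),
matching the linkage-equilibrium assumption of the downstream statistics.
Phenotypes place iid normal effects on a chosen number of QTLs, scaled so
the genetic variance is the requested heritability of a unit-variance
trait.

Every generator is bit-reproducible under its seed, and the returned truth
object is sufficient to score any detection result without re-reading
genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import CohortSummary

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class PopulationSpec:
    pop_id: str
    fst: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.fst < 1.0:
            raise SimConfigError("population Fst must lie in [0, 1)")


@dataclass
class CohortSpec:
    """One cohort: sample size, population, trait genetics and its links
    (shared individuals or first-degree relatives) to an earlier cohort."""

    cohort_id: str
    pop_id: str
    n: int
    h2: float = 0.25
    overlap_with: tuple | None = None  # (cohort_id, n_shared)
    relatives_with: tuple | None = None  # (cohort_id, n_first_degree)

    def __post_init__(self):
        if self.n < 1:
            raise SimConfigError("cohort size must be >= 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise SimConfigError("h2 must lie in [0, 1]")


@dataclass
class SimConfig:
    m_snps: int = 30_000
    populations: list = field(default_factory=lambda: [PopulationSpec("POP")])
    cohorts: list = field(default_factory=list)
    n_qtl: int = 1000
    maf_range: tuple = (0.05, 0.95)
    seed: int = 2016
    bp_spacing: int = 500_000

    def __post_init__(self):
        if self.n_qtl > self.m_snps:
            raise SimConfigError("n_qtl cannot exceed m_snps")
        pop_ids = {p.pop_id for p in self.populations}
        seen = set()
        for c in self.cohorts:
            if c.pop_id not in pop_ids:
                raise SimConfigError(f"cohort {c.cohort_id}: unknown population {c.pop_id}")
            for link in (c.overlap_with, c.relatives_with):
                if link is not None and link[0] not in seen:
                    raise SimConfigError(
                        f"cohort {c.cohort_id}: link target {link[0]} must be "
                        "an earlier cohort"
                    )
            seen.add(c.cohort_id)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        pops = [PopulationSpec(**p) for p in d.get("populations", [{"pop_id": "POP"}])]
        cohorts = []
        for c in d.get("cohorts", []):
            c = dict(c)
            for key in ("overlap_with", "relatives_with"):
                if c.get(key) is not None:
                    c[key] = tuple(c[key])
            cohorts.append(CohortSpec(**c))
        kwargs = {
            k: d[k]
            for k in ("m_snps", "n_qtl", "seed", "bp_spacing")
            if k in d
        }
        if "maf_range" in d:
            kwargs["maf_range"] = tuple(d["maf_range"])
        return cls(populations=pops, cohorts=cohorts, **kwargs)


@dataclass
class SimulatedCohort:
    cohort_id: str
    ids: list
    genotypes: np.ndarray  # n x m int8 dosages of the snp-table a1 allele
    phenotype: np.ndarray
    genetic_value: np.ndarray
    summary: CohortSummary | None = None


@dataclass
class SimTruth:
    """Ground truth recorded while generating a simulation."""

    ancestral_freq: np.ndarray
    pop_freqs: dict
    qtl_index: np.ndarray
    qtl_effects: dict  # cohort_id -> effect vector on qtl_index
    overlap: dict = field(default_factory=dict)  # (c1, c2) -> list of shared ids
    relatives: dict = field(default_factory=dict)  # (c1, c2) -> [(parent, child)]
    gamma: dict = field(default_factory=dict)  # (c1, c2) -> n12 / sqrt(n1 n2)


@dataclass
class SimResult:
    config: SimConfig
    snps: pd.DataFrame
    truth: SimTruth
    cohorts: dict


def make_snp_table(m: int, rng: np.random.Generator, bp_spacing: int = 500_000) -> pd.DataFrame:
    """Marker map: m SNPs spread over 22 autosomes with random allele pairs."""
    chrom = 1 + (np.arange(m) * 22) // m
    within = np.zeros(m, dtype=np.int64)
    for ch in range(1, 23):
        sel = chrom == ch
        within[sel] = np.arange(sel.sum())
    pairs = np.array(_ALLELE_PAIRS, dtype=object)[rng.integers(0, len(_ALLELE_PAIRS), m)]
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(m)],
            "chrom": chrom.astype(str),
            "bp": 1 + within * bp_spacing,
            "a1": pairs[:, 0],
            "a2": pairs[:, 1],
        }
    )


def sim_ref_freqs(
    ancestral: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols population frequencies around the ancestral vector."""
    p = np.asarray(ancestral, float)
    if fst == 0.0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b)


def sim_genotypes(
    freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n x m Binomial(2, p) dosage matrix (int8), chunked to bound memory."""
    p = np.asarray(freqs, np.float32)
    m = p.size
    g = np.empty((n, m), np.int8)
    chunk = max(1, int(4e7 // max(m, 1)))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        g[s:e] = (rng.random((e - s, m), dtype=np.float32) < p).astype(np.int8)
        g[s:e] += rng.random((e - s, m), dtype=np.float32) < p
    return g


def _drop_child(parent_g: np.ndarray, pop_freqs: np.ndarray, rng) -> np.ndarray:
    """Gene-drop one offspring: one allele transmitted from the parent, the
    other drawn from the population (expected relatedness 0.5)."""
    m = parent_g.shape[-1]
    transmitted = (rng.random(parent_g.shape, dtype=np.float32) < parent_g / 2.0)
    mate = rng.random(parent_g.shape, dtype=np.float32) < pop_freqs.astype(np.float32)
    return (transmitted.astype(np.int8) + mate).astype(np.int8)


def sim_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    snps: pd.DataFrame,
    cohort_id: str,
    trait: str = "trait",
) -> CohortSummary:
    """Per-SNP simple least-squares association scan.

    For each marker, slope and standard error of regressing the phenotype
    on the a1 dosage; allele frequency from the cohort's own genotypes.
    Monomorphic markers are emitted with NaN effect and SE so the record
    count matches the map (they are excluded by every downstream consumer).
    The vectorised sums reproduce a per-SNP regression loop exactly.
    """
    g = genotypes
    y = np.asarray(phenotype, float)
    n, m = g.shape
    if n < 10:
        raise SimConfigError("need at least 10 individuals for a GWAS")
    colsum = g.sum(axis=0, dtype=np.int64)
    count2 = (g == 2).sum(axis=0)
    sum_sq = colsum + 2 * count2  # g^2 = g + 2*[g == 2] for dosages
    gbar = colsum / n
    sxx = sum_sq - n * gbar**2
    ybar = y.mean()
    yg = np.zeros(m)
    chunk = max(1, int(4e7 // m))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        yg += y[s:e] @ g[s:e].astype(np.float32)
    sxy = yg - n * ybar * gbar
    syy = float(((y - ybar) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
    mono = sxx <= 0
    beta[mono] = np.nan
    se[mono] = np.nan
    se[~mono & ~(se > 0)] = np.nan
    beta[~(se > 0)] = np.nan
    table = snps.copy()
    table["freq_a1"] = colsum / (2.0 * n)
    table["beta"] = beta
    table["se"] = se
    table["n"] = n
    return CohortSummary(cohort_id=cohort_id, table=table, trait=trait)


def run_simulation(config: SimConfig, keep_genotypes: bool = True) -> SimResult:
    """Generate every cohort of a configuration, with ground truth.

    Cohorts are built in order.  ``overlap_with=(other, k)`` copies the
    first k individuals of the earlier cohort — genotype and phenotype —
    into this one; ``relatives_with=(other, k)`` gene-drops one offspring
    for each of k parents taken from the earlier cohort.  QTL positions and
    base effects are drawn once per simulation so overlapping cohorts share
    a genetic architecture; effects are rescaled to each cohort's h2 using
    its population's expected dosage variance.
    """
    rng = np.random.default_rng(config.seed)
    snps = make_snp_table(config.m_snps, rng, config.bp_spacing)
    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, config.m_snps)
    pop_freqs = {
        p.pop_id: sim_ref_freqs(ancestral, p.fst, rng) for p in config.populations
    }
    qtl_index = np.sort(rng.choice(config.m_snps, size=config.n_qtl, replace=False))
    base_u = rng.standard_normal(config.n_qtl)

    truth = SimTruth(
        ancestral_freq=ancestral,
        pop_freqs=pop_freqs,
        qtl_index=qtl_index,
        qtl_effects={},
    )
    cohorts: dict[str, SimulatedCohort] = {}

    for spec in config.cohorts:
        freqs = pop_freqs[spec.pop_id]
        if spec.h2 > 0:
            var_exp = float(
                np.sum(base_u**2 * 2 * freqs[qtl_index] * (1 - freqs[qtl_index]))
            )
            effects = base_u * np.sqrt(spec.h2 / var_exp)
        else:
            effects = np.zeros(config.n_qtl)
        truth.qtl_effects[spec.cohort_id] = effects

        ids: list = []
        blocks: list[np.ndarray] = []
        pheno: list[np.ndarray] = []
        gval: list[np.ndarray] = []

        if spec.overlap_with is not None:
            src_id, n_shared = spec.overlap_with
            src = cohorts[src_id]
            if n_shared > len(src.ids) or n_shared > spec.n:
                raise SimConfigError(
                    f"cohort {spec.cohort_id}: n_shared exceeds a cohort size"
                )
            ids.extend(src.ids[:n_shared])
            blocks.append(src.genotypes[:n_shared])
            pheno.append(src.phenotype[:n_shared])
            gval.append(src.genetic_value[:n_shared])
            key = (src_id, spec.cohort_id)
            truth.overlap[key] = list(src.ids[:n_shared])
            truth.gamma[key] = n_shared / np.sqrt(len(src.ids) * spec.n)

        if spec.relatives_with is not None:
            src_id, n_rel = spec.relatives_with
            src = cohorts[src_id]
            start = 0
            if spec.overlap_with is not None and spec.overlap_with[0] == src_id:
                start = spec.overlap_with[1]
            if start + n_rel > len(src.ids):
                raise SimConfigError(
                    f"cohort {spec.cohort_id}: not enough individuals in {src_id} "
                    "to act as parents"
                )
            parents = src.genotypes[start:start + n_rel]
            children = _drop_child(parents, freqs, rng)
            child_ids = [f"{spec.cohort_id}_rel{i}" for i in range(n_rel)]
            gv = children[:, qtl_index].astype(np.float64) @ effects
            noise = rng.standard_normal(n_rel) * np.sqrt(max(1 - spec.h2, 0.0))
            ids.extend(child_ids)
            blocks.append(children)
            pheno.append(gv + noise)
            gval.append(gv)
            key = (src_id, spec.cohort_id)
            truth.relatives[key] = list(
                zip(src.ids[start:start + n_rel], child_ids)
            )

        n_new = spec.n - len(ids)
        if n_new < 0:
            raise SimConfigError(
                f"cohort {spec.cohort_id}: copied/related individuals exceed n"
            )
        if n_new:
            g_new = sim_genotypes(freqs, n_new, rng)
            gv = g_new[:, qtl_index].astype(np.float64) @ effects
            noise = rng.standard_normal(n_new) * np.sqrt(max(1 - spec.h2, 0.0))
            ids.extend(f"{spec.cohort_id}_ind{i}" for i in range(n_new))
            blocks.append(g_new)
            pheno.append(gv + noise)
            gval.append(gv)

        genotypes = np.vstack(blocks) if len(blocks) > 1 else blocks[0]
        phenotype = np.concatenate(pheno)
        genetic_value = np.concatenate(gval)
        summary = sim_gwas(genotypes, phenotype, snps, spec.cohort_id)
        cohorts[spec.cohort_id] = SimulatedCohort(
            cohort_id=spec.cohort_id,
            ids=ids,
            genotypes=genotypes,
            phenotype=phenotype,
            genetic_value=genetic_value,
            summary=summary,
        )
    if not keep_genotypes:
        for cohort in cohorts.values():
            cohort.genotypes = np.empty((0, 0), np.int8)
    return SimResult(config=config, snps=snps, truth=truth, cohorts=cohorts)


def simulate_overlap_pair(
    n1: int,
    n2: int,
    n_overlap: int,
    h2: float = 0.25,
    n_qtl: int = 1000,
    m_snps: int = 30_000,
    seed: int = 2016,
    keep_genotypes: bool = False,
) -> SimResult:
    """Two cohorts from one population sharing ``n_overlap`` individuals.

    This is the workhorse design behind the overlap-recovery experiments:
    the true summary-statistic correlation is n_overlap / sqrt(n1 n2).
    """
    config = SimConfig(
        m_snps=m_snps,
        populations=[PopulationSpec("POP")],
        cohorts=[
            CohortSpec("cohort1", "POP", n1, h2=h2),
            CohortSpec(
                "cohort2", "POP", n2, h2=h2,
                overlap_with=("cohort1", n_overlap) if n_overlap else None,
            ),
        ],
        n_qtl=n_qtl,
        seed=seed,
    )
    return run_simulation(config, keep_genotypes=keep_genotypes)


def sim_shared_controls(
    n_cohorts: int,
    n_controls: int,
    n_cases: int,
    m_snps: int,
    seed: int = 2016,
    maf_range: tuple = (0.05, 0.95),
) -> SimResult:
    """Case-control cohorts reusing one shared control pool.

    Every cohort contains the same ``n_controls`` control individuals
    (identical genotypes and ids) plus ``n_cases`` freshly drawn cases from
    the same population; disease status has no genetic signal, which is the
    worst case for overlap detection.  A binary label phenotype
    (1 = case) is attached for completeness.
    """
    if n_cohorts < 2:
        raise SimConfigError("need at least two case-control cohorts")
    rng = np.random.default_rng(seed)
    snps = make_snp_table(m_snps, rng)
    lo, hi = maf_range
    ancestral = rng.uniform(lo, hi, m_snps)
    controls = sim_genotypes(ancestral, n_controls, rng)
    control_ids = [f"ctrl{i}" for i in range(n_controls)]
    truth = SimTruth(
        ancestral_freq=ancestral,
        pop_freqs={"POP": ancestral},
        qtl_index=np.array([], dtype=int),
        qtl_effects={},
    )
    cohorts = {}
    for c in range(n_cohorts):
        cid = f"cc{c + 1}"
        cases = sim_genotypes(ancestral, n_cases, rng)
        g = np.vstack([controls, cases]) if n_cases else controls.copy()
        ids = control_ids + [f"{cid}_case{i}" for i in range(n_cases)]
        label = np.r_[np.zeros(n_controls), np.ones(n_cases)]
        cohorts[cid] = SimulatedCohort(
            cohort_id=cid,
            ids=ids,
            genotypes=g,
            phenotype=label,
            genetic_value=np.zeros(len(ids)),
        )
    for i in range(n_cohorts):
        for j in range(i + 1, n_cohorts):
            key = (f"cc{i + 1}", f"cc{j + 1}")
            truth.overlap[key] = list(control_ids)
            n_tot = n_controls + n_cases
            truth.gamma[key] = n_controls / n_tot if n_tot else 0.0
    cfg = SimConfig(
        m_snps=m_snps,
        populations=[PopulationSpec("POP")],
        cohorts=[],
        n_qtl=0,
        maf_range=maf_range,
        seed=seed,
    )
    return SimResult(config=cfg, snps=snps, truth=truth, cohorts=cohorts)
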