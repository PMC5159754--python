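"""Reading, validation, harmonisation and thinning of GWAS summary statistics.

Per-cohort summary statistics are whitespace- or tab-delimited tables with one
row per SNP carrying the marker identity (id, chromosome, position, effect and
other allele), the effect-allele frequency, the estimated allelic effect, its
standard error and the sample size.  Every downstream QC metric in this
package consumes the :class:`CohortSummary` container produced here.

Cross-cohort comparisons require the two cohorts to report effects on the
same allele; :func:`harmonize_pair` resolves allele correspondence (including
sign flips for swapped alleles and strand flips) and drops strand-ambiguous
(A/T, C/G) markers by default, since their orientation cannot be resolved
reliably from frequency alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default header names of the supported tabular format (GWAMA-style)
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "bp": "BP",
    "a1": "A1",
    "a2": "A2",
    "freq_a1": "FREQ",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
}

#: internal column order of a validated summary-statistics table
COLUMNS = ["snp_id", "chrom", "bp", "a1", "a2", "freq_a1", "beta", "se", "n"]

MANDATORY_FIELDS = ["snp_id", "chrom", "bp", "a1", "a2", "beta", "se", "n"]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1, a2):
    """True for strand-ambiguous allele pairs (A/T or C/G), vectorised."""
    a1 = np.asarray(a1, dtype=object)
    a2 = np.asarray(a2, dtype=object)
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | (
        (a1 == "C") & (a2 == "G")
    ) | ((a1 == "G") & (a2 == "C"))


class SumstatsFormatError(ValueError):
    """A mandatory column is missing or the file is not a delimited table."""


class EmptyInputError(ValueError):
    """No row of the input survived validation."""


class EmptyOverlapError(ValueError):
    """Two cohorts share no usable SNPs."""


@dataclass
class LoadReport:
    """Accounting of rows dropped while loading one summary-statistics file."""

    n_rows: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_kept

    def summary(self) -> str:
        lines = [f"rows read: {self.n_rows}", f"rows kept: {self.n_kept}"]
        for reason, count in sorted(self.dropped.items()):
            lines.append(f"dropped ({reason}): {count}")
        return "\n".join(lines)


@dataclass
class CohortSummary:
    """One cohort's validated per-SNP summary statistics plus metadata.

    ``table`` holds the columns in :data:`COLUMNS`; rows are sorted by
    (chrom, bp) and SNP ids are unique.  ``freq_a1`` may be NaN (a cohort that
    did not report frequencies can still enter effect-size based QC);
    ``beta``/``se`` may be NaN for monomorphic markers emitted by the
    simulator, which are excluded from every analysis.
    """

    cohort_id: str
    table: pd.DataFrame
    trait: str = "trait"
    declared_ancestry: str | None = None
    load_report: LoadReport | None = None

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise SumstatsFormatError(
                f"cohort {self.cohort_id}: missing columns {missing}"
            )
        if self.table["snp_id"].duplicated().any():
            raise SumstatsFormatError(
                f"cohort {self.cohort_id}: duplicated SNP ids"
            )
        self.table = (
            self.table[COLUMNS]
            .sort_values(["chrom", "bp"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_median(self) -> int:
        return int(np.median(self.table["n"]))

    def subset(self, snp_ids) -> "CohortSummary":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return CohortSummary(
            cohort_id=self.cohort_id,
            table=self.table[keep].copy(),
            trait=self.trait,
            declared_ancestry=self.declared_ancestry,
        )


@dataclass
class AlignedPair:
    """Allele-harmonised arrays for the SNPs shared by two cohorts.

    All arrays have equal length; cohort 2's effect sign and frequency are
    expressed on cohort 1's effect allele.
    """

    cohort1_id: str
    cohort2_id: str
    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    freq1: np.ndarray
    n1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    freq2: np.ndarray
    n2: np.ndarray
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, mask_or_ids) -> "AlignedPair":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = np.isin(self.snp_id, arr)
        return AlignedPair(
            self.cohort1_id,
            self.cohort2_id,
            self.snp_id[mask],
            self.chrom[mask],
            self.bp[mask],
            self.beta1[mask],
            self.se1[mask],
            self.freq1[mask],
            self.n1[mask],
            self.beta2[mask],
            self.se2[mask],
            self.freq2[mask],
            self.n2[mask],
            self.n_dropped_ambiguous,
            self.n_dropped_mismatch,
        )


def _validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    report = LoadReport(n_rows=len(df))
    df = df.copy()
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    df["bp"] = pd.to_numeric(df["bp"], errors="coerce")
    for col in ("freq_a1", "beta", "se", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    checks = {
        "invalid allele": ~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES)),
        "a1 == a2": df["a1"] == df["a2"],
        "bad position": ~(df["bp"] > 0),
        "non-positive se": df["se"].notna() & ~(df["se"] > 0),
        "frequency outside [0,1]": df["freq_a1"].notna()
        & ~df["freq_a1"].between(0.0, 1.0),
        "bad sample size": ~(df["n"] >= 1),
        "missing id": df["snp_id"].isna() | (df["snp_id"].astype(str) == ""),
    }
    bad = np.zeros(len(df), dtype=bool)
    for reason, mask in checks.items():
        mask = mask.to_numpy(dtype=bool)
        new = mask & ~bad
        if new.any():
            report.dropped[reason] = int(new.sum())
        bad |= mask
    out = df[~bad].copy()
    out["snp_id"] = out["snp_id"].astype(str)
    out["chrom"] = out["chrom"].astype(str)
    out["bp"] = out["bp"].astype(np.int64)
    report.n_kept = len(out)
    return out, report


def read_sumstats(
    path,
    column_map: dict | None = None,
    cohort_id: str | None = None,
    trait: str = "trait",
    declared_ancestry: str | None = None,
) -> CohortSummary:
    """Load one summary-statistics table, validating and dropping bad rows.

    ``column_map`` maps internal field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to header names in the file; unmapped fields
    fall back to the defaults.  The returned cohort carries a
    :class:`LoadReport` describing rejected rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, sep=r"\s+", comment="#", dtype={cmap["chrom"]: str})
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc

    missing = [
        cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in raw.columns
    ]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory columns {missing}")

    df = pd.DataFrame({field: raw[cmap[field]] if cmap[field] in raw.columns
                       else np.nan for field in COLUMNS})
    clean, report = _validate_table(df)
    if len(clean) == 0:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    if report.n_rejected:
        logger.info("%s: %s", path, report.summary().replace("\n", "; "))
    if cohort_id is None:
        cohort_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return CohortSummary(
        cohort_id=cohort_id,
        table=clean,
        trait=trait,
        declared_ancestry=declared_ancestry,
        load_report=report,
    )


def write_sumstats(cohort: CohortSummary, path, header_comment: str | None = None):
    """Write a cohort back to the default tab-delimited layout.

    Floats are printed with 17 significant digits so a write/read round trip
    reproduces every value bit-exactly.
    """
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out = cohort.table.rename(columns=DEFAULT_COLUMN_MAP)
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def harmonize_pair(
    c1: CohortSummary, c2: CohortSummary, drop_ambiguous: bool = True
) -> AlignedPair:
    """Align two cohorts' records on shared SNPs to cohort 1's effect allele.

    Where cohort 2 reports the allele pair swapped (or strand-flipped and
    swapped) its effect sign is flipped and its frequency becomes ``1 - p``.
    Strand-ambiguous markers are dropped when ``drop_ambiguous`` is set;
    irreconcilable allele pairs are always dropped and counted.
    """
    merged = c1.table.merge(
        c2.table, on="snp_id", suffixes=("_1", "_2"), how="inner"
    )
    if merged.empty:
        raise EmptyOverlapError(
            f"no shared SNPs between {c1.cohort_id} and {c2.cohort_id}"
        )
    a1_1 = merged["a1_1"].to_numpy(dtype=object)
    a2_1 = merged["a2_1"].to_numpy(dtype=object)
    a1_2 = merged["a1_2"].to_numpy(dtype=object)
    a2_2 = merged["a2_2"].to_numpy(dtype=object)

    comp = np.vectorize(_COMPLEMENT.get, otypes=[object])
    c_a1_2, c_a2_2 = comp(a1_2), comp(a2_2)

    same = (a1_2 == a1_1) & (a2_2 == a2_1)
    swapped = (a1_2 == a2_1) & (a2_2 == a1_1)
    strand_same = (c_a1_2 == a1_1) & (c_a2_2 == a2_1)
    strand_swapped = (c_a1_2 == a2_1) & (c_a2_2 == a1_1)

    ambiguous = is_palindromic(a1_1, a2_1)
    keep_same = same | (strand_same & ~same)
    keep_flip = (swapped | strand_swapped) & ~keep_same
    resolvable = keep_same | keep_flip
    if drop_ambiguous:
        keep = resolvable & ~ambiguous
        n_ambiguous = int((resolvable & ambiguous).sum())
    else:
        keep = resolvable
        n_ambiguous = 0
    n_mismatch = int((~resolvable).sum())

    sub = merged[keep]
    flip = keep_flip[keep]
    beta2 = sub["beta_2"].to_numpy(float).copy()
    freq2 = sub["freq_a1_2"].to_numpy(float).copy()
    beta2[flip] = -beta2[flip]
    freq2[flip] = 1.0 - freq2[flip]

    return AlignedPair(
        cohort1_id=c1.cohort_id,
        cohort2_id=c2.cohort_id,
        snp_id=sub["snp_id"].to_numpy(dtype=object),
        chrom=sub["chrom_1"].to_numpy(dtype=object),
        bp=sub["bp_1"].to_numpy(np.int64),
        beta1=sub["beta_1"].to_numpy(float),
        se1=sub["se_1"].to_numpy(float),
        freq1=sub["freq_a1_1"].to_numpy(float),
        n1=sub["n_1"].to_numpy(float),
        beta2=beta2,
        se2=sub["se_2"].to_numpy(float),
        freq2=freq2,
        n2=sub["n_2"].to_numpy(float),
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_mismatch=n_mismatch,
    )


def prune_independent(
    cohort: CohortSummary,
    target_m: int = 30_000,
    min_gap_bp: int = 100_000,
    seed: int = 2016,
) -> np.ndarray:
    """Thin a cohort to approximately independent markers.

    Markers are visited in a seeded random order and accepted while no
    previously accepted marker on the same chromosome lies within
    ``min_gap_bp``, until ``target_m`` markers are selected.  With unlinked
    or well-spaced markers this is uniform random subsampling; in dense
    regions it enforces a physical spacing as a proxy for linkage
    equilibrium when genotype data are unavailable.

    Returns the selected SNP ids in genomic order, deterministically for a
    given seed.
    """
    if target_m < 1:
        raise ValueError("target_m must be >= 1")
    import bisect

    tab = cohort.table
    chroms = tab["chrom"].to_numpy(dtype=object)
    bps = tab["bp"].to_numpy(np.int64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tab))
    accepted_bp: dict[str, list[int]] = {}
    accepted_idx = []
    for i in order:
        ch, bp = chroms[i], int(bps[i])
        lst = accepted_bp.setdefault(ch, [])
        j = bisect.bisect_left(lst, bp)
        if j > 0 and bp - lst[j - 1] < min_gap_bp:
            continue
        if j < len(lst) and lst[j] - bp < min_gap_bp:
            continue
        bisect.insort(lst, bp)
        accepted_idx.append(i)
        if len(accepted_idx) == target_m:
            break
    if len(accepted_idx) < target_m:
        warnings.warn(
            f"prune_independent: only {len(accepted_idx)} of the requested "
            f"{target_m} markers satisfy the {min_gap_bp} bp spacing",
            stacklevel=2,
        )
    idx = np.sort(np.asarray(accepted_idx, dtype=np.int64))
    return tab["snp_id"].to_numpy(dtype=object)[idx]
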