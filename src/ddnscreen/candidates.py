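"""Per-subtype candidate (driver) gene selection.

Candidate genes for a disease subtype are genes that are both

* significantly copy-number aberrant in the subtype -- a G-score style
  statistic (aberration frequency x mean amplitude) screened by a
  two-sided Fisher's exact test with Benjamini-Hochberg control, after
  excluding genes carrying common germline copy-number variants
  ("CNA but no CNV"); and
* among the top differentially expressed genes, ranked by the
  chi-square statistic of equal-frequency expression bins against the
  subtype-vs-rest split.

If the aberration screen yields N genes, the expression ranking
contributes its top N, and the candidate set is the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CohortMatrices:
    """Copy-number log-ratios and expression, genes x samples, plus labels."""

    copy_number: pd.DataFrame
    expression: pd.DataFrame
    labels: pd.Series  # sample -> subtype id

    def __post_init__(self) -> None:
        cn_samples = set(self.copy_number.columns)
        ge_samples = set(self.expression.columns)
        if cn_samples != ge_samples:
            raise ValueError("copy-number and expression sample sets differ")
        self.labels = pd.Series(self.labels)
        if not cn_samples <= set(self.labels.index):
            raise ValueError("labels do not cover all samples")
        self.labels = self.labels.loc[self.copy_number.columns]
        if self.labels.nunique() < 2:
            raise ValueError("need at least 2 distinct subtypes")
        # keep the two matrices on one sample order
        self.expression = self.expression[self.copy_number.columns]

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.labels.unique())

    def collapse_one_vs_rest(self, subtype: str) -> "CohortMatrices":
        """Relabel to {subtype, 'rest'} for one-vs-rest (e.g. TN) analyses."""
        labels = self.labels.where(self.labels == subtype, other="rest")
        return CohortMatrices(self.copy_number, self.expression, labels)


@dataclass(frozen=True)
class GeneAberrationStats:
    gene: str
    g_score: float
    p_value: float
    aberrant_count_in: int
    aberrant_count_out: int


@dataclass(frozen=True)
class GeneRankRecord:
    gene: str
    chi2_statistic: float
    rank: int


@dataclass
class CandidateGeneSet:
    """Intersection of the aberration set and the expression top-N."""

    subtype: str
    genes: frozenset[str]
    n_cna: int
    provenance: dict[str, dict[str, bool]] = field(default_factory=dict)
    cna_genes: frozenset[str] = frozenset()
    ge_genes: frozenset[str] = frozenset()


def gscore(
    copy_number_row: Iterable[float],
    amp_threshold: float = 0.5,
) -> tuple[float, int]:
    """G-score of one gene over the subtype samples.

    A sample is aberrant iff |log-ratio| >= amp_threshold.  The score is
    (aberrant fraction) x (mean |log-ratio| over aberrant samples); 0
    when nothing is aberrant.  Returns (g_score, aberrant_count).
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    values = np.asarray(list(copy_number_row), dtype=float)
    if values.size == 0:
        raise ValueError("empty subtype sample set")
    amp = np.abs(values)
    aberrant = amp >= amp_threshold
    count = int(aberrant.sum())
    if count == 0:
        return 0.0, 0
    return float(count / values.size * amp[aberrant].mean()), count


def aberration_significance(
    aberrant_in: int, n_in: int, aberrant_out: int, n_out: int
) -> float:
    """Two-sided Fisher's exact p for the aberrant x subtype 2x2 table."""
    if n_in <= 0 or n_out <= 0:
        raise ValueError("both groups must be nonempty")
    if not (0 <= aberrant_in <= n_in and 0 <= aberrant_out <= n_out):
        raise ValueError("aberrant counts exceed group sizes")
    table = [[aberrant_in, n_in - aberrant_in], [aberrant_out, n_out - aberrant_out]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def filter_common_variants(genes: Iterable[str], common_variant_genes: Iterable[str]):
    """Drop genes whose copy-number signal may be a common germline CNV."""
    return set(genes) - set(common_variant_genes)


def chi2_rank(
    expression: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    subtype: str,
    n_bins: int = 3,
) -> list[GeneRankRecord]:
    """Rank genes by chi-square of binned expression vs subtype-vs-rest.

    Expression is discretised per gene into ``n_bins`` equal-frequency
    bins over all samples; the Pearson chi-square statistic of the
    bins x (in subtype / rest) contingency table ranks genes descending,
    ties broken by gene symbol.  Constant genes score 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    labels = pd.Series(labels).loc[expression.columns]
    in_subtype = (labels == subtype).to_numpy()
    if in_subtype.sum() == 0:
        raise ValueError(f"subtype {subtype!r} has no samples")
    records = []
    for gene, row in expression.iterrows():
        values = row.to_numpy(dtype=float)
        stat = 0.0
        if np.unique(values).size > 1:
            bins = pd.qcut(values, n_bins, labels=False, duplicates="drop")
            table = pd.crosstab(bins, in_subtype).to_numpy()
            if table.shape[0] >= 2 and table.shape[1] >= 2:
                stat = float(stats.chi2_contingency(table, correction=False)[0])
        records.append((gene, stat))
    records.sort(key=lambda gs: (-gs[1], gs[0]))
    return [
        GeneRankRecord(gene=g, chi2_statistic=s, rank=i)
        for i, (g, s) in enumerate(records, start=1)
    ]


def aberration_stats(
    cohort: CohortMatrices,
    subtype: str,
    amp_threshold: float = 0.5,
) -> list[GeneAberrationStats]:
    """G-score + Fisher p per gene for one subtype (no variant filter)."""
    in_mask = (cohort.labels == subtype).to_numpy()
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in == 0:
        raise ValueError(f"subtype {subtype!r} has no samples")
    cn = cohort.copy_number.to_numpy(dtype=float)
    aberrant = np.abs(cn) >= amp_threshold
    out = []
    for i, gene in enumerate(cohort.copy_number.index):
        a_in = int(aberrant[i, in_mask].sum())
        a_out = int(aberrant[i, ~in_mask].sum())
        g, _ = gscore(cn[i, in_mask], amp_threshold)
        p = aberration_significance(a_in, n_in, a_out, n_out)
        out.append(GeneAberrationStats(gene, g, p, a_in, a_out))
    return out


def select_candidates(
    cohort: CohortMatrices,
    variants: Iterable[str],
    subtype: str,
    amp_threshold: float = 0.5,
    alpha: float = 0.05,
    n_bins: int = 3,
    adjust: str = "fdr_bh",
) -> CandidateGeneSet:
    """Intersect the significant-aberration set with the expression top-N.

    The aberration (CNA) set is computed after removing common-variant
    genes: Fisher p adjusted by ``adjust`` ("fdr_bh" default, "none" for
    raw p) must be <= alpha, the in-subtype aberration frequency must
    exceed the out-of-subtype frequency, and the G-score must be > 0.
    N = |CNA set| then caps the chi-square expression ranking.
    """
    if subtype not in set(cohort.labels):
        raise ValueError(f"subtype {subtype!r} not in labels")
    stats_all = aberration_stats(cohort, subtype, amp_threshold)
    variant_set = set(variants)
    testable = [s for s in stats_all if s.gene not in variant_set]
    in_mask = (cohort.labels == subtype).to_numpy()
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    cna: set[str] = set()
    if testable:
        pvals = np.array([s.p_value for s in testable])
        if adjust == "none":
            significant = pvals <= alpha
        else:
            significant = multipletests(pvals, alpha=alpha, method=adjust)[0]
        for s, sig in zip(testable, significant):
            enriched = s.aberrant_count_in / n_in > s.aberrant_count_out / n_out
            if sig and enriched and s.g_score > 0:
                cna.add(s.gene)
    n_cna = len(cna)
    if n_cna == 0:
        logger.warning("subtype %s: no significant aberration genes", subtype)
        return CandidateGeneSet(subtype, frozenset(), 0)
    ranking = chi2_rank(cohort.expression, cohort.labels, subtype, n_bins)
    ge = {r.gene for r in ranking[:n_cna]}
    genes = cna & ge
    provenance = {
        g: {"from_cna": g in cna, "from_ge": g in ge} for g in sorted(cna | ge)
    }
    return CandidateGeneSet(
        subtype=subtype,
        genes=frozenset(genes),
        n_cna=n_cna,
        provenance=provenance,
        cna_genes=frozenset(cna),
        ge_genes=frozenset(ge),
    )


def write_candidates_tsv(cands: CandidateGeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tsubtype\tcandidate\tfrom_cna\tfrom_ge\n")
        for gene in sorted(cands.provenance):
            prov = cands.provenance[gene]
            fh.write(
                f"{gene}\t{cands.subtype}\t{int(gene in cands.genes)}"
                f"\t{int(prov['from_cna'])}\t{int(prov['from_ge'])}\n"
            )
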