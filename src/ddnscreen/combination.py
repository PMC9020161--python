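"""Drug-pair screening under the additive z-score assumption.

Every unordered pair of conditions from two distinct drugs is combined
by summing z-scores on shared genes, scored exactly like a single drug
(top-k combined genes -> shortest-path network -> Pearson r), and
compared against the two single-condition scores.  Pairs with a known
drug--drug interaction at a blocked severity are removed *after*
scoring (post-verification), so the interaction table can be updated
without recomputing scores.  The headline report keeps pairs whose
combined score is more negative than the best single drug, capped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .pathway import UnifiedPathwayGraph
from .perturbation import (
    DiseaseSignature,
    PerturbationProfile,
    ProfileKey,
    combine_profiles,
)
from .scoring import RepurposingScore, rank_drugs, score_profile

logger = logging.getLogger(__name__)

SEVERITIES = ("minor", "moderate", "major")


@dataclass(frozen=True)
class InteractionTable:
    """Known drug--drug interactions as unordered id pairs with severity."""

    severities: Mapping[frozenset[str], str]

    def __post_init__(self) -> None:
        for pair, sev in self.severities.items():
            if len(pair) != 2:
                raise ValueError(f"self-pair or malformed pair {set(pair)}")
            if sev not in SEVERITIES:
                raise ValueError(f"unknown severity {sev!r}")

    def severity(self, drug1: str, drug2: str) -> str | None:
        return self.severities.get(frozenset({drug1, drug2}))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTable":
        sev: dict[frozenset[str], str] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["drug1", "drug2", "severity"]:
                raise ValueError(f"{path}: expected header drug1, drug2, severity")
            for line in fh:
                if not line.strip():
                    continue
                d1, d2, s = line.rstrip("\n").split("\t")[:3]
                sev[frozenset({d1, d2})] = s
        return cls(sev)

    @classmethod
    def empty(cls) -> "InteractionTable":
        return cls({})


@dataclass
class PairScoreRecord:
    """One scored pair plus its components' scores and all three ranks."""

    drug1_key: ProfileKey
    drug2_key: ProfileKey
    combined_r: float
    single_r1: float | None
    single_r2: float | None
    combined_rank: int
    rank1: int | None
    rank2: int | None
    n_genes_scored: int

    @property
    def drug_ids(self) -> frozenset[str]:
        return frozenset({self.drug1_key[0], self.drug2_key[0]})


@dataclass
class PairScreenResult:
    records: list[PairScoreRecord]
    single_scores: list[RepurposingScore]
    removed: list[tuple[PairScoreRecord, str]] = field(default_factory=list)
    n_undefined_pairs: int = 0
    n_disjoint_pairs: int = 0


def screen_pairs(
    profiles: Sequence[PerturbationProfile],
    signature: DiseaseSignature,
    ughp: UnifiedPathwayGraph,
    disease_genes: Iterable[str],
    k: int = 50,
    interaction_table: InteractionTable | None = None,
    blocked_severities: frozenset[str] = frozenset(SEVERITIES),
    directed: bool = False,
) -> PairScreenResult:
    """Score every unordered cross-drug pair of conditions.

    Singles are scored first (they supply single_r and rank columns),
    then each pair's additive profile goes through the same top-k /
    network / correlation path.  Pairs of two conditions of the same
    drug are skipped, as are pairs with no shared genes or an undefined
    combined score (both counted).  If an interaction table is given the
    records are interaction-filtered before being returned.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to screen pairs")
    disease_genes = sorted(set(disease_genes))
    singles = [
        score_profile(ughp, p, signature, disease_genes, k=k, directed=directed)
        for p in profiles
    ]
    single_rank = {s.drug_key: i for i, s in enumerate(rank_drugs(singles), start=1)}
    single_r = {s.drug_key: s.r for s in singles}

    scored: list[tuple[tuple, RepurposingScore]] = []
    n_undef = n_disjoint = 0
    for p1, p2 in itertools.combinations(sorted(profiles, key=lambda p: p.key), 2):
        if p1.drug_id == p2.drug_id:
            continue
        try:
            combined = combine_profiles(p1, p2)
        except ValueError:
            n_disjoint += 1
            continue
        s = score_profile(ughp, combined, signature, disease_genes, k=k, directed=directed)
        if not s.defined:
            n_undef += 1
            continue
        scored.append(((p1.key, p2.key), s))
    scored.sort(key=lambda ks: (ks[1].r, ks[0]))
    records = []
    for rank, ((k1, k2), s) in enumerate(scored, start=1):
        records.append(
            PairScoreRecord(
                drug1_key=k1,
                drug2_key=k2,
                combined_r=s.r,
                single_r1=single_r.get(k1),
                single_r2=single_r.get(k2),
                combined_rank=rank,
                rank1=single_rank.get(k1),
                rank2=single_rank.get(k2),
                n_genes_scored=s.n_genes_scored,
            )
        )
    result = PairScreenResult(
        records=records,
        single_scores=singles,
        n_undefined_pairs=n_undef,
        n_disjoint_pairs=n_disjoint,
    )
    if interaction_table is not None:
        result.records, result.removed = filter_interactions(
            records, interaction_table, blocked_severities
        )
    return result


def filter_interactions(
    records: Sequence[PairScoreRecord],
    table: InteractionTable,
    blocked_severities: Iterable[str] = SEVERITIES,
) -> tuple[list[PairScoreRecord], list[tuple[PairScoreRecord, str]]]:
    """Drop pairs listed in the interaction table at a blocked severity.

    Returns (kept, removed-with-severity).  A flagged pair whose
    severity is not blocked is retained with a warning.
    """
    blocked = frozenset(blocked_severities)
    kept, removed = [], []
    for rec in records:
        ids = sorted(rec.drug_ids)
        sev = table.severity(*ids) if len(ids) == 2 else None
        if sev is None:
            kept.append(rec)
        elif sev in blocked:
            removed.append((rec, sev))
            logger.info("removed pair %s + %s (%s interaction)", ids[0], ids[1], sev)
        else:
            kept.append(rec)
            logger.warning(
                "pair %s + %s has %s interaction (severity not blocked); retained",
                ids[0], ids[1], sev,
            )
    return kept, removed


def pairs_beating_best_single(
    records: Sequence[PairScoreRecord],
    single_scores: Sequence[RepurposingScore],
    cap: int = 100,
) -> list[PairScoreRecord]:
    """Pairs strictly more anti-correlated than the best single drug.

    Sorted most-negative first and truncated to ``cap`` (the report
    keeps at most 100 pairs by default).
    """
    ranked = rank_drugs(single_scores)
    if not ranked:
        raise ValueError("no defined single-drug scores")
    best = ranked[0].r
    better = [r for r in records if r.combined_r < best]
    better.sort(key=lambda r: (r.combined_r, r.drug1_key, r.drug2_key))
    return better[:cap]


def write_pair_report_tsv(records: Sequence[PairScoreRecord], path) -> None:
    """Pair table: drug1, drug2, combined and single correlations + ranks."""

    def fmt(v, spec="{:.6f}"):
        return "NA" if v is None else spec.format(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "drug1\tdose1\ttime1\tdrug2\tdose2\ttime2\t"
            "c_cor\tcor1\tcor2\tc_rank\trank1\trank2\tn_genes_scored\n"
        )
        for r in records:
            d1, dose1, t1 = r.drug1_key
            d2, dose2, t2 = r.drug2_key
            fh.write(
                f"{d1}\t{dose1:g}\t{t1:g}\t{d2}\t{dose2:g}\t{t2:g}\t"
                f"{r.combined_r:.6f}\t{fmt(r.single_r1)}\t{fmt(r.single_r2)}\t"
                f"{r.combined_rank}\t{fmt(r.rank1, '{}')}\t{fmt(r.rank2, '{}')}\t"
                f"{r.n_genes_scored}\n"
            )
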