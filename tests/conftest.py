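"""Shared fixtures: cached synthetic pipeline runs at fixed seeds."""

from __future__ import annotations

import functools
from dataclasses import dataclass

import pytest

import ddnscreen as dd
from ddnscreen import synthetic as syn


@dataclass
class SingleRun:
    """One seeded end-to-end single-drug screen (200-drug library)."""

    seed: int
    ughp: dd.UnifiedPathwayGraph
    truth: syn.GroundTruth
    candidates: dd.CandidateGeneSet
    signature: dd.DiseaseSignature
    scores: list
    ranked: list


def _selected_conditions(profiles):
    by_drug: dict[str, list] = {}
    for p in profiles:
        by_drug.setdefault(p.drug_id, []).append(p)
    return [p for d in sorted(by_drug) for p in dd.select_conditions(by_drug[d])]


@functools.lru_cache(maxsize=None)
def single_run(seed: int) -> SingleRun:
    ughp = dd.build_ughp(syn.generate_pathways(seed=seed))
    cohort, variants, truth = syn.generate_cohort(seed=seed + 1)
    cands = dd.select_candidates(cohort, variants, truth.driver_subtype)
    signature = dd.normalize_signature(
        cohort.expression, cohort.labels, truth.driver_subtype
    )
    profiles, lib_truth = syn.generate_drug_library(
        signature, n_drugs=200, seed=seed + 2
    )
    truth = syn.GroundTruth(
        seed=seed,
        driver_genes=truth.driver_genes,
        decoy_cnv_genes=truth.decoy_cnv_genes,
        driver_subtype=truth.driver_subtype,
        reversal_drug_key=lib_truth.reversal_drug_key,
        complementary_pair=lib_truth.complementary_pair,
    )
    selected = _selected_conditions(profiles)
    scores = [
        dd.score_profile(ughp, p, signature, cands.genes) for p in selected
    ]
    return SingleRun(
        seed=seed, ughp=ughp, truth=truth, candidates=cands,
        signature=signature, scores=scores, ranked=dd.rank_drugs(scores),
    )


@dataclass
class PairRun:
    """One seeded pair screen (40-drug library, no full-reversal drug)."""

    seed: int
    truth: syn.GroundTruth
    result: dd.PairScreenResult
    beats: list


@functools.lru_cache(maxsize=None)
def pair_run(seed: int) -> PairRun:
    base = single_run(seed)
    profiles, lib_truth = syn.generate_drug_library(
        base.signature, n_drugs=40, seed=seed + 2, plant_reversal=False
    )
    selected = _selected_conditions(profiles)
    result = dd.screen_pairs(
        selected, base.signature, base.ughp, base.candidates.genes
    )
    beats = dd.pairs_beating_best_single(result.records, result.single_scores)
    return PairRun(seed=seed, truth=lib_truth, result=result, beats=beats)


@pytest.fixture(scope="session")
def get_single_run():
    return single_run


@pytest.fixture(scope="session")
def get_pair_run():
    return pair_run


@pytest.fixture(scope="session")
def run0() -> SingleRun:
    return single_run(0)
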