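"""Seeded synthetic inputs with known ground truth for every stage.

The generators emulate the structure (not the biology) of the real
inputs the pipeline targets: a collection of signed pathways over a
shared gene universe; a tumour cohort with copy-number log-ratios,
expression and subtype labels, with driver genes planted in one
subtype and decoy common-variant (CNV) genes planted to exercise the
"CNA but no CNV" filter; a perturbation library of per-(drug, dose,
time) z-score profiles with a planted full-reversal drug and a planted
complementary half-reversal pair; and a drug--drug interaction table.

All randomness flows from one integer seed; equal parameters give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .candidates import CohortMatrices
from .pathway import PathwayRecord
from .perturbation import (
    DiseaseSignature,
    PerturbationProfile,
    ProfileKey,
    Z_BOUND,
    normalize_signature,
    write_profiles,
    write_signature,
)

_MOD = 2**31  # sub-seeds stay below 2^31


@dataclass
class GroundTruth:
    """What was planted, so tests can check it is recovered."""

    seed: int
    driver_genes: frozenset[str] = frozenset()
    decoy_cnv_genes: frozenset[str] = frozenset()
    driver_subtype: str = ""
    reversal_drug_key: ProfileKey | None = None
    complementary_pair: tuple[ProfileKey, ProfileKey] | None = None
    blocked_pairs: frozenset[frozenset[str]] = frozenset()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "driver_genes": sorted(self.driver_genes),
            "decoy_cnv_genes": sorted(self.decoy_cnv_genes),
            "driver_subtype": self.driver_subtype,
            "reversal_drug_key": list(self.reversal_drug_key)
            if self.reversal_drug_key
            else None,
            "complementary_pair": [list(k) for k in self.complementary_pair]
            if self.complementary_pair
            else None,
            "blocked_pairs": sorted(sorted(p) for p in self.blocked_pairs),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            seed=d["seed"],
            driver_genes=frozenset(d["driver_genes"]),
            decoy_cnv_genes=frozenset(d["decoy_cnv_genes"]),
            driver_subtype=d["driver_subtype"],
            reversal_drug_key=tuple(d["reversal_drug_key"])
            if d["reversal_drug_key"]
            else None,
            complementary_pair=tuple(tuple(k) for k in d["complementary_pair"])
            if d["complementary_pair"]
            else None,
            blocked_pairs=frozenset(frozenset(p) for p in d["blocked_pairs"]),
        )


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n_genes)]


def generate_pathways(
    n_genes: int = 200,
    n_pathways: int = 12,
    mean_edges: int = 40,
    seed: int = 0,
    activation_prob: float = 0.7,
) -> list[PathwayRecord]:
    """Random signed pathways over a shared gene universe.

    Each pathway draws a node subset, wires it with a random chain (so
    it is connected-ish) plus extra random edges, and signs every edge
    +1 with probability ``activation_prob``, else -1.
    """
    if min(n_genes, n_pathways, mean_edges) <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    universe = np.array(gene_universe(n_genes))
    pathways = []
    for p in range(n_pathways):
        n_edges = max(3, int(rng.poisson(mean_edges)))
        n_nodes = min(n_genes, max(3, int(0.8 * n_edges)))
        members = rng.choice(universe, size=n_nodes, replace=False)
        edges: list[tuple[str, str, int]] = []
        seen: set[tuple[str, str]] = set()

        def add(s: str, t: str) -> None:
            if s != t and (s, t) not in seen:
                sign = 1 if rng.random() < activation_prob else -1
                seen.add((s, t))
                edges.append((s, t, sign))

        chain = rng.permutation(members)
        for a, b in zip(chain[:-1], chain[1:]):
            add(str(a), str(b))
        while len(edges) < n_edges:
            s, t = rng.choice(members, size=2, replace=False)
            add(str(s), str(t))
        pathways.append(
            PathwayRecord(
                pathway_id=f"P{p + 1:02d}", name=f"synthetic pathway {p + 1}",
                edges=tuple(edges),
            )
        )
    return pathways


def generate_cohort(
    n_genes: int = 200,
    n_samples: int = 120,
    subtypes: Sequence[str] = ("S1", "S2", "S3"),
    n_drivers: int = 12,
    n_decoys: int = 5,
    effect_size: float = 1.0,
    expr_effect_scale: float = 8.0,
    seed: int = 0,
) -> tuple[CohortMatrices, set[str], GroundTruth]:
    """Cohort with drivers planted in the first subtype.

    Drivers get a copy-number log-ratio shift of ``effect_size`` (sign
    fixed per gene) and a correlated expression shift of
    ``expr_effect_scale * effect_size`` standard deviations in the
    driver subtype.  Decoy CNV genes get a fixed-amplitude aberration in
    the same subtype but *no* expression shift, and are listed in the
    returned common-variant set together with a few null genes.
    """
    if n_drivers + n_decoys >= n_genes:
        raise ValueError("too many planted genes for the universe")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    samples = [f"T{i:03d}" for i in range(n_samples)]
    labels = pd.Series(
        np.array([subtypes[i % len(subtypes)] for i in range(n_samples)])[
            rng.permutation(n_samples)
        ],
        index=samples,
    )
    target = subtypes[0]
    in_mask = (labels == target).to_numpy()

    planted = rng.choice(n_genes, size=n_drivers + n_decoys, replace=False)
    drivers = [genes[i] for i in planted[:n_drivers]]
    decoys = [genes[i] for i in planted[n_drivers:]]
    signs = {g: (1 if rng.random() < 0.5 else -1) for g in drivers + decoys}

    cn = rng.normal(0.0, 0.15, size=(n_genes, n_samples))
    ge = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    gi = {g: i for i, g in enumerate(genes)}
    for g in drivers:
        cn[gi[g], in_mask] += signs[g] * effect_size
        ge[gi[g], in_mask] += signs[g] * expr_effect_scale * effect_size
    for g in decoys:
        # germline-style CNV: aberrant copy number, expression untouched
        cn[gi[g], in_mask] += signs[g] * 1.0

    background = [g for g in genes if g not in set(drivers) | set(decoys)]
    extra_variants = list(rng.choice(background, size=min(10, len(background)), replace=False))
    variants = set(decoys) | set(str(g) for g in extra_variants)

    cohort = CohortMatrices(
        copy_number=pd.DataFrame(cn, index=genes, columns=samples),
        expression=pd.DataFrame(ge, index=genes, columns=samples),
        labels=labels,
    )
    truth = GroundTruth(
        seed=seed,
        driver_genes=frozenset(drivers),
        decoy_cnv_genes=frozenset(decoys),
        driver_subtype=target,
    )
    return cohort, variants, truth


def generate_drug_library(
    signature: DiseaseSignature,
    n_drugs: int = 200,
    noise_sd: float = 0.5,
    background_sd: float = 2.0,
    seed: int = 0,
    plant_reversal: bool = True,
    plant_pair: bool = True,
    doses: Sequence[float] = (0.04, 10.0),
    times: Sequence[float] = (24.0, 6.0),
    extra_gene_fraction: float = 0.2,
) -> tuple[list[PerturbationProfile], GroundTruth]:
    """Perturbation library with planted reversal drug and pair.

    All drugs share one measured gene universe: the signature's genes
    plus a fraction of extra genes absent from the pathway graph (so
    unmapped-gene handling is exercised).  Background drugs are clipped
    Gaussian noise (sd ``background_sd``).  The planted reversal drug
    has z = -signature + noise (sd ``noise_sd``); the planted pair
    splits the signature genes in two |z|-balanced halves and each
    member reverses one half, leaving the other at noise level.  Every
    drug is emitted at each dose x time condition.
    """
    if n_drugs < 3:
        raise ValueError("need n_drugs >= 3")
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature.z)
    n_extra = int(round(extra_gene_fraction * len(sig_genes)))
    extra_genes = [f"X{i:03d}" for i in range(n_extra)]
    universe = sig_genes + extra_genes
    sig_vec = np.array([signature.z[g] for g in sig_genes])

    # |z|-balanced alternating split for the complementary pair
    by_strength = np.argsort(-np.abs(sig_vec), kind="stable")
    half_a = np.zeros(len(sig_genes), dtype=bool)
    half_a[by_strength[::2]] = True

    def clip(v: np.ndarray) -> np.ndarray:
        return np.clip(v, -Z_BOUND, Z_BOUND)

    def emit(drug_id: str, base: np.ndarray | None, mask: np.ndarray | None = None):
        for dose in doses:
            for t in times:
                noise = rng.normal(0.0, noise_sd, size=len(universe))
                if base is None:
                    z = clip(rng.normal(0.0, background_sd, size=len(universe)))
                else:
                    z = noise.copy()
                    target = base if mask is None else np.where(mask, base, 0.0)
                    z[: len(sig_genes)] += target
                    z = clip(z)
                profiles.append(
                    PerturbationProfile(
                        drug_id=drug_id, dose=float(dose), time_h=float(t),
                        z={g: float(v) for g, v in zip(universe, z)},
                    )
                )

    profiles: list[PerturbationProfile] = []
    for i in range(n_drugs):
        emit(f"DRUG{i:03d}", None)
    reversal_key = pair_keys = None
    if plant_reversal:
        emit("REVDRUG", -sig_vec)
        reversal_key = ("REVDRUG", float(min(doses)), 24.0)
    if plant_pair:
        emit("PAIRDRUG-A", -sig_vec, half_a)
        emit("PAIRDRUG-B", -sig_vec, ~half_a)
        pair_keys = (
            ("PAIRDRUG-A", float(min(doses)), 24.0),
            ("PAIRDRUG-B", float(min(doses)), 24.0),
        )
    truth = GroundTruth(
        seed=seed, reversal_drug_key=reversal_key, complementary_pair=pair_keys
    )
    return profiles, truth


def generate_interactions(
    drug_ids: Sequence[str],
    n_random: int = 15,
    seed: int = 0,
    forced_pairs: Sequence[tuple[str, str, str]] = (),
) -> tuple[dict[frozenset[str], str], frozenset[frozenset[str]]]:
    """Random interaction table over the given drug ids.

    ``forced_pairs`` (drug1, drug2, severity) are always included.
    Returns the severity map and the set of blocked (all-severity) pairs.
    """
    rng = np.random.default_rng(seed)
    severities = {}
    ids = sorted(set(drug_ids))
    for d1, d2, sev in forced_pairs:
        severities[frozenset({d1, d2})] = sev
    attempts = 0
    while len(severities) < n_random + len(forced_pairs) and attempts < 50 * n_random:
        attempts += 1
        d1, d2 = rng.choice(ids, size=2, replace=False)
        pair = frozenset({str(d1), str(d2)})
        if pair not in severities:
            severities[pair] = ["minor", "moderate", "major"][int(rng.integers(3))]
    return severities, frozenset(severities)


def write_cohort(cohort: CohortMatrices, outdir: str | Path) -> None:
    outdir = Path(outdir)
    cohort.copy_number.round(6).to_csv(outdir / "copy_number.tsv", sep="\t")
    cohort.expression.round(6).to_csv(outdir / "expression.tsv", sep="\t")
    cohort.labels.rename("subtype").to_csv(outdir / "labels.tsv", sep="\t")


def load_cohort(indir: str | Path) -> CohortMatrices:
    indir = Path(indir)
    cn = pd.read_csv(indir / "copy_number.tsv", sep="\t", index_col=0)
    ge = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col=0)["subtype"]
    return CohortMatrices(cn, ge, labels)


def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 200,
    n_pathways: int = 12,
    mean_edges: int = 40,
    n_samples: int = 120,
    subtypes: Sequence[str] = ("S1", "S2", "S3"),
    n_drivers: int = 12,
    n_decoys: int = 5,
    effect_size: float = 1.0,
    n_drugs: int = 60,
    noise_sd: float = 0.5,
    plant_reversal: bool = True,
    plant_pair: bool = True,
) -> GroundTruth:
    """Write a complete, mutually consistent input bundle to ``outdir``.

    Layout: pathways/*.tsv, copy_number.tsv, expression.tsv, labels.tsv,
    variants.txt, profiles.tsv, interactions.tsv, signature.tsv (the
    driver subtype's signature, for reference), truth.json, manifest.yaml.
    """
    outdir = Path(outdir)
    (outdir / "pathways").mkdir(parents=True, exist_ok=True)
    params = {k: v for k, v in locals().items() if k not in {"outdir"}}
    params["subtypes"] = list(subtypes)

    pathways = generate_pathways(n_genes, n_pathways, mean_edges, seed=seed % _MOD)
    for pw in pathways:
        with open(outdir / "pathways" / f"{pw.pathway_id}.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# {pw.name}\n")
            for s, t, sign in pw.edges:
                fh.write(f"{s}\t{t}\t{sign:+d}\n")

    cohort, variants, cohort_truth = generate_cohort(
        n_genes, n_samples, subtypes, n_drivers, n_decoys, effect_size,
        seed=(seed + 1) % _MOD,
    )
    write_cohort(cohort, outdir)
    (outdir / "variants.txt").write_text(
        "".join(f"{g}\n" for g in sorted(variants)), encoding="utf-8"
    )

    signature = normalize_signature(
        cohort.expression, cohort.labels, cohort_truth.driver_subtype
    )
    write_signature(signature, outdir / "signature.tsv")

    profiles, lib_truth = generate_drug_library(
        signature, n_drugs=n_drugs, noise_sd=noise_sd, seed=(seed + 2) % _MOD,
        plant_reversal=plant_reversal, plant_pair=plant_pair,
    )
    write_profiles(profiles, outdir / "profiles.tsv")

    drug_ids = sorted({p.drug_id for p in profiles})
    severities, blocked = generate_interactions(
        drug_ids, n_random=15, seed=(seed + 3) % _MOD
    )
    with open(outdir / "interactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug1\tdrug2\tseverity\n")
        for pair in sorted(severities, key=sorted):
            d1, d2 = sorted(pair)
            fh.write(f"{d1}\t{d2}\t{severities[pair]}\n")

    truth = dataclasses.replace(
        cohort_truth,
        reversal_drug_key=lib_truth.reversal_drug_key,
        complementary_pair=lib_truth.complementary_pair,
        blocked_pairs=blocked,
    )
    truth.to_json(outdir / "truth.json")
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(params, sort_keys=True), encoding="utf-8"
    )
    return truth
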