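"""Perturbation profiles and disease signatures.

A perturbation profile holds the gene-level z-scores of one
(drug, dose, time) condition, clipped to [-10, 10] as in level-5
connectivity-map style data: z near 0 means the drug leaves the gene
unchanged, negative/positive means expression goes down/up.  A disease
signature holds the analogous per-subtype z-scores, same bounds and
sign convention, derived here from a cohort expression matrix by a
robust median/MAD contrast against the rest of the cohort.

Drug pairs are modelled as additive: the combined z on a shared gene is
the plain sum of the two single-drug z-scores (not re-clipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_BOUND = 10.0
#: key identifying one profile: (drug_id, dose in umol, time in hours)
ProfileKey = tuple[str, float, float]


@dataclass
class PerturbationProfile:
    drug_id: str
    dose: float
    time_h: float
    z: dict[str, float]

    @property
    def key(self) -> ProfileKey:
        return (self.drug_id, self.dose, self.time_h)

    def __post_init__(self) -> None:
        bad = [g for g, v in self.z.items() if abs(v) > Z_BOUND]
        if bad:
            raise ValueError(f"z out of [-10, 10] for genes {bad[:5]}")


@dataclass
class DiseaseSignature:
    subtype_id: str
    z: dict[str, float]


@dataclass
class CombinedProfile:
    """Additive two-drug profile over the shared gene set (unbounded z)."""

    drug_ids: tuple[str, str]
    component_keys: tuple[ProfileKey, ProfileKey]
    z: dict[str, float]

    @property
    def key(self) -> tuple[ProfileKey, ProfileKey]:
        return self.component_keys


_META_COLS = ["drug_id", "dose", "time_h"]


def load_profiles(path: str | Path) -> list[PerturbationProfile]:
    """Read profiles from TSV (wide: meta columns then gene columns; or
    long: drug_id, dose, time_h, gene, z).  Out-of-bound z are clipped
    (count logged); a duplicate (drug, dose, time) key is an error."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if set(df.columns) == set(_META_COLS + ["gene", "z"]):
        wide = df.pivot_table(
            index=_META_COLS, columns="gene", values="z", aggfunc="first"
        )
        n_rows = len(df.drop_duplicates(_META_COLS))
        if len(df) != len(df.drop_duplicates(_META_COLS + ["gene"])):
            raise ValueError(f"{path}: duplicate (drug, dose, time, gene) rows")
        records = wide.reset_index()
        gene_cols = [c for c in records.columns if c not in _META_COLS]
    else:
        records = df
        gene_cols = [c for c in df.columns if c not in _META_COLS]
        n_rows = len(records.drop_duplicates(_META_COLS))
    if n_rows != len(records):
        raise ValueError(f"{path}: duplicate (drug_id, dose, time_h) key")
    profiles = []
    n_clipped = 0
    for _, row in records.iterrows():
        z = {}
        for g in gene_cols:
            v = row[g]
            if pd.isna(v):
                continue
            v = float(v)
            if abs(v) > Z_BOUND:
                n_clipped += 1
                v = float(np.clip(v, -Z_BOUND, Z_BOUND))
            z[str(g)] = v
        profiles.append(
            PerturbationProfile(
                drug_id=str(row["drug_id"]),
                dose=float(row["dose"]),
                time_h=float(row["time_h"]),
                z=z,
            )
        )
    if n_clipped:
        logger.info("%s: clipped %d z value(s) to [-10, 10]", path, n_clipped)
    profiles.sort(key=lambda p: p.key)
    return profiles


def write_profiles(profiles: Sequence[PerturbationProfile], path: str | Path) -> None:
    """Write profiles in long TSV format (drug_id, dose, time_h, gene, z)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdose\ttime_h\tgene\tz\n")
        for p in sorted(profiles, key=lambda p: p.key):
            for g in sorted(p.z):
                fh.write(f"{p.drug_id}\t{p.dose:g}\t{p.time_h:g}\t{g}\t{p.z[g]:.6g}\n")


def select_conditions(
    profiles: Sequence[PerturbationProfile], preferred_time: float = 24.0
) -> list[PerturbationProfile]:
    """Keep one drug's lowest- and highest-dose profiles at 24 h.

    If a chosen dose has no 24 h measurement, fall back to the drug's
    default time point: its most frequent time across all conditions
    (smallest on ties), then the smallest time present at that dose.
    """
    if not profiles:
        raise ValueError("no profiles given")
    drug_ids = {p.drug_id for p in profiles}
    if len(drug_ids) != 1:
        raise ValueError(f"profiles span multiple drugs: {sorted(drug_ids)}")
    times = sorted(p.time_h for p in profiles)
    counts: dict[float, int] = {}
    for t in times:
        counts[t] = counts.get(t, 0) + 1
    default_time = min(counts, key=lambda t: (-counts[t], t))
    doses = {p.dose for p in profiles}
    kept = []
    for dose in sorted({min(doses), max(doses)}):
        at_dose = {p.time_h: p for p in profiles if p.dose == dose}
        if preferred_time in at_dose:
            kept.append(at_dose[preferred_time])
        elif default_time in at_dose:
            kept.append(at_dose[default_time])
        else:
            kept.append(at_dose[min(at_dose)])
    return kept


def normalize_signature(
    expression: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    subtype: str,
) -> DiseaseSignature:
    """Robust per-gene subtype-vs-rest z, clipped to [-10, 10].

    z = (median_in - median_out) / (1.4826 * MAD_out), where MAD_out is
    the median absolute deviation of the rest-of-cohort samples.  The
    denominator is floored at 1e-6 times the gene's dynamic range to
    avoid division by zero; a gene with zero range scores 0.  Positive z
    means the gene is higher in the subtype.
    """
    labels = pd.Series(labels).loc[expression.columns]
    in_mask = (labels == subtype).to_numpy()
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need >= 3 samples in the subtype and in the rest")
    X = expression.to_numpy(dtype=float)
    med_in = np.median(X[:, in_mask], axis=1)
    out = X[:, ~in_mask]
    med_out = np.median(out, axis=1)
    mad_out = np.median(np.abs(out - med_out[:, None]), axis=1)
    dynamic_range = X.max(axis=1) - X.min(axis=1)
    denom = np.maximum(1.4826 * mad_out, 1e-6 * dynamic_range)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (med_in - med_out) / np.where(denom > 0, denom, 1), 0.0)
    z = np.clip(z, -Z_BOUND, Z_BOUND)
    return DiseaseSignature(
        subtype_id=subtype, z={g: float(v) for g, v in zip(expression.index, z)}
    )


def load_signature(path: str | Path, subtype_id: str | None = None) -> DiseaseSignature:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "z"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene, z")
    if subtype_id is None:
        subtype_id = str(df["subtype"].iloc[0]) if "subtype" in df.columns else Path(path).stem
    return DiseaseSignature(
        subtype_id=subtype_id,
        z={str(g): float(np.clip(v, -Z_BOUND, Z_BOUND)) for g, v in zip(df["gene"], df["z"])},
    )


def write_signature(sig: DiseaseSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tz\tsubtype\n")
        for g in sorted(sig.z):
            fh.write(f"{g}\t{sig.z[g]:.6g}\t{sig.subtype_id}\n")


def select_drug_genes(
    profile: PerturbationProfile | CombinedProfile, k: int = 50
) -> list[str]:
    """Top-k genes by |z|, descending, ties broken by gene symbol."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not profile.z:
        raise ValueError("empty profile")
    ordered = sorted(profile.z, key=lambda g: (-abs(profile.z[g]), g))
    return ordered[: min(k, len(ordered))]


def combine_profiles(
    p1: PerturbationProfile, p2: PerturbationProfile
) -> CombinedProfile:
    """Additive combination over the shared gene set (no re-clipping)."""
    shared = set(p1.z) & set(p2.z)
    if not shared:
        raise ValueError(
            f"profiles {p1.key} and {p2.key} share no genes"
        )
    first, second = sorted((p1, p2), key=lambda p: p.key)
    return CombinedProfile(
        drug_ids=(first.drug_id, second.drug_id),
        component_keys=(first.key, second.key),
        z={g: p1.z[g] + p2.z[g] for g in shared},
    )
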