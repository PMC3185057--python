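"""Diet summary statistics across evidence sources.

Records come from four evidence sources: W (ethnobotanical reports),
B (browsing signs), D (macroscopic fruit residues in dung) and G
(genetic identification of dung fibres). The summaries mirror a field
study's reporting: pipeline success rates, per-rank overlap between
sources, monthly fruit diversity per dung pile, fruit-taxon dung-pile
frequencies, and seed-intactness proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SOURCES = ("W", "B", "D", "G")
RANKS = ("species", "genus", "family")


@dataclass(frozen=True)
class DietRecord:
    """One (taxon, evidence source, sample) observation.

    ``species`` and ``genus`` may be None when the taxon was resolved
    only to a coarser rank; ``family`` is always present. ``month`` is
    1-12 for dung records, ``seed_condition`` one of intact / damaged /
    mixed / n/a (fruit items only).
    """

    family: str
    genus: str | None = None
    species: str | None = None
    source: str = "D"
    item: str = "fruit"  # fruit | browse
    sample_id: str | None = None
    month: int | None = None
    seed_condition: str = "n/a"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        if self.item not in ("fruit", "browse"):
            raise ValueError("item must be fruit or browse")
        if self.seed_condition != "n/a" and self.item != "fruit":
            raise ValueError("seed_condition applies to fruit items only")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError("month must be 1-12")

    def taxon_at(self, rank: str) -> str | None:
        return {"species": self.species, "genus": self.genus, "family": self.family}[rank]

    def finest_taxon(self) -> str:
        return self.species or self.genus or self.family


@dataclass(frozen=True)
class PipelineCounts:
    """Particle counts through the molecular pipeline."""

    n_particles: int
    n_amplified: int
    n_sequenced: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_sequenced <= self.n_amplified <= self.n_particles:
            raise ValueError("need n_sequenced <= n_amplified <= n_particles")


def success_rates(counts: PipelineCounts) -> dict:
    """Amplification and sequencing success percentages.

    Returns both integer-rounded percentages (reporting style) and the
    full-precision values. Zero denominators yield None.
    """

    def pct(num, den):
        return 100.0 * num / den if den else None

    amp = pct(counts.n_amplified, counts.n_particles)
    seq_overall = pct(counts.n_sequenced, counts.n_particles)
    seq_success = pct(counts.n_sequenced, counts.n_amplified)
    out = {
        "amplification_pct": amp,
        "sequencing_overall_pct": seq_overall,
        "sequencing_success_pct": seq_success,
    }
    out["rounded"] = {
        k: (round(v) if v is not None else None) for k, v in out.items()
    }
    return out


def _taxa_by_source(
    records: Iterable[DietRecord], rank: str, item: str
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {s: set() for s in SOURCES}
    for r in records:
        if r.item != item:
            continue
        taxon = r.taxon_at(rank)
        if taxon is not None:
            out[r.source].add(taxon)
    return out


def method_overlap(records: Sequence[DietRecord]) -> pd.DataFrame:
    """Per-rank, per-item overlap between evidence sources.

    For each (rank, item): taxa per source, taxa shared by each pair
    of sources and by all sources with any taxa, and the percentage of
    each source's taxa also found by the union of the other sources.
    """
    rows = []
    for item in ("fruit", "browse"):
        for rank in RANKS:
            by_src = _taxa_by_source(records, rank, item)
            active = {s: t for s, t in by_src.items() if t}
            shared_all = set.intersection(*active.values()) if len(active) > 1 else set()
            row = {
                "item": item,
                "rank": rank,
                **{f"n_{s}": len(by_src[s]) for s in SOURCES},
                "n_shared_all": len(shared_all) if len(active) > 1 else 0,
            }
            for i, a in enumerate(SOURCES):
                for b in SOURCES[i + 1 :]:
                    row[f"n_shared_{a}{b}"] = len(by_src[a] & by_src[b])
            for s in SOURCES:
                others = set().union(*(by_src[o] for o in SOURCES if o != s))
                row[f"pct_{s}_found_elsewhere"] = (
                    100.0 * len(by_src[s] & others) / len(by_src[s]) if by_src[s] else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows)


def seasonal_fruit_diversity(
    records: Sequence[DietRecord], sample_sd: bool = True
) -> pd.DataFrame:
    """Monthly mean and SD of distinct fruit taxa per dung pile.

    Restricted to dung fruit-residue records (source D). Months with
    no dung piles are absent from the output. SD is the sample SD
    (ddof=1) by default; a single pile in a month yields SD 0.
    """
    rows = [
        {"month": r.month, "sample_id": r.sample_id, "taxon": r.finest_taxon()}
        for r in records
        if r.source == "D" and r.item == "fruit" and r.month is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["month", "n_piles", "mean_taxa", "sd_taxa"])
    df = pd.DataFrame(rows)
    per_pile = df.groupby(["month", "sample_id"])["taxon"].nunique()
    ddof = 1 if sample_sd else 0

    def sd(x):
        return float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0

    out = per_pile.groupby("month").agg(
        n_piles="count", mean_taxa="mean", sd_taxa=sd
    ).reset_index()
    return out


def taxon_frequency(
    records: Sequence[DietRecord],
    min_family_piles: int = 5,
    min_genus_piles: int = 4,
) -> pd.DataFrame:
    """Dung-pile frequency of fruit families and genera.

    Counts distinct dung piles containing each family and genus among
    dung fruit records, then keeps families present in more than four
    piles and genera in more than three (strict thresholds: a family
    needs >= ``min_family_piles`` piles, a genus >= ``min_genus_piles``).
    """
    rows = [
        {"family": r.family, "genus": r.genus, "sample_id": r.sample_id}
        for r in records
        if r.source == "D" and r.item == "fruit" and r.sample_id is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["rank", "taxon", "family", "n_piles"])
    df = pd.DataFrame(rows)
    fam = (
        df.groupby("family")["sample_id"].nunique().reset_index(name="n_piles")
    )
    fam = fam[fam["n_piles"] >= min_family_piles]
    gen = (
        df.dropna(subset=["genus"])
        .groupby(["family", "genus"])["sample_id"]
        .nunique()
        .reset_index(name="n_piles")
    )
    gen = gen[gen["n_piles"] >= min_genus_piles]
    out = pd.concat(
        [
            fam.assign(rank="family", taxon=fam["family"]),
            gen.assign(rank="genus", taxon=gen["genus"]),
        ],
        ignore_index=True,
    )[["rank", "taxon", "family", "n_piles"]]
    return out.sort_values(["rank", "n_piles", "taxon"], ascending=[True, False, True]).reset_index(
        drop=True
    )


def seed_intactness(records: Sequence[DietRecord]) -> dict:
    """Proportions of dung fruit taxa with sometimes/always intact seeds.

    The denominator is the number of distinct fruit taxa found in dung
    (source D) with a recorded seed condition. "Sometimes intact"
    counts taxa with at least one intact observation (a "mixed" record
    counts as one intact and one damaged observation); "always intact"
    counts taxa whose every observation is intact.
    """
    obs: dict[str, list[str]] = {}
    for r in records:
        if r.source != "D" or r.item != "fruit" or r.seed_condition == "n/a":
            continue
        obs.setdefault(r.finest_taxon(), []).append(r.seed_condition)
    n = len(obs)
    if n == 0:
        return {"n_taxa": 0, "pct_sometimes_intact": None, "pct_always_intact": None}
    sometimes = sum(
        1 for conds in obs.values() if any(c in ("intact", "mixed") for c in conds)
    )
    always = sum(1 for conds in obs.values() if all(c == "intact" for c in conds))
    return {
        "n_taxa": n,
        "pct_sometimes_intact": 100.0 * sometimes / n,
        "pct_always_intact": 100.0 * always / n,
    }


def read_records(path) -> list[DietRecord]:
    """Read diet records from TSV.

    Columns: taxon_species, taxon_genus, taxon_family, source, item,
    sample_id, month, seed_condition. Empty cells become None/"n/a".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():

        def get(col):
            v = row.get(col)
            return None if pd.isna(v) or v == "" else v

        records.append(
            DietRecord(
                family=row["taxon_family"],
                genus=get("taxon_genus"),
                species=get("taxon_species"),
                source=row["source"],
                item=row["item"],
                sample_id=get("sample_id"),
                month=int(float(row["month"])) if get("month") else None,
                seed_condition=get("seed_condition") or "n/a",
            )
        )
    return records


def write_records(records: Sequence[DietRecord], path) -> None:
    df = pd.DataFrame(
        {
            "taxon_species": [r.species for r in records],
            "taxon_genus": [r.genus for r in records],
            "taxon_family": [r.family for r in records],
            "source": [r.source for r in records],
            "item": [r.item for r in records],
            "sample_id": [r.sample_id for r in records],
            "month": [r.month for r in records],
            "seed_condition": [r.seed_condition for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
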