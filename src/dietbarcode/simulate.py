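"""Synthetic reference databases, degraded queries and incidence data.

The downstream stages assume a reference whose pairwise sequence
divergences respect the taxonomic rank of the most recent shared
ancestor: two species of one genus diverge within the genus band,
species of different genera within one family diverge within the
family band, and species of different families diverge beyond the
family threshold. The generator realises these bands exactly by
mutating *disjoint* position sets along the family -> genus -> species
chain, so every pairwise Hamming divergence is the sum of the private
mutation counts on the two paths — the band calibration holds by
construction and is additionally verified by :func:`audit_divergences`.

Queries emulate fragments of chloroplast barcodes recovered from dung
fibres: truncated to a random window, with point substitutions and
short indels (single-base, geometrically extended), optionally drawn
from taxa absent from the reference ("novel").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .align import align_pair
from .seqio import QueryFragment, ReferenceDB

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Degradation:
    """Per-base damage applied to query fragments."""

    substitution_rate: float = 0.001
    indel_rate: float = 0.0
    truncation_range: tuple[int, int] = (100, 400)

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.truncation_range
        if not (0 < lo <= hi):
            raise ValueError("truncation_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and calibration of the synthetic study system.

    The *_band values are target pairwise divergences (fractions):
    species_band is the divergence of a degraded query from its source
    species (must sit under the 0.3% species threshold), genus_band
    the divergence between congeneric species (in (0.3%, 2%]), and
    family_band the divergence between confamilial genera (in
    (2%, 4%]). Cross-family pairs are pushed beyond
    ``novel_divergence``, which is also the divergence of novel-taxon
    queries from their nearest reference relative.
    """

    n_families: int = 3
    genera_per_family: int = 2
    species_per_genus: int = 2
    seq_length: int = 500
    species_band: float = 0.002
    genus_band: float = 0.015
    family_band: float = 0.035
    novel_divergence: float = 0.07
    degradation: Degradation = field(default_factory=Degradation)
    frac_novel: float = 0.0
    n_dung_piles: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.genera_per_family, self.species_per_genus) < 1:
            raise ValueError("taxonomy counts must be >= 1")
        if not (0 < self.species_band < self.genus_band < self.family_band < self.novel_divergence):
            raise ValueError(
                "bands must be nested: species < genus < family < novel divergence"
            )
        if not 0 <= self.frac_novel <= 1:
            raise ValueError("frac_novel must lie in [0, 1]")
        # disjoint-position budget must fit in the sequence
        k_s, k_g, k_f = _mutation_counts(self)
        n_sp = self.n_families * self.genera_per_family * self.species_per_genus
        n_gen = self.n_families * self.genera_per_family
        need = self.n_families * k_f + n_gen * k_g + n_sp * k_s
        if need > self.seq_length - 20:
            raise ValueError(
                f"bands infeasible: {need} private mutation sites needed, "
                f"{self.seq_length - 20} usable positions available"
            )


def _mutation_counts(cfg: SimulationConfig) -> tuple[int, int, int]:
    """Private mutations per species, genus and family branch.

    Chosen so that 2*k_s/L hits the genus band, 2*(k_s+k_g)/L the
    family band and 2*(k_s+k_g+k_f)/L the cross-family divergence.
    """
    L = cfg.seq_length
    k_s = max(1, round(cfg.genus_band * L / 2))
    k_g = max(1, round((cfg.family_band - cfg.genus_band) * L / 2))
    k_f = max(1, round((cfg.novel_divergence - cfg.family_band) * L / 2))
    return k_s, k_g, k_f


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_at(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def generate_reference(config: SimulationConfig) -> ReferenceDB:
    """Generate one barcode sequence per species plus its taxonomy.

    Deterministic under ``config.seed``. Pairwise divergences fall in
    the band of the finest shared rank by construction (disjoint
    mutated positions; see module docstring). Positions within 10
    bases of either end are never mutated so that local alignment
    cannot trim band-defining differences.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    k_s, k_g, k_f = _mutation_counts(config)
    n_gen = config.n_families * config.genera_per_family
    n_sp = n_gen * config.species_per_genus

    root = _random_seq(rng, L)
    pool = rng.permutation(np.arange(10, L - 10))
    need = config.n_families * k_f + n_gen * k_g + n_sp * k_s
    sites = iter(pool[:need])

    def take(k: int) -> np.ndarray:
        return np.array([next(sites) for _ in range(k)], dtype=int)

    records: dict[str, str] = {}
    rows = []
    for fi in range(config.n_families):
        family = f"Fam{fi + 1:02d}"
        fam_seq = _mutate_at(root, take(k_f), rng)
        for gi in range(config.genera_per_family):
            genus = f"{family}-Gen{gi + 1:02d}"
            gen_seq = _mutate_at(fam_seq, take(k_g), rng)
            for si in range(config.species_per_genus):
                species = f"{genus}-Sp{si + 1:02d}"
                sp_seq = _mutate_at(gen_seq, take(k_s), rng)
                seq_id = f"ref-{species}"
                records[seq_id] = "".join(sp_seq)
                rows.append({"seq_id": seq_id, "species": species, "genus": genus, "family": family})
    taxonomy = pd.DataFrame(rows).set_index("seq_id")
    return ReferenceDB(records=records, taxonomy=taxonomy)


def audit_divergences(db: ReferenceDB) -> pd.DataFrame:
    """All-pairs alignment divergences with the rank each pair shares.

    Returns a DataFrame with columns id_a, id_b, shared_rank (genus,
    family or none) and divergence (the alignment mismatch score).
    Used to verify that the realized divergences respect the bands.
    """
    rows = []
    ids = sorted(db.records)
    for a, b in combinations(ids, 2):
        lin_a, lin_b = db.lineage(a), db.lineage(b)
        if lin_a["genus"] == lin_b["genus"]:
            shared = "genus"
        elif lin_a["family"] == lin_b["family"]:
            shared = "family"
        else:
            shared = "none"
        res = align_pair(db.records[a], db.records[b], query_id=a, ref_id=b)
        rows.append(
            {"id_a": a, "id_b": b, "shared_rank": shared,
             "divergence": res.mismatch_score if res else np.nan}
        )
    return pd.DataFrame(rows)


def _apply_degradation(
    seq: str, deg: Degradation, rng: np.random.Generator
) -> str:
    """Truncate to a random window, then substitute and indel."""
    lo, hi = deg.truncation_range
    target = int(rng.integers(lo, hi + 1))
    target = min(target, len(seq))
    start = int(rng.integers(0, len(seq) - target + 1))
    frag = list(seq[start : start + target])

    if deg.substitution_rate > 0:
        n_sub = rng.binomial(len(frag), deg.substitution_rate)
        for p in rng.choice(len(frag), size=n_sub, replace=False):
            frag[p] = [b for b in "ACGT" if b != frag[p]][rng.integers(0, 3)]
    if deg.indel_rate > 0:
        n_indel = rng.binomial(len(frag), deg.indel_rate)
        for _ in range(n_indel):
            length = 1 + rng.geometric(0.5) - 1  # single-base, geometric extension
            p = int(rng.integers(0, len(frag)))
            if rng.random() < 0.5:  # deletion
                del frag[p : p + length]
            else:  # insertion
                ins = _random_seq(rng, length)
                frag[p:p] = list(ins)
            if not frag:
                frag = list(seq[start : start + 1])
    return "".join(frag)


def generate_queries(
    db: ReferenceDB,
    config: SimulationConfig,
    n_queries: int,
) -> list[QueryFragment]:
    """Degraded query fragments with truth labels.

    Each query records its true source species (or "novel" for queries
    drawn from taxa absent from the reference; those are derived from
    a reference sequence mutated by ``config.novel_divergence`` so
    their nearest relative lies beyond the family threshold). Dung
    piles are assigned uniformly at random among ``config.n_dung_piles``.
    Deterministic under ``config.seed``.
    """
    if n_queries <= 0:
        raise ValueError("n_queries must be positive")
    if len(db) == 0:
        raise ValueError("reference database is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = sorted(db.records)
    n_novel = int(round(config.frac_novel * n_queries))
    queries: list[QueryFragment] = []
    for i in range(n_queries):
        novel = i < n_novel
        src_id = ids[rng.integers(0, len(ids))]
        src_seq = db.records[src_id]
        if novel:
            k = max(1, round(config.novel_divergence * len(src_seq)))
            pos = rng.choice(len(src_seq), size=k, replace=False)
            src_seq = "".join(_mutate_at(np.array(list(src_seq)), pos, rng))
            label = "novel"
        else:
            label = db.lineage(src_id)["species"]
        frag = _apply_degradation(src_seq, config.degradation, rng)
        if rng.random() < 0.5:  # unknown strand
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            frag = "".join(comp.get(b, b) for b in reversed(frag))
        pile = f"pile{int(rng.integers(0, config.n_dung_piles)) + 1:02d}"
        queries.append(
            QueryFragment(
                seq_id=f"q{i + 1:04d}",
                sequence=frag,
                dung_pile_id=pile,
                true_taxon=label,
            )
        )
    return queries


def generate_incidence(
    n_samples: int,
    richness: int,
    detection_prob,
    seed: int | None = None,
) -> pd.DataFrame:
    """Random binary samples x taxa incidence matrix.

    ``detection_prob`` is a scalar or a per-taxon vector of Bernoulli
    detection probabilities; cells are independent. Taxa with
    probability 1 appear in every sample.
    """
    if richness <= 0:
        raise ValueError("richness must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    p = np.broadcast_to(np.asarray(detection_prob, dtype=float), (richness,))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("detection probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = (rng.random((n_samples, richness)) < p).astype(int)
    return pd.DataFrame(
        cells,
        index=[f"sample{i + 1:03d}" for i in range(n_samples)],
        columns=[f"taxon{j + 1:03d}" for j in range(richness)],
    )
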