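"""End-to-end orchestration: simulate -> QC -> match -> assign -> cluster -> richness.

One call runs every stage on either simulated or user-supplied data,
writes all stage outputs as plain text under an output directory, and
records a machine-readable manifest (parameters, seeds, per-stage
record counts, truth-label evaluation when available). Re-running
with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import search
from .assign import Assignment, AssignmentThresholds, assign, tally_assignments
from .cluster import ClusteringParams, cluster, min_richness
from .richness import chao2, rarefy
from .seqio import (
    QueryFragment,
    ReferenceDB,
    qc_filter,
    read_queries,
    read_reference,
    write_incidence,
    write_queries,
    write_reference,
)
from .simulate import SimulationConfig, generate_queries, generate_reference
from .summary import PipelineCounts, success_rates


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: str
    # either simulate ...
    simulate: SimulationConfig | None = None
    n_queries: int = 60
    # ... or read from disk
    reference_fasta: str | None = None
    taxonomy_tsv: str | None = None
    queries_fasta: str | None = None

    thresholds: AssignmentThresholds = field(default_factory=AssignmentThresholds)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    min_length: int = 120
    rarefaction_R: int = 500
    chao2_variant: str = "auto"
    cluster_all: bool = False
    seed: int = 0


def _incidence_from_calls(
    assignments: list[Assignment],
    fragments: list[QueryFragment],
    cluster_label: dict[str, str],
) -> pd.DataFrame:
    """Dung-pile x taxon incidence from taxon calls and cluster labels.

    Assigned queries contribute their assigned taxon; unassigned ones
    contribute their divergence cluster (a putative species), so the
    matrix reflects the minimum set of taxa present.
    """
    pile_of = {f.seq_id: f.dung_pile_id for f in fragments}
    cells: set[tuple[str, str]] = set()
    for a in assignments:
        pile = pile_of.get(a.query_id, "")
        taxon = a.assigned_taxon if a.is_assigned else cluster_label.get(a.query_id)
        if taxon and pile:
            cells.add((pile, taxon))
    if not cells:
        return pd.DataFrame()
    piles = sorted({p for p, _ in cells})
    taxa = sorted({t for _, t in cells})
    df = pd.DataFrame(0, index=piles, columns=taxa)
    for p, t in cells:
        df.loc[p, t] = 1
    df.index.name = "sample_id"
    return df


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ---------------------------------------------------------
    if config.simulate is not None:
        db = generate_reference(config.simulate)
        queries = generate_queries(db, config.simulate, config.n_queries)
        write_reference(db, out / "reference.fasta", out / "taxonomy.tsv")
        write_queries(queries, out / "queries.fasta")
    else:
        if not (config.reference_fasta and config.taxonomy_tsv and config.queries_fasta):
            raise ValueError("provide either a simulation config or input paths")
        db = read_reference(config.reference_fasta, config.taxonomy_tsv)
        queries = read_queries(config.queries_fasta, min_length=config.min_length)

    # --- QC -------------------------------------------------------------
    kept, discarded = qc_filter(queries, min_length=config.min_length)

    # --- match + assign --------------------------------------------------
    hit_rows = []
    assignments: list[Assignment] = []
    for q in kept:
        hits = search(q, db)
        for h in hits[:5]:
            hit_rows.append(
                {
                    "query_id": h.query_id, "ref_id": h.ref_id,
                    "mismatch_score": round(h.mismatch_score, 6),
                    "n_mismatches": h.n_mismatches, "n_gap_openings": h.n_gap_openings,
                    "alignment_length": h.alignment_length,
                    "coverage": round(h.coverage, 6), "strand": h.strand,
                }
            )
        a = assign(hits, db, config.thresholds)
        if not hits:
            a.query_id = q.seq_id
        assignments.append(a)
    pd.DataFrame(hit_rows).to_csv(out / "hits.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        {
            "query_id": [a.query_id for a in assignments],
            "assigned_rank": [a.assigned_rank for a in assignments],
            "assigned_taxon": [a.assigned_taxon for a in assignments],
            "best_score": [None if a.best_score is None else round(a.best_score, 6) for a in assignments],
        }
    ).to_csv(out / "assignments.tsv", sep="\t", index=False, lineterminator="\n")

    # --- cluster the unassigned ------------------------------------------
    unassigned_ids = {a.query_id for a in assignments if not a.is_assigned}
    to_cluster = kept if config.cluster_all else [q for q in kept if q.seq_id in unassigned_ids]
    cs = cluster(to_cluster, config.clustering)
    cluster_label = {
        sid: f"cluster{k + 1:03d}" for k, members in enumerate(cs.clusters) for sid in members
    }
    pd.DataFrame(
        sorted(
            ({"cluster_id": lab, "seq_id": sid} for sid, lab in cluster_label.items()),
            key=lambda r: (r["cluster_id"], r["seq_id"]),
        )
    ).to_csv(out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")

    # --- richness ---------------------------------------------------------
    incidence = _incidence_from_calls(assignments, kept, cluster_label)
    richness_summary: dict = {}
    if len(incidence) > 0:
        write_incidence(incidence, out / "incidence.tsv")
        curve = rarefy(incidence, R=config.rarefaction_R, seed=config.seed)
        pd.DataFrame(
            {"t": curve.t, "mean": curve.mean.round(4), "sd": curve.sd.round(4)}
        ).to_csv(out / "accumulation_curve.tsv", sep="\t", index=False, lineterminator="\n")
        est = chao2(incidence, variant=config.chao2_variant)
        richness_summary = {
            "S_obs": est.S_obs, "m": est.m, "Q1": est.Q1, "Q2": est.Q2,
            "S_chao2": round(est.S_chao2, 4),
            "ci_low": round(est.ci_low, 4), "ci_high": round(est.ci_high, 4),
            "variant": est.variant,
        }

    # --- manifest ---------------------------------------------------------
    counts = PipelineCounts(
        n_particles=len(queries), n_amplified=len(queries), n_sequenced=len(kept)
    )
    tallies = tally_assignments(assignments)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "thresholds": asdict(config.thresholds),
            "clustering": asdict(config.clustering),
            "min_length": config.min_length,
            "rarefaction_R": config.rarefaction_R,
            "chao2_variant": config.chao2_variant,
            "cluster_all": config.cluster_all,
            "simulation": asdict(config.simulate) if config.simulate else None,
            "n_queries": config.n_queries if config.simulate else None,
        },
        "counts": {
            "n_particles": counts.n_particles,
            "n_amplified": counts.n_amplified,
            "n_sequenced": counts.n_sequenced,
            "n_discarded_qc": len(discarded),
            "n_reference": len(db),
            "n_clusters": min_richness(cs),
        },
        "success_rates": success_rates(counts)["rounded"],
        "assignment_tallies": tallies,
        "richness": richness_summary,
    }

    # truth evaluation when headers carry labels (synthetic runs)
    labelled = [q for q in kept if q.true_taxon is not None]
    if labelled:
        by_id = {a.query_id: a for a in assignments}
        non_novel = [q for q in labelled if q.true_taxon != "novel"]
        correct = sum(
            1
            for q in non_novel
            if by_id[q.seq_id].assigned_rank == "species"
            and by_id[q.seq_id].assigned_taxon == q.true_taxon
        )
        novel = [q for q in labelled if q.true_taxon == "novel"]
        novel_unassigned = sum(1 for q in novel if not by_id[q.seq_id].is_assigned)
        manifest["truth_evaluation"] = {
            "n_non_novel": len(non_novel),
            "species_accuracy": round(correct / len(non_novel), 4) if non_novel else None,
            "n_novel": len(novel),
            "novel_unassigned": novel_unassigned,
        }

    # normalize to JSON-native types (tuples -> lists) so the returned
    # manifest equals what a reader of manifest.json sees
    manifest = json.loads(json.dumps(manifest))
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
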