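"""Sequence and table I/O plus fragment quality control.

The pipeline exchanges plain-text formats only: FASTA for reference and
query sequences, TSV for the taxonomy table and incidence matrices.
Query provenance (dung pile, true source taxon for synthetic data)
travels inside FASTA headers as ``|key=value|`` tokens so that no side
file is needed downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fragments must be strictly longer than this many bases to pass QC.
DEFAULT_MIN_LENGTH = 120

_TOKEN_RE = re.compile(r"\|([A-Za-z_]+)=([^|]*)\|")


@dataclass(frozen=True)
class QueryFragment:
    """One dung-fibre barcode fragment with its provenance.

    ``passed_qc`` reflects the strict length rule: fragments are kept
    only if longer than ``min_length`` bases (a 120-base fragment is
    discarded under the default).
    """

    seq_id: str
    sequence: str
    dung_pile_id: str = ""
    true_taxon: str | None = None
    min_length: int = DEFAULT_MIN_LENGTH

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def passed_qc(self) -> bool:
        return self.length > self.min_length


@dataclass
class ReferenceDB:
    """Barcode reference: sequences with a three-rank taxonomy.

    ``records`` maps seq_id -> sequence; ``taxonomy`` is a DataFrame
    indexed by seq_id with columns species, genus, family.
    """

    records: dict[str, str]
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.records) - set(self.taxonomy.index)
        if missing:
            raise ValueError(
                "FASTA ids missing from taxonomy: " + ", ".join(sorted(missing))
            )
        for col in ("species", "genus", "family"):
            if col not in self.taxonomy.columns:
                raise ValueError(f"taxonomy table lacks required column {col!r}")
            if self.taxonomy.loc[list(self.records), col].isna().any():
                raise ValueError(f"taxonomy rank {col!r} incomplete for some records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(sorted(self.records))

    def lineage(self, seq_id: str) -> dict[str, str]:
        """Return {'species': ..., 'genus': ..., 'family': ...} for a record."""
        row = self.taxonomy.loc[seq_id]
        return {"species": row["species"], "genus": row["genus"], "family": row["family"]}


def _header_tokens(description: str) -> dict[str, str]:
    return {k: v for k, v in _TOKEN_RE.findall(description)}


def format_query_header(fragment: QueryFragment) -> str:
    tokens = f"|pile={fragment.dung_pile_id}|"
    if fragment.true_taxon is not None:
        tokens += f"|taxon_id={fragment.true_taxon}|"
    return f"{fragment.seq_id} {tokens}"


def read_queries(fasta_path: str | Path, min_length: int = DEFAULT_MIN_LENGTH) -> list[QueryFragment]:
    """Read query fragments, recovering provenance tokens from headers."""
    fragments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tokens = _header_tokens(rec.description)
        fragments.append(
            QueryFragment(
                seq_id=rec.id,
                sequence=str(rec.seq),
                dung_pile_id=tokens.get("pile", ""),
                true_taxon=tokens.get("taxon_id"),
                min_length=min_length,
            )
        )
    return fragments


def write_queries(fragments: Iterable[QueryFragment], fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(f.sequence), id=f.seq_id, description=format_query_header(f)[len(f.seq_id) + 1 :])
        for f in fragments
    ]
    with open(fasta_path, "w", newline="\n") as handle:
        SeqIO.write(records, handle, "fasta")


def read_reference(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Read a reference FASTA plus its taxonomy TSV into a validated DB.

    Raises ``ValueError`` naming the orphans when a FASTA id is absent
    from the taxonomy, and on duplicate FASTA ids.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", dtype=str).set_index("seq_id")
    if taxonomy.index.duplicated().any():
        dups = taxonomy.index[taxonomy.index.duplicated()].tolist()
        raise ValueError(f"duplicate taxonomy ids: {dups}")
    return ReferenceDB(records=records, taxonomy=taxonomy)


def write_reference(db: ReferenceDB, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sorted(db.records.items())
    ]
    with open(fasta_path, "w", newline="\n") as handle:
        SeqIO.write(records, handle, "fasta")
    out = db.taxonomy.loc[sorted(db.records)].reset_index()
    out.to_csv(taxonomy_path, sep="\t", index=False, lineterminator="\n")


def qc_filter(
    fragments: Sequence[QueryFragment],
    min_length: int = DEFAULT_MIN_LENGTH,
    inclusive: bool = False,
) -> tuple[list[QueryFragment], list[QueryFragment]]:
    """Partition fragments by the length rule.

    A fragment is kept iff its length is strictly greater than
    ``min_length`` (or ``>=`` when ``inclusive`` is set). Returns
    ``(kept, discarded)``; the two lists partition the input in order.
    """
    kept, discarded = [], []
    for f in fragments:
        ok = f.length >= min_length if inclusive else f.length > min_length
        (kept if ok else discarded).append(f)
    return kept, discarded


def read_incidence(path: str | Path) -> pd.DataFrame:
    """Read a samples x taxa 0/1 incidence TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.isin([0, 1]).all().all():
        raise ValueError("incidence matrix must be binary 0/1")
    return df.astype(int)


def write_incidence(df: pd.DataFrame, path: str | Path) -> None:
    df.astype(int).to_csv(path, sep="\t", lineterminator="\n")
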