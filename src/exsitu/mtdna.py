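"""mtDNA control-region haplotype matching.

Maternal-lineage assignment works by matching a query control-region
fragment (canonically 695 bp in Galapagos tortoises) against a database of
known haplotypes, each annotated with the population(s) and island(s) where
it was sampled in the wild and a per-population native/non-native flag
(a "non-native" haplotype is one phylogenetically characteristic of another
island's species — evidence of translocation or admixture).

Queries and database sequences are pre-aligned, equal-length fragments, so
similarity reduces to Hamming distance; positions where either sequence is
an ambiguous base (N) or an alignment gap (-) are excluded pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset(b"ACGT")


@dataclass
class HaplotypeRecord:
    haplotype_id: str
    sequence: str
    sampled_populations: set[tuple[str, str]]  # (population, island)
    accession: str | None = None
    native_status: dict[str, str] = field(default_factory=dict)  # pop -> flag

    def __post_init__(self) -> None:
        if not self.sampled_populations:
            raise ValueError(
                f"haplotype {self.haplotype_id} has no sampled populations"
            )


@dataclass
class HaplotypeMatch:
    query_id: str
    haplotype_ids: list[str]  # all minimal-distance records (ties kept)
    distance: int
    populations: set[str]
    islands: set[str]
    exact: bool


class HaplotypeDB:
    """Aligned haplotype sequences with provenance metadata."""

    def __init__(self, records: list[HaplotypeRecord]):
        if not records:
            raise ValueError("empty haplotype database")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError(
                f"database sequences are not aligned to one length: {sorted(lengths)}"
            )
        self.records = records
        self.alignment_length = lengths.pop()
        self._by_id = {r.haplotype_id: r for r in records}
        self._matrix = np.frombuffer(
            "".join(r.sequence.upper() for r in records).encode(), dtype=np.uint8
        ).reshape(len(records), self.alignment_length)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, haplotype_id: str) -> HaplotypeRecord:
        return self._by_id[haplotype_id]

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_files(cls, fasta_path: str | Path, metadata_path: str | Path) -> "HaplotypeDB":
        """Load sequences (FASTA, record id = haplotype id) plus a TSV of
        (haplotype_id, population, island, native_status[, accession]) rows."""
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        records: dict[str, HaplotypeRecord] = {}
        for _, row in meta.iterrows():
            hid = row["haplotype_id"]
            if hid not in seqs:
                raise ValueError(f"haplotype {hid} in metadata but not in FASTA")
            rec = records.get(hid)
            if rec is None:
                rec = HaplotypeRecord(
                    haplotype_id=hid,
                    sequence=seqs[hid],
                    sampled_populations={(row["population"], row["island"])},
                    accession=row.get("accession") or None,
                )
                records[hid] = rec
            else:
                rec.sampled_populations.add((row["population"], row["island"]))
            if row.get("native_status"):
                rec.native_status[row["population"]] = row["native_status"]
        return cls(list(records.values()))

    def to_files(self, fasta_path: str | Path, metadata_path: str | Path) -> None:
        SeqIO.write(
            [
                SeqRecord(Seq(r.sequence), id=r.haplotype_id, description="")
                for r in self.records
            ],
            str(fasta_path),
            "fasta",
        )
        rows = []
        for r in self.records:
            for pop, island in sorted(r.sampled_populations):
                rows.append(
                    {
                        "haplotype_id": r.haplotype_id,
                        "population": pop,
                        "island": island,
                        "native_status": r.native_status.get(pop, ""),
                        "accession": r.accession or "",
                    }
                )
        pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def match_haplotype(query: str, db: HaplotypeDB, query_id: str = "query") -> HaplotypeMatch:
    """Minimal-Hamming-distance match of an aligned query against the database.

    Positions where either sequence is not an unambiguous base (A/C/G/T) are
    excluded from the distance. Ties return every tied haplotype id, and the
    reported populations/islands are the union over the tied records.
    """
    q = query.upper()
    if len(q) != db.alignment_length:
        raise ValueError(
            f"query length {len(q)} != database alignment length "
            f"{db.alignment_length}; pre-align the query to the reference fragment"
        )
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    q_ok = np.isin(qa, np.frombuffer(b"ACGT", dtype=np.uint8))
    db_ok = np.isin(db._matrix, np.frombuffer(b"ACGT", dtype=np.uint8))
    comparable = q_ok[None, :] & db_ok
    mismatch = (db._matrix != qa[None, :]) & comparable
    dists = mismatch.sum(axis=1)
    best = int(dists.min())
    tied = [db.records[i] for i in np.nonzero(dists == best)[0]]
    pops = {p for r in tied for p, _ in r.sampled_populations}
    islands = {isl for r in tied for _, isl in r.sampled_populations}
    return HaplotypeMatch(
        query_id=query_id,
        haplotype_ids=[r.haplotype_id for r in tied],
        distance=best,
        populations=pops,
        islands=islands,
        exact=best == 0,
    )


def classify_native_status(match: HaplotypeMatch, db: HaplotypeDB, sampling_population: str) -> str:
    """Native/non-native flag of the matched haplotype in the population
    where it was sampled; "unclassified" when the metadata has no entry."""
    for hid in match.haplotype_ids:
        flag = db.get(hid).native_status.get(sampling_population)
        if flag:
            return flag
    return "unclassified"
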