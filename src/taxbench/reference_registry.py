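"""Species reference registry: genome loading, composition annotation, toy genomes.

The registry is the shared vocabulary between the read simulator and the
evaluator: every simulated read is labelled with a ``species_id`` from the
registry, and classifier outputs are mapped back onto the same ids before
scoring.  One optional entry may be flagged as the *host* (the decoy
background a real RNA-seq sample would contribute); host reads are never
counted as microbial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SpeciesRecord",
    "Registry",
    "read_fasta",
    "annotate_species",
    "make_toy_genome",
]

_VALID_BASES = frozenset("ACGTN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesRecord:
    """One reference genome with identity and composition annotations.

    ``gc_fraction`` excludes N bases from the numerator but counts them in
    the denominator (``genome_length`` is the full sequence length).
    """

    species_id: str
    display_name: str
    fasta_path: str
    record_id: str
    genome_length: int
    gc_count: int
    host: bool = False
    gram_category: Optional[str] = None
    phylum: Optional[str] = None

    @property
    def gc_fraction(self) -> float:
        return self.gc_count / self.genome_length

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError(f"genome_length must be >= 1, got {self.genome_length}")
        if not 0 <= self.gc_count <= self.genome_length:
            raise ValueError(
                f"gc_count {self.gc_count} outside [0, {self.genome_length}]"
            )


class Registry:
    """Ordered collection of :class:`SpeciesRecord` with at most one host."""

    def __init__(self, records: Iterable[SpeciesRecord] = ()):
        self._records: List[SpeciesRecord] = []
        self._by_id: Dict[str, SpeciesRecord] = {}
        self._sequences: Dict[str, str] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SpeciesRecord, sequence: Optional[str] = None) -> None:
        if record.species_id in self._by_id:
            raise ValueError(f"duplicate species_id {record.species_id!r}")
        if record.host and self.host is not None:
            raise ValueError("registry already has a host record")
        self._records.append(record)
        self._by_id[record.species_id] = record
        if sequence is not None:
            if len(sequence) != record.genome_length:
                raise ValueError("sequence length does not match genome_length")
            self._sequences[record.species_id] = sequence

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self._records)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        return self._by_id[species_id]

    @property
    def host(self) -> Optional[SpeciesRecord]:
        for rec in self._records:
            if rec.host:
                return rec
        return None

    @property
    def microbial(self) -> List[SpeciesRecord]:
        return [r for r in self._records if not r.host]

    def sequence(self, species_id: str) -> str:
        """Genome sequence for a species, loading from FASTA on first use."""
        if species_id not in self._sequences:
            rec = self._by_id[species_id]
            seqs = read_fasta(rec.fasta_path)
            if rec.record_id not in seqs:
                raise KeyError(
                    f"record {rec.record_id!r} not found in {rec.fasta_path}"
                )
            self._sequences[species_id] = seqs[rec.record_id]
        return self._sequences[species_id]

    # -- manifest persistence -------------------------------------------------

    _COLUMNS = [
        "species_id",
        "display_name",
        "fasta_path",
        "record_id",
        "genome_length",
        "gc_count",
        "gc_fraction",
        "host",
        "gram_category",
        "phylum",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_id": r.species_id,
                "display_name": r.display_name,
                "fasta_path": r.fasta_path,
                "record_id": r.record_id,
                "genome_length": r.genome_length,
                "gc_count": r.gc_count,
                "gc_fraction": r.gc_fraction,
                "host": r.host,
                "gram_category": r.gram_category if r.gram_category else "",
                "phylum": r.phylum if r.phylum else "",
            }
            for r in self._records
        ]
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def write_manifest(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_manifest(cls, path: str | Path) -> "Registry":
        df = pd.read_csv(path, sep="\t", dtype={"species_id": str}, keep_default_na=False)
        reg = cls()
        for row in df.itertuples(index=False):
            reg.add(
                SpeciesRecord(
                    species_id=str(row.species_id),
                    display_name=str(row.display_name),
                    fasta_path=str(row.fasta_path),
                    record_id=str(row.record_id),
                    genome_length=int(row.genome_length),
                    gc_count=int(row.gc_count),
                    host=str(row.host) in ("True", "true", "1"),
                    gram_category=str(row.gram_category) or None,
                    phylum=str(row.phylum) or None,
                )
            )
        return reg

    def validate_for_read_length(self, read_length: int, min_gap: int = 0) -> None:
        """Check every genome admits at least one full paired fragment."""
        span = 2 * read_length + min_gap
        for rec in self._records:
            if rec.genome_length < span:
                raise ValueError(
                    f"{rec.species_id}: genome length {rec.genome_length} < "
                    f"minimum fragment span {span}"
                )


def read_fasta(path: str | Path, max_invalid_fraction: float = 0.0) -> Dict[str, str]:
    """Read a FASTA file into ``{record_id: uppercase sequence}``.

    Record order is preserved (Python dicts are ordered).  Characters outside
    ``{A,C,G,T,N}`` raise unless their fraction is within
    ``max_invalid_fraction``, in which case they are replaced by N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA record id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {record.id!r} in {path}")
        invalid = [c for c in set(seq) if c not in _VALID_BASES]
        if invalid:
            n_bad = sum(seq.count(c) for c in invalid)
            if n_bad / len(seq) > max_invalid_fraction:
                raise ValueError(
                    f"record {record.id!r}: non-nucleotide characters {sorted(invalid)}"
                )
            table = str.maketrans({c: "N" for c in invalid})
            seq = seq.translate(table)
        out[record.id] = seq
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def annotate_species(
    species_id: str,
    display_name: str,
    sequence: str,
    fasta_path: str = "",
    record_id: str = "",
    host: bool = False,
    gram_category: Optional[str] = None,
    phylum: Optional[str] = None,
) -> SpeciesRecord:
    """Build a :class:`SpeciesRecord` with GC/length annotations computed.

    N bases count toward ``genome_length`` but not ``gc_count``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return SpeciesRecord(
        species_id=species_id,
        display_name=display_name,
        fasta_path=fasta_path,
        record_id=record_id or species_id,
        genome_length=len(seq),
        gc_count=seq.count("G") + seq.count("C"),
        host=host,
        gram_category=gram_category,
        phylum=phylum,
    )


def make_toy_genome(length: int, gc_target: float, rng_seed: int) -> str:
    """Generate a random genome with an expected GC fraction of ``gc_target``.

    Bases are drawn i.i.d.; G and C each carry probability ``gc_target / 2``,
    A and T each ``(1 - gc_target) / 2``.  Deterministic for a given seed.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError(f"gc_target must be in [0, 1], got {gc_target}")
    rng = np.random.default_rng(rng_seed)
    at = (1.0 - gc_target) / 2.0
    gc = gc_target / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[codes].tobytes().decode("ascii")
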