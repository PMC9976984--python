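"""Parsers that normalise heterogeneous classifier outputs for scoring.

Binners report per-read counts; profilers report relative abundances.  To
score both kinds of tools with one count-based metric, profiles are
converted to *pseudo-counts* by proportional allocation over the number of
input reads, and every taxon label is matched back onto the registry's
species ids (unmatched credit is kept under the reserved ``off_target``
key so nothing is silently dropped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

from .reference_registry import Registry

__all__ = [
    "OFF_TARGET",
    "ClassificationResult",
    "parse_kraken2_report",
    "parse_metaphlan_profile",
    "parse_generic_tsv",
    "to_pseudo_counts",
    "match_taxa",
]

OFF_TARGET = "off_target"

_ABUNDANCE_SUM_TOL = 0.5  # percentage points of slack on a 100% profile


@dataclass(frozen=True)
class ClassificationResult:
    """One tool's output reduced to species-level taxon -> value."""

    tool_name: str
    unit: str  # "read_count" | "relative_abundance"
    entries: Dict[str, float]
    total_input_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.unit not in ("read_count", "relative_abundance"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("entry values must be non-negative")
        if self.unit == "relative_abundance":
            total = sum(self.entries.values())
            if total > 100.0 + _ABUNDANCE_SUM_TOL:
                raise ValueError(f"relative abundances sum to {total:.3f} > 100")


def parse_kraken2_report(path: str | Path, tool_name: str = "kraken2") -> ClassificationResult:
    """Parse the standard six-column Kraken2 report.

    Columns: percentage, clade read count, taxon read count, rank code,
    taxid, indented name.  Species-rank rows (rank code ``S``) are kept,
    credited with their *clade* counts so strain-level assignments under a
    species still count toward it; sub-species rows (``S1``, ...) are not
    double-counted.  ``total_input_reads`` is unclassified + root clade.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty Kraken2 report: {path}")
    entries: Dict[str, float] = {}
    unclassified = 0
    classified = 0
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) != 6:
            raise ValueError(f"malformed Kraken2 report line (expected 6 columns): {ln!r}")
        _, clade_count, _taxon_count, rank, taxid, name = parts
        count = int(clade_count)
        if count < 0:
            raise ValueError(f"negative count in Kraken2 report: {ln!r}")
        name = name.strip()
        if rank == "U" or taxid.strip() == "0":
            unclassified += count
        elif taxid.strip() == "1":
            classified = count
        if rank == "S":
            entries[name] = entries.get(name, 0.0) + count
    return ClassificationResult(
        tool_name=tool_name,
        unit="read_count",
        entries=entries,
        total_input_reads=unclassified + classified,
    )


def parse_metaphlan_profile(path: str | Path, tool_name: str = "metaphlan") -> ClassificationResult:
    """Parse a MetaPhlAn-style profile (clade name, relative abundance %).

    Only species-level clades (deepest rank ``s__``, no ``t__`` strain
    suffix) are kept; comment/header lines start with ``#``.
    """
    path = Path(path)
    entries: Dict[str, float] = {}
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed profile line: {ln!r}")
        clade = parts[0]
        # some dialects interpose an NCBI taxid column; abundance is the
        # first numeric field after the clade
        try:
            value = float(parts[2] if ":" in parts[1] or "|" in parts[1] else parts[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed profile line: {ln!r}") from exc
        levels = clade.split("|")
        if not levels[-1].startswith("s__"):
            continue
        species = levels[-1][3:]
        entries[species] = entries.get(species, 0.0) + value
    return ClassificationResult(
        tool_name=tool_name, unit="relative_abundance", entries=entries
    )


def parse_generic_tsv(path: str | Path, tool_name: str = "generic") -> ClassificationResult:
    """Parse a two-column taxon/count TSV; duplicate taxa are summed."""
    path = Path(path)
    entries: Dict[str, float] = {}
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected two tab-separated columns: {ln!r}")
        taxon, raw = parts
        try:
            value = float(raw)
        except ValueError as exc:
            raise ValueError(f"non-numeric count for {taxon!r}: {raw!r}") from exc
        if value < 0:
            raise ValueError(f"negative count for {taxon!r}")
        entries[taxon] = entries.get(taxon, 0.0) + value
    return ClassificationResult(tool_name=tool_name, unit="read_count", entries=entries)


def to_pseudo_counts(
    result: ClassificationResult, total_input_reads: Optional[int] = None
) -> ClassificationResult:
    """Convert relative abundances to pseudo read counts.

    Each abundance ``v`` (in %) becomes ``round(v / 100 * total)``.  Results
    already in read counts pass through unchanged (idempotent).
    """
    if result.unit == "read_count":
        return result
    total = total_input_reads if total_input_reads is not None else result.total_input_reads
    if total is None or total <= 0:
        raise ValueError("total_input_reads required to convert relative abundances")
    entries = {k: float(round(v / 100.0 * total)) for k, v in result.entries.items()}
    return ClassificationResult(
        tool_name=result.tool_name,
        unit="read_count",
        entries=entries,
        total_input_reads=total,
    )


def _normalize_label(label: str) -> str:
    label = re.sub(r"^[a-z]__", "", label.strip())
    label = re.sub(r"[\s_]+", " ", label)
    return label.lower()


def match_taxa(result: ClassificationResult, registry: Registry) -> ClassificationResult:
    """Re-key a result by registry species ids.

    Matching is case-insensitive on genus+species after separator
    normalisation (spaces vs underscores); both the display name and the
    species id are accepted as labels.  Taxa that match nothing are summed
    under :data:`OFF_TARGET`; total value is conserved.
    """
    lookup: Dict[str, str] = {}
    for rec in registry:
        lookup[_normalize_label(rec.display_name)] = rec.species_id
        lookup[_normalize_label(rec.species_id)] = rec.species_id
    entries: Dict[str, float] = {}
    for label, value in result.entries.items():
        key = lookup.get(_normalize_label(label), OFF_TARGET)
        entries[key] = entries.get(key, 0.0) + value
    return replace(result, entries=entries)
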