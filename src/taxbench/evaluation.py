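"""Performance estimators: subtraction TP, exclusion FP, Se/PPV/F1, coverage.

The scoring logic mirrors the exclusion-database design.  For one replicate:

* true positives for a species present in a mixture file are its Dataset-2
  count minus its count in the host-only negative control (clamped at zero —
  the control can only ever remove credit);
* false positives for a species come from two places: the mixture file that
  *excludes* it (bacterial-origin FP — any credit there is wrong by
  construction) and the negative control (host-origin FP);
* sensitivity, precision (PPV) and F1 follow the usual definitions
  Se = TP/(TP+FN), PPV = TP/(TP+FP), F1 = 2·Se·PPV/(Se+PPV).

A coverage-evidence score is also provided: the breadth of genome actually
covered by a tool's assigned reads, divided by the breadth expected if the
same number of reads were placed uniformly at random
(1 − (1 − L/G)^n).  Assignments whose observed breadth falls far below
expectation are flagged for discard — a pile-up of reads on one locus is
weak evidence that the genome is really present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .result_adapters import ClassificationResult
from .reference_registry import Registry

__all__ = [
    "ConfusionCounts",
    "PerformanceScore",
    "CoverageEvidence",
    "subtract_negative",
    "exclusion_fp",
    "confusion",
    "score",
    "aggregate_replicates",
    "coverage_score",
    "evaluate_replicate",
]

Counts = Union[Mapping[str, float], ClassificationResult]


def _as_counts(obj: Counts) -> Mapping[str, float]:
    if isinstance(obj, ClassificationResult):
        if obj.unit != "read_count":
            raise ValueError(
                "counts must be in read_count units; run to_pseudo_counts first"
            )
        return obj.entries
    return obj


@dataclass(frozen=True)
class ConfusionCounts:
    species_id: str
    tp: int
    fp: int
    fn: int
    ground_truth_reads: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("TP, FP, FN must be non-negative")
        if self.tp + self.fn != self.ground_truth_reads:
            raise ValueError("TP + FN must equal ground_truth_reads")


@dataclass(frozen=True)
class PerformanceScore:
    species_id: str
    sensitivity: float
    ppv: float
    f1: float
    tool: str = ""
    replicate: int = 0
    degenerate_truth: bool = False  # ground truth had zero reads
    vacuous_ppv: bool = False  # TP = FP = 0, PPV defined as 1


@dataclass(frozen=True)
class CoverageEvidence:
    species_id: str
    n_assigned_reads: int
    read_length: int
    genome_length: int
    observed_breadth: float
    expected_breadth: float
    score: float
    keep: bool


def subtract_negative(
    dataset2_counts: Counts, dataset1_counts: Counts, species: str
) -> int:
    """TP for one species: Dataset-2 count minus Dataset-1 count, clamped at 0."""
    c2 = _as_counts(dataset2_counts).get(species, 0.0)
    c1 = _as_counts(dataset1_counts).get(species, 0.0)
    return max(0, int(round(c2 - c1)))


def exclusion_fp(dataset2_counts: Counts, left_out_species: str) -> int:
    """Bacterial-origin FP: any credit given to the species the file excludes."""
    return int(round(_as_counts(dataset2_counts).get(left_out_species, 0.0)))


def confusion(tp: int, fp: int, ground_truth_reads: int, species_id: str = "") -> ConfusionCounts:
    """Assemble a confusion table; FN is the truth shortfall."""
    if tp > ground_truth_reads:
        raise ValueError(
            f"TP ({tp}) cannot exceed ground truth ({ground_truth_reads})"
        )
    return ConfusionCounts(
        species_id=species_id,
        tp=tp,
        fp=fp,
        fn=ground_truth_reads - tp,
        ground_truth_reads=ground_truth_reads,
    )


def score(
    counts: ConfusionCounts, tool: str = "", replicate: int = 0
) -> PerformanceScore:
    """Se/PPV/F1 from a confusion table.

    Conventions for degenerate corners: PPV = 1 when TP = FP = 0 (the tool
    made no false claim); Se = 0 when the ground truth is empty.  Both are
    flagged on the returned score.
    """
    degenerate = counts.ground_truth_reads == 0
    se = 0.0 if degenerate else counts.tp / (counts.tp + counts.fn)
    vacuous = counts.tp + counts.fp == 0
    ppv = 1.0 if vacuous else counts.tp / (counts.tp + counts.fp)
    f1 = 0.0 if se + ppv == 0 else 2.0 * se * ppv / (se + ppv)
    return PerformanceScore(
        species_id=counts.species_id,
        sensitivity=se,
        ppv=ppv,
        f1=f1,
        tool=tool,
        replicate=replicate,
        degenerate_truth=degenerate,
        vacuous_ppv=vacuous,
    )


def aggregate_replicates(scores: Iterable[PerformanceScore]) -> pd.DataFrame:
    """Mean and sample SD (n−1) of Se/PPV/F1 per (tool, species).

    Single-replicate groups get SD 0 and ``single_replicate=True``.
    """
    rows = [
        {
            "tool": s.tool,
            "species_id": s.species_id,
            "replicate": s.replicate,
            "sensitivity": s.sensitivity,
            "ppv": s.ppv,
            "f1": s.f1,
        }
        for s in scores
    ]
    if not rows:
        raise ValueError("no scores to aggregate")
    df = pd.DataFrame(rows)
    agg = df.groupby(["tool", "species_id"]).agg(
        n_replicates=("replicate", "size"),
        sensitivity_mean=("sensitivity", "mean"),
        sensitivity_sd=("sensitivity", lambda x: x.std(ddof=1)),
        ppv_mean=("ppv", "mean"),
        ppv_sd=("ppv", lambda x: x.std(ddof=1)),
        f1_mean=("f1", "mean"),
        f1_sd=("f1", lambda x: x.std(ddof=1)),
    )
    agg["single_replicate"] = agg["n_replicates"] == 1
    for col in ("sensitivity_sd", "ppv_sd", "f1_sd"):
        agg[col] = agg[col].fillna(0.0)
    return agg.reset_index()


def coverage_score(
    assigned_read_placements: Sequence[Tuple[int, int]],
    read_length: int,
    genome_length: int,
    species_id: str = "",
    threshold: float = 0.5,
) -> CoverageEvidence:
    """Score coverage breadth of assigned reads against random expectation.

    ``assigned_read_placements`` are half-open (start, end) intervals on the
    genome.  Observed breadth is the fraction of the genome under the union
    of the intervals; expected breadth under independent uniform placement
    of n reads of length L on a genome of length G is 1 − (1 − L/G)^n.
    The score observed/expected is 0 when n = 0; assignments scoring below
    ``threshold`` are flagged for discard.
    """
    if genome_length < 1 or read_length < 1:
        raise ValueError("read_length and genome_length must be positive")
    n = len(assigned_read_placements)
    covered = 0
    if n:
        ivals = sorted(assigned_read_placements)
        for start, end in ivals:
            if start < 0 or end > genome_length or end <= start:
                raise ValueError(f"interval ({start}, {end}) out of bounds")
        cur_s, cur_e = ivals[0]
        for start, end in ivals[1:]:
            if start > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = start, end
            else:
                cur_e = max(cur_e, end)
        covered += cur_e - cur_s
    observed = covered / genome_length
    expected = 1.0 - (1.0 - read_length / genome_length) ** n if n else 0.0
    s = observed / expected if n else 0.0
    return CoverageEvidence(
        species_id=species_id,
        n_assigned_reads=n,
        read_length=read_length,
        genome_length=genome_length,
        observed_breadth=observed,
        expected_breadth=expected,
        score=s,
        keep=s >= threshold,
    )


def evaluate_replicate(
    registry: Registry,
    dataset2_counts: Mapping[str, Counts],
    dataset1_counts: Counts,
    ground_truth_reads: int,
    tool: str = "",
    replicate: int = 0,
) -> List[PerformanceScore]:
    """Score every microbial species for one replicate of one tool.

    ``dataset2_counts`` maps each left-out species id to the registry-keyed
    counts the tool reported on that file.  For each species, TP is the
    negative-control subtraction averaged over the files that contain it
    (rounded to the nearest read and capped at the ground truth), and FP is
    the sum of its bacterial-origin credit (from its own exclusion file)
    and its host-origin credit (from Dataset-1).
    """
    d1 = _as_counts(dataset1_counts)
    species_ids = [r.species_id for r in registry.microbial]
    missing = [s for s in dataset2_counts if s not in species_ids]
    if missing:
        raise KeyError(f"left-out ids not in registry: {missing}")
    out: List[PerformanceScore] = []
    for sid in species_ids:
        tps = [
            subtract_negative(counts, d1, sid)
            for left_out, counts in dataset2_counts.items()
            if left_out != sid
        ]
        tp = int(round(float(np.mean(tps)))) if tps else 0
        tp = min(tp, ground_truth_reads)
        fp_bacterial = (
            exclusion_fp(dataset2_counts[sid], sid) if sid in dataset2_counts else 0
        )
        fp_host = int(round(d1.get(sid, 0.0)))
        cc = confusion(tp, fp_bacterial + fp_host, ground_truth_reads, species_id=sid)
        out.append(score(cc, tool=tool, replicate=replicate))
    return out
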