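"""Seeded paired-end read simulator with a bounded Phred-quality model.

The simulator emulates an Illumina-like paired-end assay in which base
quality is the controlled variable:

* every non-tail base quality is an integer drawn from a symmetric bounded
  distribution centred on the scenario mean — a binomial(2·f, 1/2) shifted
  onto the window [mean − f, mean + f], where f is the *variance frame*
  (default 4 Phred units), so no sampled quality ever leaves the window;
* the last ``tail_length`` bases (default 10) receive a progressive linear
  penalty (position k of the tail loses k·``tail_step`` Phred units before
  flooring), mimicking the phasing / signal-decay drop-off at the 3′ end;
* fragments are placed uniformly at random on the (linear) genome with a
  random unsequenced gap between the mates and a random strand; mate 2 is
  reported reverse-complemented, as a sequencer would;
* substitution errors are injected per base with probability
  10^(−q/10) for the base's sampled quality q, making the quality string
  operationally meaningful (a flag disables this).

All randomness flows through a single :class:`numpy.random.Generator`, so
identical (configuration, seed) pairs produce byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "QualityModel",
    "ReadPair",
    "phred_to_error",
    "sample_quality_string",
    "sample_read_pair",
    "apply_sequencing_errors",
    "simulate_reads",
    "write_fastq",
]

# base codes: A=0 C=1 G=2 T=3 N=4
_CODE_TO_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGTN"):
    _CHAR_TO_CODE[_c] = _i
# complement in code space (N -> N)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_MAX_ENCODABLE_PHRED = 93  # chr(33 + 93) == '~', top of the printable range


@dataclass(frozen=True)
class QualityModel:
    """Parameters governing per-base Phred quality sampling.

    ``mean_phred`` is the scenario mean (23 for the bad-quality scenarios,
    35 for the good ones); ``variance_frame`` bounds how far any non-tail
    quality may stray from it.  ``floor_phred`` is the minimum emitted
    quality after the tail penalty.
    """

    mean_phred: int
    variance_frame: int = 4
    tail_length: int = 10
    tail_step: int = 1
    floor_phred: int = 2

    def __post_init__(self) -> None:
        if self.mean_phred < 0:
            raise ValueError("mean_phred must be non-negative")
        if self.variance_frame < 0:
            raise ValueError("variance_frame must be non-negative")
        if self.tail_length < 0 or self.tail_step < 0:
            raise ValueError("tail parameters must be non-negative")
        if self.mean_phred - self.variance_frame < self.floor_phred:
            raise ValueError(
                "mean_phred - variance_frame must stay above floor_phred"
            )

    def sample_matrix(
        self, n_reads: int, read_length: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Sample an (n_reads, read_length) integer quality matrix."""
        if read_length <= self.tail_length:
            raise ValueError(
                f"read_length ({read_length}) must exceed tail_length "
                f"({self.tail_length})"
            )
        f = self.variance_frame
        if f == 0:
            q = np.full((n_reads, read_length), self.mean_phred, dtype=np.int16)
        else:
            # binomial(2f, 1/2) has mean f and support [0, 2f]; shifting by
            # (mean - f) centres it on the scenario mean inside the frame
            q = rng.binomial(2 * f, 0.5, size=(n_reads, read_length)).astype(np.int16)
            q += self.mean_phred - f
        if self.tail_length > 0:
            penalty = np.arange(1, self.tail_length + 1, dtype=np.int16) * self.tail_step
            q[:, read_length - self.tail_length :] -= penalty
        np.maximum(q, self.floor_phred, out=q)
        return q


@dataclass(frozen=True)
class ReadPair:
    """One simulated fragment: two mates with coordinates and truth labels.

    ``start1`` / ``start2`` are 0-based forward-genome offsets of each
    mate's slice; ``strand`` is the fragment orientation ('+' means mate 1
    reads the forward strand).  Qualities are integer Phred vectors, or
    ``None`` before quality sampling.
    """

    fragment_id: str
    species_id: str
    seq1: str
    seq2: str
    qual1: Optional[np.ndarray]
    qual2: Optional[np.ndarray]
    start1: int
    start2: int
    gap: int
    strand: str


def phred_to_error(q) -> float:
    """Convert Phred quality to base-call error probability, 10^(−q/10)."""
    q_arr = np.asarray(q)
    if np.any(q_arr < 0):
        raise ValueError("Phred quality must be non-negative")
    out = np.power(10.0, -q_arr / 10.0)
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def sample_quality_string(
    model: QualityModel, read_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample one integer quality vector of length ``read_length``."""
    return model.sample_matrix(1, read_length, rng)[0]


def _encode_genome(genome: str) -> np.ndarray:
    arr = _CHAR_TO_CODE[np.frombuffer(genome.encode("ascii"), dtype=np.uint8)]
    if np.any(arr == 255):
        raise ValueError("genome contains characters outside {A,C,G,T,N}")
    return arr


def _sample_coordinates(
    genome_length: int,
    n: int,
    read_length: int,
    gap_min: int,
    gap_max: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (start, gap, strand) for ``n`` fragments; start is the leftmost
    forward-genome offset of the whole fragment."""
    if gap_min < 0 or gap_max < gap_min:
        raise ValueError("need 0 <= gap_min <= gap_max")
    max_feasible_gap = genome_length - 2 * read_length
    if max_feasible_gap < gap_min:
        raise ValueError(
            f"genome too short ({genome_length}) for two {read_length} nt "
            f"mates with gap >= {gap_min}"
        )
    gap_hi = min(gap_max, max_feasible_gap)
    gaps = rng.integers(gap_min, gap_hi + 1, size=n)
    starts = rng.integers(0, genome_length - 2 * read_length - gaps + 1, size=n)
    forward = rng.random(n) < 0.5
    return starts, gaps, forward


def _slice_mates(
    genome_codes: np.ndarray,
    starts: np.ndarray,
    gaps: np.ndarray,
    forward: np.ndarray,
    read_length: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract mate code matrices.  Mate 1 reads the fragment strand; mate 2
    is the reverse complement of the opposite end of the fragment."""
    left = starts
    right = starts + read_length + gaps  # offset of the rightmost mate slice
    a1 = np.where(forward, left, right)
    a2 = np.where(forward, right, left)
    idx = np.arange(read_length)
    m1 = genome_codes[a1[:, None] + idx]
    m2 = genome_codes[a2[:, None] + idx]
    # '+' fragments: mate1 as-is, mate2 revcomp; '-' fragments: the reverse
    rev = ~forward
    m1[rev] = _COMPLEMENT[m1[rev][:, ::-1]]
    m2[forward] = _COMPLEMENT[m2[forward][:, ::-1]]
    return m1, m2, a1, a2


def sample_read_pair(
    genome: str,
    read_length: int,
    rng: np.random.Generator,
    gap_min: int = 0,
    gap_max: int = 300,
    species_id: str = "species",
    fragment_id: str = "frag0",
) -> ReadPair:
    """Sample one error-free read pair from a genome.

    The fragment start is uniform over all placements admitting both mates
    and the gap; the gap is uniform on [gap_min, min(gap_max, feasible)].
    """
    codes = _encode_genome(genome)
    starts, gaps, forward = _sample_coordinates(
        len(codes), 1, read_length, gap_min, gap_max, rng
    )
    m1, m2, a1, a2 = _slice_mates(codes, starts, gaps, forward, read_length)
    return ReadPair(
        fragment_id=fragment_id,
        species_id=species_id,
        seq1=_CODE_TO_CHAR[m1[0]].tobytes().decode("ascii"),
        seq2=_CODE_TO_CHAR[m2[0]].tobytes().decode("ascii"),
        qual1=None,
        qual2=None,
        start1=int(a1[0]),
        start2=int(a2[0]),
        gap=int(gaps[0]),
        strand="+" if forward[0] else "-",
    )


def _inject_errors_codes(
    codes: np.ndarray, quals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute bases in-place-free according to per-base error probability.

    Each base flips with probability 10^(−q/10) to one of the three
    alternatives uniformly; N bases are never substituted.
    """
    p = np.power(10.0, -quals / 10.0)
    hit = (rng.random(codes.shape) < p) & (codes < 4)
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[hit] = (codes[hit] + shift[hit]) % 4
    return out


def apply_sequencing_errors(pair: ReadPair, rng: np.random.Generator) -> ReadPair:
    """Return a copy of ``pair`` with quality-driven substitutions applied."""
    if pair.qual1 is None or pair.qual2 is None:
        raise ValueError("quality vectors must be populated before error injection")
    c1 = _CHAR_TO_CODE[np.frombuffer(pair.seq1.encode(), dtype=np.uint8)][None, :]
    c2 = _CHAR_TO_CODE[np.frombuffer(pair.seq2.encode(), dtype=np.uint8)][None, :]
    e1 = _inject_errors_codes(c1, pair.qual1[None, :], rng)
    e2 = _inject_errors_codes(c2, pair.qual2[None, :], rng)
    return replace(
        pair,
        seq1=_CODE_TO_CHAR[e1[0]].tobytes().decode("ascii"),
        seq2=_CODE_TO_CHAR[e2[0]].tobytes().decode("ascii"),
    )


def simulate_reads(
    genome: str,
    n_pairs: int,
    read_length: int,
    model: QualityModel,
    rng: np.random.Generator,
    species_id: str = "species",
    gap_min: int = 0,
    gap_max: int = 300,
    inject_errors: bool = True,
    id_prefix: str = "frag",
) -> List[ReadPair]:
    """Simulate ``n_pairs`` complete read pairs from one genome.

    Vectorised end-to-end: coordinates, sequences, qualities and
    substitution errors are all drawn as matrices, then materialised as
    :class:`ReadPair` objects.
    """
    if n_pairs == 0:
        return []
    codes = _encode_genome(genome)
    starts, gaps, forward = _sample_coordinates(
        len(codes), n_pairs, read_length, gap_min, gap_max, rng
    )
    m1, m2, a1, a2 = _slice_mates(codes, starts, gaps, forward, read_length)
    q1 = model.sample_matrix(n_pairs, read_length, rng)
    q2 = model.sample_matrix(n_pairs, read_length, rng)
    if inject_errors:
        m1 = _inject_errors_codes(m1, q1, rng)
        m2 = _inject_errors_codes(m2, q2, rng)
    s1 = _CODE_TO_CHAR[m1]
    s2 = _CODE_TO_CHAR[m2]
    pairs = []
    for i in range(n_pairs):
        pairs.append(
            ReadPair(
                fragment_id=f"{id_prefix}{i}",
                species_id=species_id,
                seq1=s1[i].tobytes().decode("ascii"),
                seq2=s2[i].tobytes().decode("ascii"),
                qual1=q1[i],
                qual2=q2[i],
                start1=int(a1[i]),
                start2=int(a2[i]),
                gap=int(gaps[i]),
                strand="+" if forward[i] else "-",
            )
        )
    return pairs


def _quality_to_ascii(q: np.ndarray) -> str:
    if q.max(initial=0) > _MAX_ENCODABLE_PHRED:
        raise ValueError(f"Phred quality above {_MAX_ENCODABLE_PHRED} is not encodable")
    return (q.astype(np.uint8) + 33).tobytes().decode("ascii")


def write_fastq(
    pairs: Sequence[ReadPair], out_prefix: str | Path
) -> Tuple[Path, Path, pd.DataFrame]:
    """Write paired gzipped FASTQ files and return the truth manifest.

    Emits ``<prefix>_R1.fastq.gz`` / ``<prefix>_R2.fastq.gz`` with Phred+33
    quality encoding and read ids ``<fragment_id>/1`` and ``/2``.  The
    returned manifest maps each fragment id to its origin species and
    coordinates.  Output is byte-identical across runs (gzip mtime pinned).
    """
    out_prefix = Path(out_prefix)
    r1_path = out_prefix.parent / (out_prefix.name + "_R1.fastq.gz")
    r2_path = out_prefix.parent / (out_prefix.name + "_R2.fastq.gz")
    lengths = {len(p.seq1) for p in pairs} | {len(p.seq2) for p in pairs}
    if len(lengths) > 1:
        raise ValueError("all pairs must share one read length")
    rows = []
    for path, mate in ((r1_path, 1), (r2_path, 2)):
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", fileobj=raw, mode="wb", mtime=0
        ) as gz:
            chunks = []
            for p in pairs:
                seq = p.seq1 if mate == 1 else p.seq2
                qual = p.qual1 if mate == 1 else p.qual2
                if qual is None:
                    raise ValueError("quality vectors must be populated")
                chunks.append(
                    f"@{p.fragment_id}/{mate}\n{seq}\n+\n{_quality_to_ascii(qual)}\n"
                )
            gz.write("".join(chunks).encode("ascii"))
    for p in pairs:
        rows.append(
            {
                "read_id": p.fragment_id,
                "species_id": p.species_id,
                "start1": p.start1,
                "start2": p.start2,
                "gap": p.gap,
                "strand": p.strand,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["read_id", "species_id", "start1", "start2", "gap", "strand"]
    )
    return r1_path, r2_path, manifest
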