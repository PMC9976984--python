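"""Benchmark scenario composition and the leave-one-out exclusion database.

A *scenario* fixes the controlled conditions of one benchmark run: fragments
per microbe, per-species prevalence, read length and mean base quality.  The
four presets span low/high prevalence (1 000 / 10 000 fragments per microbe at
1.5% / 3.9% prevalence), bad/good quality (Phred 23 / 35) and short/long
reads (48 / 100 nt):

* ``LPBQ``   — low proportion, bad quality
* ``HPBQ``   — high proportion, bad quality
* ``HPGQ``   — high proportion, good quality
* ``LSHPGQ`` — longer sequences, high proportion, good quality

From a scenario and a species registry the builder emits the *exclusion
database*: a host-only negative control per replicate (Dataset-1) and, for
every microbial species, a mixture file in which that species is left out
(Dataset-2).  Any credit a classifier gives the left-out species in its own
file is, by construction, a false positive of bacterial origin; credit in
Dataset-1 exposes false positives of host origin.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .read_simulator import QualityModel, ReadPair, simulate_reads, write_fastq
from .reference_registry import Registry

__all__ = [
    "ScenarioConfig",
    "ExclusionDatabase",
    "SolvedCounts",
    "solve_counts",
    "build_dataset1_file",
    "build_dataset2_file",
    "build_exclusion_database",
    "preset_scenarios",
    "derive_seed",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One benchmark condition set.

    ``reads_per_species`` counts fragments (read pairs), matching the
    paired-end design; ``per_species_prevalence`` is the fraction of the
    file's fragments contributed by each microbe, the remainder being host.
    """

    name: str
    reads_per_species: int
    per_species_prevalence: float
    read_length: int
    mean_phred: int
    variance_frame: int = 4
    tail_length: int = 10
    tail_step: int = 1
    floor_phred: int = 2
    gap_min: int = 0
    gap_max: int = 300
    n_replicates: int = 20
    base_seed: int = 0
    inject_errors: bool = True

    def __post_init__(self) -> None:
        if self.reads_per_species < 1:
            raise ValueError("reads_per_species must be >= 1")
        if not 0.0 < self.per_species_prevalence <= 1.0:
            raise ValueError("per_species_prevalence must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def quality_model(self) -> QualityModel:
        return QualityModel(
            mean_phred=self.mean_phred,
            variance_frame=self.variance_frame,
            tail_length=self.tail_length,
            tail_step=self.tail_step,
            floor_phred=self.floor_phred,
        )


class SolvedCounts(NamedTuple):
    total_reads: int
    host_reads: int
    overall_prevalence: float


def solve_counts(
    reads_per_species: int, n_species: int, per_species_prevalence: float
) -> SolvedCounts:
    """Solve the file composition implied by a per-species prevalence target.

    ``total = round(reads_per_species / prevalence)`` fragments overall;
    host fragments fill the remainder after ``n_species`` microbes contribute
    ``reads_per_species`` each.  The overall microbial prevalence is
    ``n_species * per_species_prevalence`` (0.78 and 0.30 for the two preset
    prevalence regimes with 20 mixed species).
    """
    if reads_per_species < 1 or n_species < 1:
        raise ValueError("reads_per_species and n_species must be positive")
    if not 0.0 < per_species_prevalence <= 1.0:
        raise ValueError("per_species_prevalence must be in (0, 1]")
    if per_species_prevalence * n_species > 1.0 + 1e-12:
        raise ValueError("per-species prevalence infeasible: microbes exceed 100%")
    total = int(round(reads_per_species / per_species_prevalence))
    host = total - n_species * reads_per_species
    if host < 0:
        raise ValueError("prevalence infeasible: host read count negative")
    return SolvedCounts(total, host, n_species * per_species_prevalence)


def derive_seed(base_seed: int, scenario_name: str, left_out: str, replicate: int) -> int:
    """Deterministic child seed for one file, independent across files.

    Stable hash of the identifying tuple, folded to a non-negative 31-bit
    integer so it is portable across platforms and runs.
    """
    key = f"{base_seed}|{scenario_name}|{left_out}|{replicate}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def _relabel_and_shuffle(
    pairs: List[ReadPair], rng: np.random.Generator
) -> List[ReadPair]:
    """Deterministically shuffle pairs and assign neutral sequential ids.

    Ids are assigned after the shuffle so a read's id carries no hint of its
    origin; truth lives only in the manifest.
    """
    from dataclasses import replace

    order = rng.permutation(len(pairs))
    width = max(6, len(str(max(len(pairs) - 1, 1))))
    return [
        replace(pairs[j], fragment_id=f"r{i:0{width}d}")
        for i, j in enumerate(order.tolist())
    ]


def build_dataset2_file(
    registry: Registry,
    scenario: ScenarioConfig,
    left_out_species: str,
    replicate_seed: int,
    out_prefix: str | Path,
) -> Tuple[Path, Path, Path]:
    """Build one leave-one-out mixture file (Dataset-2).

    Every microbial species except ``left_out_species`` contributes
    ``reads_per_species`` fragments; host fragments are appended so the
    microbial fraction matches the scenario prevalence.  Records are
    shuffled deterministically.  Returns (R1, R2, manifest) paths.
    """
    if left_out_species not in registry:
        raise KeyError(f"left-out species {left_out_species!r} not in registry")
    host = registry.host
    if host is None:
        raise ValueError("registry has no host record")
    included = [r for r in registry.microbial if r.species_id != left_out_species]
    if not included:
        raise ValueError("registry needs >= 2 microbial species")
    counts = solve_counts(
        scenario.reads_per_species, len(included), scenario.per_species_prevalence
    )
    rng = np.random.default_rng(replicate_seed)
    model = scenario.quality_model()
    pairs: List[ReadPair] = []
    for rec in included:
        pairs.extend(
            simulate_reads(
                registry.sequence(rec.species_id),
                scenario.reads_per_species,
                scenario.read_length,
                model,
                rng,
                species_id=rec.species_id,
                gap_min=scenario.gap_min,
                gap_max=scenario.gap_max,
                inject_errors=scenario.inject_errors,
            )
        )
    pairs.extend(
        simulate_reads(
            registry.sequence(host.species_id),
            counts.host_reads,
            scenario.read_length,
            model,
            rng,
            species_id=host.species_id,
            gap_min=scenario.gap_min,
            gap_max=scenario.gap_max,
            inject_errors=scenario.inject_errors,
        )
    )
    pairs = _relabel_and_shuffle(pairs, rng)
    r1, r2, manifest = write_fastq(pairs, out_prefix)
    manifest_path = Path(str(out_prefix) + ".truth.tsv")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return r1, r2, manifest_path


def build_dataset1_file(
    registry: Registry,
    scenario: ScenarioConfig,
    replicate_seed: int,
    out_prefix: str | Path,
) -> Tuple[Path, Path, Path]:
    """Build one host-only negative-control file (Dataset-1).

    Sized to match the Dataset-2 total so false-positive rates from the two
    datasets are directly comparable.
    """
    host = registry.host
    if host is None:
        raise ValueError("registry has no host record")
    n_mixed = max(len(registry.microbial) - 1, 1)
    counts = solve_counts(
        scenario.reads_per_species, n_mixed, scenario.per_species_prevalence
    )
    rng = np.random.default_rng(replicate_seed)
    pairs = simulate_reads(
        registry.sequence(host.species_id),
        counts.total_reads,
        scenario.read_length,
        scenario.quality_model(),
        rng,
        species_id=host.species_id,
        gap_min=scenario.gap_min,
        gap_max=scenario.gap_max,
        inject_errors=scenario.inject_errors,
    )
    pairs = _relabel_and_shuffle(pairs, rng)
    r1, r2, manifest = write_fastq(pairs, out_prefix)
    manifest_path = Path(str(out_prefix) + ".truth.tsv")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return r1, r2, manifest_path


@dataclass
class ExclusionDatabase:
    """Index of an emitted exclusion database.

    ``index`` has one row per file set: dataset (1 or 2), left_out species
    (empty for Dataset-1), replicate, seed, file paths and read count.
    """

    scenario: ScenarioConfig
    out_dir: Path
    index: pd.DataFrame

    INDEX_COLUMNS = [
        "dataset",
        "left_out",
        "replicate",
        "seed",
        "r1",
        "r2",
        "manifest",
        "n_reads",
    ]

    def write_index(self, path: Optional[str | Path] = None) -> Path:
        path = Path(path) if path else self.out_dir / "db_index.tsv"
        self.index.to_csv(path, sep="\t", index=False)
        return path

    @staticmethod
    def read_index(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", keep_default_na=False)


def build_exclusion_database(
    registry: Registry, scenario: ScenarioConfig, out_dir: str | Path
) -> ExclusionDatabase:
    """Build the full exclusion database for one scenario.

    Emits ``n_microbial_species x n_replicates`` Dataset-2 files plus
    ``n_replicates`` Dataset-1 files, each with a seed derived
    deterministically from (base_seed, scenario, left-out species,
    replicate), and an index TSV covering all of them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry.validate_for_read_length(scenario.read_length, scenario.gap_min)
    rows = []
    for rep in range(scenario.n_replicates):
        for rec in registry.microbial:
            seed = derive_seed(scenario.base_seed, scenario.name, rec.species_id, rep)
            prefix = out_dir / f"ds2_{rec.species_id}_rep{rep}"
            r1, r2, man = build_dataset2_file(
                registry, scenario, rec.species_id, seed, prefix
            )
            n_reads = solve_counts(
                scenario.reads_per_species,
                len(registry.microbial) - 1,
                scenario.per_species_prevalence,
            ).total_reads
            rows.append(
                {
                    "dataset": 2,
                    "left_out": rec.species_id,
                    "replicate": rep,
                    "seed": seed,
                    "r1": str(r1),
                    "r2": str(r2),
                    "manifest": str(man),
                    "n_reads": n_reads,
                }
            )
        seed = derive_seed(scenario.base_seed, scenario.name, "", rep)
        prefix = out_dir / f"ds1_rep{rep}"
        r1, r2, man = build_dataset1_file(registry, scenario, seed, prefix)
        rows.append(
            {
                "dataset": 1,
                "left_out": "",
                "replicate": rep,
                "seed": seed,
                "r1": str(r1),
                "r2": str(r2),
                "manifest": str(man),
                "n_reads": solve_counts(
                    scenario.reads_per_species,
                    max(len(registry.microbial) - 1, 1),
                    scenario.per_species_prevalence,
                ).total_reads,
            }
        )
    index = pd.DataFrame(rows, columns=ExclusionDatabase.INDEX_COLUMNS)
    db = ExclusionDatabase(scenario=scenario, out_dir=out_dir, index=index)
    db.write_index()
    return db


def preset_scenarios(base_seed: int = 0, n_replicates: int = 20) -> Dict[str, ScenarioConfig]:
    """The four named benchmark scenarios."""
    common = dict(base_seed=base_seed, n_replicates=n_replicates)
    return {
        "LPBQ": ScenarioConfig(
            name="LPBQ",
            reads_per_species=1_000,
            per_species_prevalence=0.015,
            read_length=48,
            mean_phred=23,
            **common,
        ),
        "HPBQ": ScenarioConfig(
            name="HPBQ",
            reads_per_species=10_000,
            per_species_prevalence=0.039,
            read_length=48,
            mean_phred=23,
            **common,
        ),
        "HPGQ": ScenarioConfig(
            name="HPGQ",
            reads_per_species=10_000,
            per_species_prevalence=0.039,
            read_length=48,
            mean_phred=35,
            **common,
        ),
        "LSHPGQ": ScenarioConfig(
            name="LSHPGQ",
            reads_per_species=10_000,
            per_species_prevalence=0.039,
            read_length=100,
            mean_phred=35,
            **common,
        ),
    }
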