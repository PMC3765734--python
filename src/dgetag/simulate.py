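"""Synthetic reference transcriptomes and tag libraries with known ground truth.

The generator emulates the structure of a two-species, four-stage DGE-tag
experiment: a transcript reference in which nearly every transcript carries
a CATG site with 17 clean nt downstream; per-transcript abundances drawn
log-normal (heavy-tailed, as tag libraries are); a multiplicative
between-condition noise term; a configurable fraction of genes with a fixed
between-species fold change; and tag reads that are the transcript's
canonical 17 nt payload behind an intact CATG anchor, subjected to i.i.d.
per-base substitution and N-call errors, plus a minority of
adaptor-contaminated reads.  Library depth is a parameter: the study-scale
millions of tags per library scale down to 1e4-1e5 for tests without
changing the statistical structure.

Determinism: one pseudo-random stream per library, derived from the master
seed by stable hashing of (species, stage), so output is byte-identical for
a given config regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import reference as ref
from .processing import STAGES, DEFAULT_ADAPTOR, TagLibrary


class ConfigurationError(ValueError):
    """Invalid simulation configuration (message names the offending field)."""


class SimulationError(RuntimeError):
    """Simulation cannot proceed (e.g. no taggable transcript)."""


_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    n_transcripts: int = 500
    transcript_length_range: tuple[int, int] = (200, 1500)
    gc_content: float = 0.42
    n_species: int = 2
    n_stages: int = 4
    depth_per_library: int = 100_000
    substitution_rate: float = 0.002
    n_rate: float = 0.001
    adaptor_read_fraction: float = 0.01
    adaptor_sequence: str = DEFAULT_ADAPTOR
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    seed: int = 0
    # distributional shape (unstated by any protocol; see docs/methods.md)
    lognormal_sigma: float = 1.2
    condition_sigma: float = 0.25
    taggable_fraction: float = 0.95
    read_length: int = 21  # 21 = anchor+tag only; 35 adds adaptor-2 bases

    def __post_init__(self):
        lo, hi = self.transcript_length_range
        checks = [
            (self.n_transcripts >= 0, "n_transcripts must be >= 0"),
            (lo >= 25, "transcript_length_range min must be >= 25 (CATG + 17 nt)"),
            (hi >= lo, "transcript_length_range max must be >= min"),
            (0 <= self.gc_content <= 1, "gc_content must be in [0, 1]"),
            (self.n_species >= 1, "n_species must be >= 1"),
            (1 <= self.n_stages <= len(STAGES), f"n_stages must be in [1, {len(STAGES)}]"),
            (self.depth_per_library >= 1, "depth_per_library must be >= 1"),
            (0 <= self.substitution_rate < 1, "substitution_rate must be in [0, 1)"),
            (0 <= self.n_rate < 1, "n_rate must be in [0, 1)"),
            (self.substitution_rate + self.n_rate < 1,
             "substitution_rate + n_rate must be < 1"),
            (0 <= self.adaptor_read_fraction < 1,
             "adaptor_read_fraction must be in [0, 1)"),
            (len(self.adaptor_sequence) >= 17, "adaptor_sequence must be >= 17 nt"),
            (0 <= self.de_fraction <= 1, "de_fraction must be in [0, 1]"),
            (self.de_log2fc > 0, "de_log2fc must be positive"),
            (0 <= self.taggable_fraction <= 1, "taggable_fraction must be in [0, 1]"),
            (self.read_length >= 21, "read_length must be >= 21"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    @property
    def stage_names(self) -> tuple[str, ...]:
        return STAGES[: self.n_stages]


@dataclass
class GroundTruth:
    """Expected per-library tag counts and per-transcript canonical tags."""

    expression: dict[tuple[str, str, str], float] = field(default_factory=dict)
    transcript_tags: dict[str, str] = field(default_factory=dict)
    contaminant_reads: dict[tuple[str, str], int] = field(default_factory=dict)
    de_genes: dict[str, int] = field(default_factory=dict)  # transcript -> fc sign

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, species, stage, expected)
            for (tid, species, stage), expected in sorted(self.expression.items())
        ]
        return pd.DataFrame(
            rows, columns=["transcript_id", "species", "stage", "expected_count"]
        )


def _library_rng(seed: int, species: str, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed, zlib.crc32(species.encode()), zlib.crc32(stage.encode())]
    )


def simulate_reference(config: SimulationConfig) -> list[SeqRecord]:
    """Random transcript sequences at the configured GC content.

    For a ``taggable_fraction`` share of transcripts a CATG site with >= 17
    nt downstream is guaranteed (inserted at a random admissible position if
    the random sequence lacks one); the remainder are left as drawn.  Each
    record's description flags whether it is taggable.
    """
    rng = np.random.default_rng([config.seed, zlib.crc32(b"reference")])
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lo, hi = config.transcript_length_range
    records = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        seq = _BASES[codes].tobytes().decode()
        force_taggable = rng.random() < config.taggable_fraction
        if force_taggable and not ref.extract_virtual_tags(f"T{i:05d}", seq):
            pos = int(rng.integers(0, length - 20))
            seq = seq[:pos] + "CATG" + seq[pos + 4:]
        taggable = int(bool(ref.extract_virtual_tags(f"T{i:05d}", seq)))
        records.append(
            SeqRecord(Seq(seq), id=f"T{i:05d}", description=f"taggable={taggable}")
        )
    return records


def _expression_weights(
    config: SimulationConfig, transcript_ids: list[str]
) -> tuple[np.ndarray, dict[str, int]]:
    """Base log-normal abundances and injected DE signs (species-2 effect)."""
    rng = np.random.default_rng([config.seed, zlib.crc32(b"expression")])
    n = len(transcript_ids)
    base = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    # Fold-change signs are assigned greedily so that total transcript
    # output is (approximately) conserved between species: otherwise the
    # library-size renormalization would shift every null gene's expected
    # proportion by a common factor and the genes injected at +-de_log2fc
    # would no longer be the only between-species signal.
    fc_up = 2.0 ** config.de_log2fc
    fc_dn = 2.0 ** -config.de_log2fc
    de_genes: dict[str, int] = {}
    delta = 0.0
    for i in de_idx[np.argsort(-base[de_idx])]:
        d_up = base[i] * (fc_up - 1.0)
        d_dn = base[i] * (fc_dn - 1.0)
        if abs(delta + d_up) <= abs(delta + d_dn):
            de_genes[transcript_ids[i]] = 1
            delta += d_up
        else:
            de_genes[transcript_ids[i]] = -1
            delta += d_dn
    return base, de_genes


def _read_matrix(
    tags: np.ndarray, counts: np.ndarray, rng: np.random.Generator,
    sub_rate: float, n_rate: float,
) -> np.ndarray:
    """Error-perturbed (reads x 17) base-code matrix from per-transcript counts."""
    reads = np.repeat(tags, counts, axis=0).copy()
    if sub_rate > 0 or n_rate > 0:
        u = rng.random(reads.shape)
        sub_mask = (u >= n_rate) & (u < n_rate + sub_rate)
        if sub_mask.any():
            shift = rng.integers(1, 4, size=int(sub_mask.sum()))
            reads[sub_mask] = (reads[sub_mask] + shift) % 4
        reads[u < n_rate] = 4  # N
    return reads


def simulate_libraries(
    records: Iterable[SeqRecord], config: SimulationConfig
) -> tuple[dict[tuple[str, str], TagLibrary], GroundTruth]:
    """Simulate one tag library per species x stage plus the ground truth.

    Each library holds exactly ``depth_per_library`` reads: a binomial
    number of adaptor-contaminated reads, the rest multinomial over
    transcript weights; every transcript read is its canonical tag with
    i.i.d. per-base N/substitution errors on the 17 nt payload.
    """
    records = list(records)
    if not records:
        raise SimulationError("empty reference")
    tag_by_tid: dict[str, str] = {}
    for rec in records:
        tags = ref.extract_virtual_tags(rec.id, str(rec.seq))
        if tags:
            tag_by_tid[rec.id] = tags[0].tag17
    if not tag_by_tid:
        raise SimulationError("reference contains no taggable transcript")
    tids = sorted(tag_by_tid)
    tag_matrix = np.frombuffer(
        "".join(tag_by_tid[t] for t in tids).encode(), dtype=np.uint8
    ).reshape(len(tids), 17)
    # back to 0..3 codes
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    tag_codes = lut[tag_matrix]

    base, de_genes = _expression_weights(config, tids)
    truth = GroundTruth(transcript_tags=dict(tag_by_tid), de_genes=de_genes)
    libraries: dict[tuple[str, str], TagLibrary] = {}
    adaptor_tag = config.adaptor_sequence[:17]
    decode = _BASES  # code -> ASCII

    for si, species in enumerate(config.species_names):
        abund = base.copy()
        if si > 0:
            for tid, sign in de_genes.items():
                abund[tids.index(tid)] *= 2.0 ** (sign * config.de_log2fc)
        for stage in config.stage_names:
            # stage effect is shared between species so that, within a stage,
            # the injected fold changes are the only between-species signal
            stage_rng = np.random.default_rng(
                [config.seed, zlib.crc32(b"stage-effect"), zlib.crc32(stage.encode())]
            )
            noise = stage_rng.lognormal(0.0, config.condition_sigma, size=len(tids))
            rng = _library_rng(config.seed, species, stage)
            weights = abund * noise
            weights = weights / weights.sum()
            depth = config.depth_per_library
            n_adaptor = int(rng.binomial(depth, config.adaptor_read_fraction))
            counts = rng.multinomial(depth - n_adaptor, weights)
            reads = _read_matrix(
                tag_codes, counts, rng, config.substitution_rate, config.n_rate
            )
            ascii_reads = np.ascontiguousarray(decode[reads])
            uniq, uniq_counts = np.unique(ascii_reads.view("S17").ravel(),
                                          return_counts=True)
            raw = {u.decode(): int(c) for u, c in zip(uniq, uniq_counts)}
            if n_adaptor:
                raw[adaptor_tag] = raw.get(adaptor_tag, 0) + n_adaptor
            libraries[(species, stage)] = TagLibrary(
                species, stage, raw, raw_reads=depth
            )
            truth.contaminant_reads[(species, stage)] = n_adaptor
            expected = depth * (1 - config.adaptor_read_fraction) * weights
            for tid, e in zip(tids, expected):
                truth.expression[(tid, species, stage)] = float(e)
    return libraries, truth


def library_reads(
    library: TagLibrary, config: SimulationConfig, anchor: str = "CATG"
) -> list[str]:
    """Expand a simulated library's raw counts into full read sequences.

    Reads are anchor + tag, padded to ``config.read_length`` with
    adaptor-2 bases (deterministic order: sorted tag, then repeats).
    """
    pad = config.adaptor_sequence
    reads = []
    for tag in sorted(library.raw_counts):
        read = anchor + tag
        if config.read_length > len(read):
            read = (read + pad * 4)[: config.read_length]
        reads.extend([read] * library.raw_counts[tag])
    return reads
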