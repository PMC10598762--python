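"""Synthetic barcode corpora with controlled within/between-species divergence.

Real ITS barcode reference sets have three statistical features the
classifier relies on: strong class imbalance (tens to hundreds of sequences
per species), broad length variation (roughly 200-2000 bases), and a clear
divergence contrast — sequences of the same species are nearly identical
while different species differ at a few percent of positions or more.

The generator reproduces exactly that structure with a star phylogeny per
species: a single dataset root sequence is drawn uniformly over ACGT; each
species ancestor is a length-L_s prefix of the root mutated at the
between-species substitution rate ``d``; each record is its species ancestor
mutated independently at the within-species rate ``mu`` (optionally with
indels).  Two species ancestors therefore differ at ~2d(1-d) of their shared
positions in expectation, and two records of one species at ~2mu(1-mu).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .barcode_io import (
    BarcodeDataset,
    BarcodeRecord,
    DatasetManifest,
    ManifestRow,
    encode_labels,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "termitomyces_profile",
    "TERMITOMYCES_SPECIES",
    "TERMITOMYCES_COUNTS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The 17 Termitomyces (and allied) species of the published ITS reference
#: corpus compiled from NCBI GenBank and BOLD, with their sequence counts
#: after the minimum-7-sequences filter (1704 records total).  Names are
#: verbatim, including provisional labels, since each is its own class.
TERMITOMYCES_SPECIES: tuple[str, ...] = (
    "Uncultured Termitomyces",
    "Termitomyces sp.",
    "Termitomyces intermedius",
    "Termitomyces symbiont",
    "Termitomyces microcarpus",
    "Termitomyces clypeatus",
    "Termitomyces cylindricus",
    "Termitomyces striatus",
    "Termitomyces DKA-2007",
    "Termitomyces heimii",
    "Termitomyces bulborhizus",
    "Termitomyces fuliginosus",
    "Termitomyces eurrhizus",
    "Termitomyces albuminosus",
    "Termitomyces sp. symbiont of Macrotermes bellicosus",
    "Termitomyces sp. symbiont of Macrotermes subhyalinus",
    "Uncultured Ascomycota",
)

TERMITOMYCES_COUNTS: tuple[int, ...] = (
    799, 483, 94, 60, 34, 33, 30, 29, 24, 24, 17, 16, 15, 14, 12, 10, 10,
)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic corpus.

    Parameters
    ----------
    n_species:
        Number of classes.
    counts:
        Explicit per-species record counts; when None, counts are drawn
        log-uniform over ``count_range`` to mimic the long-tailed imbalance
        of repository data.
    count_range:
        (low, high) bounds of the log-uniform class-size sampler.
    length_range:
        Ancestor length bounds in bases; real ITS barcodes span roughly
        200-2000.
    divergence:
        Between-species substitution fraction ``d`` applied root -> ancestor.
    noise:
        Within-species substitution fraction ``mu`` applied ancestor -> record.
    indel_rate:
        Per-base insertion/deletion probability applied ancestor -> record
        (default off: length variation already comes from ancestor lengths
        and the feature model is alignment-free).
    species_names:
        Optional explicit class names; default ``Species_000`` ...
    seed:
        Seed of the single PRNG driving every draw.
    """

    n_species: int = 17
    counts: Sequence[int] | None = None
    count_range: tuple[int, int] = (10, 800)
    length_range: tuple[int, int] = (200, 2000)
    divergence: float = 0.05
    noise: float = 0.005
    indel_rate: float = 0.0
    species_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name, rate in (
            ("divergence", self.divergence),
            ("noise", self.noise),
            ("indel_rate", self.indel_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.noise > self.divergence:
            warnings.warn(
                "within-species noise exceeds between-species divergence; "
                "classes will overlap heavily",
                stacklevel=2,
            )
        if self.counts is not None:
            if len(self.counts) != self.n_species:
                raise ValueError("counts must have one entry per species")
            if min(self.counts) < 1:
                raise ValueError("every species needs at least one record")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")
        if self.species_names is not None and len(self.species_names) != self.n_species:
            raise ValueError("species_names must have one entry per species")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated corpus: ancestors and per-record mutations."""

    root: str
    ancestors: dict[str, str]
    #: record_id -> sorted substituted positions (on the ancestor coordinate)
    substitutions: dict[str, list[int]] = field(default_factory=dict)
    #: record_id -> number of indel events applied
    indels: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _substitute(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each position independently with probability ``rate``.

    A substituted base is drawn uniformly among the 3 alternatives, so every
    flagged position really changes.  Returns (mutated copy, positions).
    """
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        # offset 1..3 from the current base, cyclic over ACGT
        current = np.searchsorted(_BASES, out[hits])
        offset = rng.integers(1, 4, size=hits.size)
        out[hits] = _BASES[(current + offset) % 4]
    return out, hits


def _apply_indels(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    if rate <= 0.0:
        return seq, 0
    events = 0
    out: list[int] = []
    for base in seq:
        if rng.random() < rate:
            events += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(int(base))
            out.append(int(_BASES[rng.integers(0, 4)]))  # insertion after
        else:
            out.append(int(base))
    if not out:  # degenerate: everything deleted
        out = [int(_BASES[rng.integers(0, 4)])]
    return np.asarray(out, dtype=np.uint8), events


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[BarcodeDataset, SyntheticTruth]:
    """Generate a labeled synthetic corpus plus its ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    sequences, record IDs and ordering.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    root = _random_seq(rng, hi)

    if config.counts is not None:
        counts = [int(c) for c in config.counts]
    else:
        c_lo, c_hi = config.count_range
        draws = rng.uniform(math.log(c_lo), math.log(c_hi), size=config.n_species)
        counts = [int(round(math.exp(x))) for x in draws]

    if config.species_names is not None:
        names = [str(n) for n in config.species_names]
    else:
        names = [f"Species_{s:03d}" for s in range(config.n_species)]

    truth = SyntheticTruth(root=root.tobytes().decode(), ancestors={})
    records: list[BarcodeRecord] = []
    for s, name in enumerate(names):
        length = int(rng.integers(lo, hi + 1))
        ancestor, _ = _substitute(root[:length], config.divergence, rng)
        truth.ancestors[name] = ancestor.tobytes().decode()
        for j in range(counts[s]):
            seq, subs = _substitute(ancestor, config.noise, rng)
            seq, n_indels = _apply_indels(seq, config.indel_rate, rng)
            record_id = f"SYN{s:03d}_{j:04d}"
            records.append(
                BarcodeRecord(record_id, name, seq.tobytes().decode())
            )
            truth.substitutions[record_id] = [int(p) for p in subs]
            if n_indels:
                truth.indels[record_id] = n_indels

    dataset = BarcodeDataset(
        records=records, label_map=encode_labels(names), min_count=0
    )
    return dataset, truth


def termitomyces_profile(**overrides) -> SyntheticConfig:
    """Config mirroring the 17-species Termitomyces ITS reference corpus.

    Class sizes are exactly the published per-species sequence counts
    (1704 records over 17 classes, largest 799, smallest 10); divergence
    parameters keep their defaults unless overridden.
    """
    base = dict(
        n_species=len(TERMITOMYCES_SPECIES),
        counts=TERMITOMYCES_COUNTS,
        species_names=TERMITOMYCES_SPECIES,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def dataset_manifest(dataset: BarcodeDataset, source: str = "other") -> DatasetManifest:
    """Manifest rows for a generated dataset (all records one source)."""
    return DatasetManifest(
        [
            ManifestRow(r.record_id, r.species, source=source, length=len(r))
            for r in dataset.records
        ]
    )
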