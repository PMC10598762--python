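"""Reading, writing and assembly of labeled DNA-barcode datasets.

A dataset is a list of identified barcode sequences (FASTA) plus a manifest
(TSV) mapping record IDs to verbatim species names.  The manifest is the
authoritative source of species labels; a ``species=`` token in the FASTA
description line is accepted as a fallback so self-describing FASTA files
round-trip without a manifest.

Species names are treated verbatim — ``"Termitomyces sp."`` and
``"Uncultured Termitomyces"`` are distinct classes, as is conventional for
barcode reference sets where provisional names carry real signal.  Integer
class codes are assigned by case-sensitive lexicographic (byte-order) sort of
the names, which makes label maps reproducible from the names alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "BarcodeDataset",
    "ManifestRow",
    "DatasetManifest",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_manifest",
    "encode_labels",
    "deduplicate",
    "filter_min_count",
    "assemble_dataset",
]

#: default minimum number of sequences a species needs to stay in the dataset
DEFAULT_MIN_COUNT = 7

_SPECIES_TOKEN = "species="


@dataclass(frozen=True)
class BarcodeRecord:
    """One identified barcode sequence.

    Parameters
    ----------
    record_id:
        Unique accession-like identifier (e.g. ``"MF163136"``).
    species:
        Verbatim species name.
    sequence:
        Nucleotide string over the IUPAC alphabet; stored uppercase.
    """

    record_id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"record {self.record_id!r}: sequence contains whitespace")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ManifestRow:
    record_id: str
    species: str
    source: str = "other"
    length: int | None = None


@dataclass
class DatasetManifest:
    """Record-to-species mapping, one row per record ID."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.record_id in seen:
                raise ValueError(f"duplicate record_id in manifest: {row.record_id!r}")
            if not row.species:
                raise ValueError(f"manifest row {row.record_id!r}: empty species")
            seen.add(row.record_id)

    def species_of(self) -> dict[str, str]:
        return {r.record_id: r.species for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class BarcodeDataset:
    """Filtered record collection with an integer label map.

    ``label_map`` assigns codes ``0..S-1`` by byte-order sort of the species
    names; every retained species has at least ``min_count`` records.
    """

    records: list[BarcodeRecord]
    label_map: dict[str, int]
    min_count: int = 0

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.species not in self.label_map:
                raise ValueError(f"species {rec.species!r} missing from label_map")
        codes = sorted(self.label_map.values())
        if codes != list(range(len(codes))):
            raise ValueError("label codes must be 0..S-1 with no gaps")

    # -- basic views ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(self.label_map)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int]:
        """Integer class code of each record, in record order."""
        return [self.label_map[r.species] for r in self.records]

    @property
    def inverse_label_map(self) -> dict[int, str]:
        return {code: name for name, code in self.label_map.items()}

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {name: 0 for name in self.label_map}
        for rec in self.records:
            counts[rec.species] += 1
        return counts

    def subset(self, indices: Sequence[int]) -> "BarcodeDataset":
        """New dataset with the same label map restricted to ``indices``."""
        return BarcodeDataset(
            records=[self.records[i] for i in indices],
            label_map=dict(self.label_map),
            min_count=0,
        )

    def summary(self) -> pd.DataFrame:
        """Per-species table (species, code, n_sequences), largest class first."""
        counts = self.species_counts()
        frame = pd.DataFrame(
            {
                "species": list(counts),
                "code": [self.label_map[s] for s in counts],
                "n_sequences": [counts[s] for s in counts],
            }
        )
        return frame.sort_values(
            ["n_sequences", "species"], ascending=[False, True]
        ).reset_index(drop=True)

    def write_summary(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA and manifest I/O
# ---------------------------------------------------------------------------


def _species_from_description(description: str) -> str:
    """Extract a trailing ``species=<name>`` token; names may contain spaces."""
    if _SPECIES_TOKEN in description:
        return description.split(_SPECIES_TOKEN, 1)[1].strip()
    return ""


def read_fasta(
    path: str | Path, manifest: DatasetManifest | None = None
) -> list[BarcodeRecord]:
    """Read barcode records from a FASTA file.

    Species come from ``manifest`` when given (authoritative), otherwise from a
    ``species=`` token in the description line; records with neither get an
    empty species string.  Residues are uppercased; record order is preserved.

    Raises
    ------
    ValueError
        On a duplicate record ID or a record with an empty sequence, naming
        the offending record.
    """
    species_by_id = manifest.species_of() if manifest is not None else {}
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record ID in FASTA: {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"FASTA record {entry.id!r} has an empty sequence")
        species = species_by_id.get(entry.id) or _species_from_description(
            entry.description
        )
        records.append(BarcodeRecord(entry.id, species, seq))
    return records


def write_fasta(
    records: Iterable[BarcodeRecord], path: str | Path, species_token: bool = True
) -> None:
    """Write records as FASTA; headers carry ``|species=<name>`` by default."""
    entries = []
    for rec in records:
        desc = f"|{_SPECIES_TOKEN}{rec.species}" if species_token and rec.species else ""
        entries.append(SeqRecord(Seq(rec.sequence), id=rec.record_id, description=desc))
    SeqIO.write(entries, str(path), "fasta")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a TSV manifest with header ``record_id<TAB>species<TAB>source``."""
    rows: list[ManifestRow] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"record_id", "species"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"manifest {path}: header must contain columns {sorted(required)}"
            )
        for raw in reader:
            length = raw.get("length")
            rows.append(
                ManifestRow(
                    record_id=raw["record_id"],
                    species=raw["species"],
                    source=raw.get("source") or "other",
                    length=int(length) if length else None,
                )
            )
    return DatasetManifest(rows)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "species", "source", "length"])
        for row in manifest.rows:
            writer.writerow(
                [row.record_id, row.species, row.source, row.length or ""]
            )


# ---------------------------------------------------------------------------
# Label encoding and filtering
# ---------------------------------------------------------------------------


def encode_labels(species_names: Iterable[str]) -> dict[str, int]:
    """Assign integer codes 0..S-1 by case-sensitive byte-order sort.

    The sort is over the verbatim species strings, so uppercase-initial names
    (strain designations, "Uncultured ...") order before lowercase epithets in
    the usual ASCII way.  Deterministic: the codes are a pure function of the
    name set.
    """
    names = sorted(set(species_names))
    if not names:
        raise ValueError("encode_labels requires at least one species name")
    return {name: code for code, name in enumerate(names)}


def deduplicate(records: Sequence[BarcodeRecord]) -> list[BarcodeRecord]:
    """Drop records whose (species, exact sequence) pair was already seen.

    Merging mirrored repositories (NCBI and BOLD both carry many of the same
    barcodes) otherwise double-counts sequences.  First occurrence wins; order
    is preserved.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[BarcodeRecord] = []
    for rec in records:
        key = (rec.species, rec.sequence)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return kept


def filter_min_count(
    records: Sequence[BarcodeRecord], min_count: int = DEFAULT_MIN_COUNT
) -> BarcodeDataset:
    """Drop every species with fewer than ``min_count`` records.

    Surviving records keep their input order; the label map is rebuilt from
    the surviving species only, so codes stay 0..S-1.

    Raises
    ------
    ValueError
        If ``min_count`` is negative or the filter removes every record.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.species] = counts.get(rec.species, 0) + 1
    keep = {name for name, n in counts.items() if n >= min_count}
    survivors = [rec for rec in records if rec.species in keep]
    if not survivors:
        raise ValueError(
            f"empty dataset: no species has >= {min_count} sequences"
        )
    return BarcodeDataset(
        records=survivors, label_map=encode_labels(keep), min_count=min_count
    )


def assemble_dataset(
    records: Sequence[BarcodeRecord],
    min_count: int = DEFAULT_MIN_COUNT,
    drop_duplicates: bool = True,
) -> BarcodeDataset:
    """Deduplicate (optionally) and apply the minimum-count filter."""
    pool = deduplicate(records) if drop_duplicates else list(records)
    return filter_min_count(pool, min_count=min_count)
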