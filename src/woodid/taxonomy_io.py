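"""Dataset manifests and the species -> genus -> family taxonomy.

A dataset is described by a flat CSV manifest with one row per image and
columns ``image_path, species, genus, family, tree_id, view`` (optionally
``specimen_id, piece_index, transform``).  The taxonomy is deduplicated from
the manifest rows and validated: a species belongs to exactly one genus and a
genus to exactly one family.

The three anatomical views of a wood sample are ``transverse`` (perpendicular
to the stem axis), ``tangential`` (across the rays) and ``radial`` (parallel
to the rays).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

VIEWS = ("transverse", "tangential", "radial")
TRANSFORMS = ("original", "smoothed", "rotated", "noisy")


class ManifestFormatError(ValueError):
    """Manifest is structurally invalid (missing column, bad enum value)."""


class TaxonomyConsistencyError(ValueError):
    """Species/genus/family mapping is contradictory across rows."""


@dataclass(frozen=True)
class TaxonomyTable:
    """Strict three-level hierarchy: species < genus < family."""

    entries: Mapping[str, tuple[str, str]]  # species -> (genus, family)

    def __post_init__(self) -> None:
        genus_family: dict[str, str] = {}
        for species, (genus, fam) in self.entries.items():
            if not species or not genus or not fam:
                raise TaxonomyConsistencyError(
                    f"empty name in taxonomy entry {species!r} -> ({genus!r}, {fam!r})"
                )
            seen = genus_family.setdefault(genus, fam)
            if seen != fam:
                raise TaxonomyConsistencyError(
                    f"genus {genus!r} mapped to two families: {seen!r} and {fam!r}"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.entries)

    def genus(self, species: str) -> str:
        return self._lookup(species)[0]

    def family(self, species: str) -> str:
        return self._lookup(species)[1]

    def _lookup(self, species: str) -> tuple[str, str]:
        try:
            return self.entries[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in taxonomy") from None

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def from_rows(rows: Iterable[tuple[str, str, str]]) -> "TaxonomyTable":
        """Build from (species, genus, family) triples, checking consistency."""
        entries: dict[str, tuple[str, str]] = {}
        for species, genus, fam in rows:
            species, genus, fam = species.strip(), genus.strip(), fam.strip()
            prev = entries.setdefault(species, (genus, fam))
            if prev != (genus, fam):
                raise TaxonomyConsistencyError(
                    f"species {species!r} mapped to both {prev} and {(genus, fam)}"
                )
        return TaxonomyTable(entries)

    def taxonomy_order(self) -> list[str]:
        """Species sorted by family, then genus, then species name."""
        return sorted(self.entries, key=lambda s: (*self.entries[s][::-1], s))


@dataclass(frozen=True)
class ImageRecord:
    """One image together with its labels and provenance."""

    image_id: str
    path: str
    species: str
    tree_id: str
    view: str
    specimen_id: str = ""
    piece_index: int = 0
    transform: str = "original"

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ManifestFormatError(
                f"unknown view {self.view!r} for {self.image_id!r}; expected one of {VIEWS}"
            )
        if self.transform not in TRANSFORMS:
            raise ManifestFormatError(
                f"unknown transform {self.transform!r} for {self.image_id!r}"
            )
        if self.piece_index < 0:
            raise ManifestFormatError(f"negative piece_index for {self.image_id!r}")
        if not self.specimen_id:
            object.__setattr__(self, "specimen_id", self.image_id)

    @property
    def group_id(self) -> str:
        """Identifier linking the three views of one specimen piece."""
        return f"{self.specimen_id}#p{self.piece_index}"


@dataclass
class DatasetIndex:
    """All records of a dataset plus the taxonomy they are labelled against."""

    records: list[ImageRecord] = field(default_factory=list)
    taxonomy: TaxonomyTable = field(default_factory=lambda: TaxonomyTable({}))
    root: Path = Path(".")

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestFormatError(f"duplicate image_id(s): {dup[:5]}")
        seen: set[tuple[str, int, str]] = set()
        for r in self.records:
            if r.species not in self.taxonomy:
                raise TaxonomyConsistencyError(
                    f"record {r.image_id!r} labelled with unknown species {r.species!r}"
                )
            key = (r.specimen_id, r.piece_index, r.view)
            if key in seen:
                raise ManifestFormatError(
                    f"two records for specimen {r.specimen_id!r} piece "
                    f"{r.piece_index} view {r.view!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, image_ids: Iterable[str]) -> "DatasetIndex":
        keep = set(image_ids)
        return DatasetIndex(
            [r for r in self.records if r.image_id in keep], self.taxonomy, self.root
        )


_REQUIRED = ("image_path", "species", "genus", "family", "tree_id", "view")


def load_manifest(manifest_path: str | Path) -> DatasetIndex:
    """Read a manifest CSV into a :class:`DatasetIndex`.

    The taxonomy is deduplicated from the rows; contradictory genus/family
    assignments raise :class:`TaxonomyConsistencyError`.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED:
            if col not in header:
                raise ManifestFormatError(
                    f"manifest {manifest_path} is missing required column {col!r}"
                )
        rows = list(reader)

    taxonomy = TaxonomyTable.from_rows(
        (r["species"], r["genus"], r["family"]) for r in rows
    )
    records = []
    for i, r in enumerate(rows):
        path = r["image_path"].strip()
        records.append(
            ImageRecord(
                image_id=r.get("image_id", "").strip() or Path(path).stem or f"row{i}",
                path=path,
                species=r["species"].strip(),
                tree_id=r["tree_id"].strip(),
                view=r["view"].strip(),
                specimen_id=r.get("specimen_id", "").strip(),
                piece_index=int(r["piece_index"]) if r.get("piece_index") else 0,
                transform=r.get("transform", "").strip() or "original",
            )
        )
    return DatasetIndex(records, taxonomy, root=manifest_path.parent)


def save_manifest(index: DatasetIndex, manifest_path: str | Path) -> None:
    """Write a manifest CSV that round-trips through :func:`load_manifest`."""
    cols = [
        "image_id", "image_path", "species", "genus", "family",
        "tree_id", "view", "specimen_id", "piece_index", "transform",
    ]
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in index.records:
            genus, fam = index.taxonomy.entries[r.species]
            writer.writerow(
                [r.image_id, r.path, r.species, genus, fam,
                 r.tree_id, r.view, r.specimen_id, r.piece_index, r.transform]
            )


def load_taxonomy_csv(path: str | Path) -> TaxonomyTable:
    """Read a standalone taxonomy CSV with columns species, genus, family."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("species", "genus", "family"):
            if col not in (reader.fieldnames or []):
                raise ManifestFormatError(f"taxonomy CSV missing column {col!r}")
        return TaxonomyTable.from_rows(
            (r["species"], r["genus"], r["family"]) for r in reader
        )


def congo_taxonomy() -> TaxonomyTable:
    """The bundled 77-species taxonomy of the Congo-basin timber dataset.

    Species and family labels follow the published species table of the
    reference collection (Tervuren Wood Collection); the genus is the first
    epithet of the binomial.
    """
    ref = resources.files("woodid.data") / "congo_taxonomy.csv"
    with resources.as_file(ref) as path:
        return load_taxonomy_csv(path)


def congo_sample_counts() -> dict[str, int]:
    """Per-species sample counts of the reference dataset (805 in total)."""
    ref = resources.files("woodid.data") / "congo_taxonomy.csv"
    counts: dict[str, int] = {}
    with resources.as_file(ref) as path, open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            counts[row["species"]] = int(row["n_samples"])
    return counts


def trees_of(index: DatasetIndex) -> dict[str, list[ImageRecord]]:
    """Group records by physical tree.

    The returned mapping is a partition of ``index.records``: every record
    appears under exactly its own ``tree_id``.
    """
    out: dict[str, list[ImageRecord]] = {}
    for r in index.records:
        out.setdefault(r.tree_id, []).append(r)
    return out


__all__ = [
    "VIEWS", "TRANSFORMS",
    "TaxonomyTable", "ImageRecord", "DatasetIndex",
    "ManifestFormatError", "TaxonomyConsistencyError",
    "load_manifest", "save_manifest", "load_taxonomy_csv",
    "congo_taxonomy", "congo_sample_counts", "trees_of",
]
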