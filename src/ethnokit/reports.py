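"""Use-report data model, tabular IO and validation.

The atomic record of an ethnomedicinal survey is the *use report* (use
citation): one informant stating that one plant species treats one ailment.
All consensus statistics count these deduplicated (informant, species,
ailment) triples; descriptive attributes (plant part, preparation mode,
administration route) are multi-valued and live as attribute sets on the
triple so that composite cells such as "infusion, brewing" never inflate
citation counts.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ROUTES",
    "CANONICAL_CATEGORIES",
    "UseReport",
    "SpeciesRecord",
    "AilmentCategoryMap",
    "ValidationIssue",
    "ValidationReport",
    "read_use_reports",
    "write_use_reports",
    "read_species_table",
    "write_species_table",
    "resolve_categories",
    "validate_dataset",
]

#: Admissible administration routes.
ROUTES = ("oral", "topical")

#: The 16 Heinrich-style ailment categories used to bin free-text ailments.
CANONICAL_CATEGORIES = (
    "Muscular-skeletal disorders",
    "Pains",
    "Respiratory system disorders",
    "Liver complaints",
    "Cuts and wounds",
    "Inflammation",
    "Genitourinary system disorders",
    "Circulatory system disorders",
    "Skin diseases and disorders",
    "Gastrointestinal disorders",
    "Diabetes",
    "Nervous system disorders",
    "Veterinary ailments",
    "Poisonings",
    "Others",
    "Birth-related disorders",
)

#: Default CSV column names; pass a mapping to the readers to override.
DEFAULT_COLUMNS = {
    "informant_id": "informant_id",
    "species_id": "species_id",
    "ailment": "ailment",
    "plant_part": "plant_part",
    "preparation": "preparation",
    "route": "route",
}


def _split_cell(cell: str) -> frozenset[str]:
    """Split a composite comma-separated cell into an attribute set."""
    return frozenset(p.strip() for p in str(cell).split(",") if p.strip())


@dataclass(frozen=True)
class UseReport:
    """One informant's citation of one species for one ailment."""

    informant_id: str
    species_id: str
    ailment: str
    plant_parts: frozenset = frozenset()
    preparations: frozenset = frozenset()
    routes: frozenset = frozenset()
    category: str | None = None

    def __post_init__(self) -> None:
        for name in ("informant_id", "species_id", "ailment"):
            if not str(getattr(self, name)).strip():
                raise ValidationError(f"UseReport field {name!r} must be non-empty")
        bad = set(self.routes) - set(ROUTES)
        if bad:
            raise ValidationError(
                f"invalid route(s) {sorted(bad)}; allowed: {list(ROUTES)}"
            )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.informant_id, self.species_id, self.ailment)

    def merged_with(self, other: "UseReport") -> "UseReport":
        """Union the attribute sets of two reports sharing a triple."""
        if self.triple != other.triple:
            raise ValueError("cannot merge reports with different triples")
        return replace(
            self,
            plant_parts=self.plant_parts | other.plant_parts,
            preparations=self.preparations | other.preparations,
            routes=self.routes | other.routes,
            category=self.category or other.category,
        )


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species voucher table."""

    species_id: str
    scientific_name: str = ""
    family: str = ""
    local_name: str = ""
    voucher: str = ""

    def __post_init__(self) -> None:
        if not str(self.species_id).strip():
            raise ValidationError("species_id must be non-empty")


@dataclass(frozen=True)
class AilmentCategoryMap:
    """Total map from free-text ailment labels to ailment categories."""

    mapping: Mapping[str, str]
    categories: tuple = CANONICAL_CATEGORIES

    def __post_init__(self) -> None:
        unknown = sorted(set(self.mapping.values()) - set(self.categories))
        if unknown:
            raise ValidationError(
                f"mapped categories not in the canonical list: {unknown}"
            )

    def __getitem__(self, ailment: str) -> str:
        return self.mapping[ailment]

    def __contains__(self, ailment: str) -> bool:
        return ailment in self.mapping

    def unmapped(self, ailments: Iterable[str]) -> list[str]:
        return sorted({a for a in ailments if a not in self.mapping})

    @classmethod
    def from_csv(cls, path: str | Path, categories: Sequence[str] | None = None):
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        if rows and not {"ailment", "category"} <= set(rows[0]):
            raise SchemaError("category map CSV needs 'ailment' and 'category' columns")
        mapping = {r["ailment"]: r["category"] for r in rows}
        if categories is not None:
            cats = tuple(categories)
        elif set(mapping.values()) <= set(CANONICAL_CATEGORIES):
            cats = CANONICAL_CATEGORIES
        else:  # user-extended taxonomy: the file defines its own categories
            cats = tuple(sorted(set(mapping.values())))
        return cls(mapping=mapping, categories=cats)

    @classmethod
    def from_yaml(cls, path: str | Path):
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc, Mapping) and "mapping" in doc:
            cats = tuple(doc.get("categories", CANONICAL_CATEGORIES))
            return cls(mapping=dict(doc["mapping"]), categories=cats)
        return cls(mapping=dict(doc))

    @classmethod
    def bundled(cls):
        """The editable starter taxonomy shipped with the package."""
        ref = resources.files("ethnokit.data").joinpath("ailment_categories.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["ailment", "category"])
            for ailment in sorted(self.mapping):
                writer.writerow([ailment, self.mapping[ailment]])


def _resolve_columns(header: Sequence[str], columns: Mapping[str, str] | None,
                     required: Sequence[str]) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    for key in required:
        if cols[key] not in header:
            raise SchemaError(
                f"missing required column {cols[key]!r} (for field {key!r}); "
                f"found columns: {list(header)}"
            )
    return cols


def read_use_reports(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    merge_duplicates: bool = True,
) -> list[UseReport]:
    """Read a tidy use-report CSV into deduplicated :class:`UseReport` records.

    Composite comma-separated cells become attribute sets on a single record.
    Duplicate (informant, species, ailment) triples are merged with attribute
    union and a logged warning; pass ``merge_duplicates=False`` to keep one
    record per row (used by validation to surface duplicates).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        cols = _resolve_columns(
            reader.fieldnames, columns,
            required=("informant_id", "species_id", "ailment"),
        )
        out: list[UseReport] = []
        merged: dict[tuple[str, str, str], UseReport] = {}
        n_dup = 0
        for lineno, row in enumerate(reader, start=2):
            routes = _split_cell(row.get(cols["route"], "") or "")
            bad = {r for r in routes if r not in ROUTES}
            if bad:
                raise ValidationError(
                    f"{path}: row {lineno}: unparseable route value(s) {sorted(bad)}"
                )
            try:
                report = UseReport(
                    informant_id=str(row[cols["informant_id"]]).strip(),
                    species_id=str(row[cols["species_id"]]).strip(),
                    ailment=str(row[cols["ailment"]]).strip(),
                    plant_parts=_split_cell(row.get(cols["plant_part"], "") or ""),
                    preparations=_split_cell(row.get(cols["preparation"], "") or ""),
                    routes=routes,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            if not merge_duplicates:
                out.append(report)
            elif report.triple in merged:
                merged[report.triple] = merged[report.triple].merged_with(report)
                n_dup += 1
            else:
                merged[report.triple] = report
    if not merge_duplicates:
        return out
    if n_dup:
        logger.warning(
            "%s: merged %d duplicate (informant, species, ailment) rows", path, n_dup
        )
    return list(merged.values())


def write_use_reports(reports: Iterable[UseReport], path: str | Path,
                      include_category: bool = False) -> None:
    """Write reports to CSV deterministically (sorted triples, sorted sets)."""
    fieldnames = list(DEFAULT_COLUMNS)
    if include_category:
        fieldnames.append("category")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(fieldnames)
        for r in sorted(reports, key=lambda r: r.triple):
            row = [
                r.informant_id,
                r.species_id,
                r.ailment,
                ", ".join(sorted(r.plant_parts)),
                ", ".join(sorted(r.preparations)),
                ", ".join(sorted(r.routes)),
            ]
            if include_category:
                row.append(r.category or "")
            writer.writerow(row)


def read_species_table(path: str | Path,
                       columns: Mapping[str, str] | None = None
                       ) -> dict[str, SpeciesRecord]:
    """Read the species voucher table keyed by species_id."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return {}
        if "species_id" not in reader.fieldnames:
            raise SchemaError("species table needs a 'species_id' column")
        table: dict[str, SpeciesRecord] = {}
        for row in reader:
            rec = SpeciesRecord(
                species_id=row["species_id"].strip(),
                scientific_name=row.get("scientific_name", "").strip(),
                family=row.get("family", "").strip(),
                local_name=row.get("local_name", "").strip(),
                voucher=row.get("voucher", "").strip(),
            )
            if rec.species_id in table:
                raise ValidationError(f"duplicate species_id {rec.species_id!r}")
            table[rec.species_id] = rec
    return table


def write_species_table(table: Mapping[str, SpeciesRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["species_id", "scientific_name", "family", "local_name",
                         "voucher"])
        for sid in sorted(table):
            rec = table[sid]
            writer.writerow([rec.species_id, rec.scientific_name, rec.family,
                             rec.local_name, rec.voucher])


def resolve_categories(reports: Sequence[UseReport],
                       category_map: AilmentCategoryMap) -> list[UseReport]:
    """Fill each report's ailment category; idempotent, count-preserving."""
    missing = category_map.unmapped(r.ailment for r in reports)
    if missing:
        raise ValidationError(f"unmapped ailment label(s): {missing}")
    return [replace(r, category=category_map[r.ailment]) for r in reports]


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    message: str
    context: Mapping[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "message": self.message,
             "context": dict(self.context)},
            sort_keys=True,
        )


@dataclass
class ValidationReport:
    issues: list

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json_lines(self) -> str:
        return "\n".join(issue.to_json() for issue in self.issues)


def validate_dataset(
    reports: Sequence[UseReport],
    species_table: Mapping[str, SpeciesRecord] | None = None,
    category_map: AilmentCategoryMap | None = None,
) -> ValidationReport:
    """Report content problems without raising: unknown species, unmapped
    ailments, route violations and duplicate triples."""
    issues: list[ValidationIssue] = []
    if species_table is not None:
        unknown = sorted({r.species_id for r in reports} - set(species_table))
        for sid in unknown:
            issues.append(ValidationIssue(
                "unknown_species",
                f"species_id {sid!r} absent from species table",
                {"species_id": sid},
            ))
    if category_map is not None:
        for ailment in category_map.unmapped(r.ailment for r in reports):
            issues.append(ValidationIssue(
                "unmapped_ailment",
                f"ailment {ailment!r} has no category mapping",
                {"ailment": ailment},
            ))
    for r in reports:
        bad = sorted(set(r.routes) - set(ROUTES))
        if bad:  # unreachable via the reader, but manual records may carry it
            issues.append(ValidationIssue(
                "route", f"invalid route(s) {bad} on {r.triple}",
                {"triple": list(r.triple), "routes": bad},
            ))
    for triple, count in sorted(Counter(r.triple for r in reports).items()):
        if count > 1:
            issues.append(ValidationIssue(
                "duplicate_triple",
                f"(informant, species, ailment) triple {triple} appears "
                f"{count} times",
                {"triple": list(triple), "count": count},
            ))
    return ValidationReport(issues=issues)
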