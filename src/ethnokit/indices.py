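"""Consensus and fidelity statistics over use reports.

Two statistics drive the analysis:

* **Informant consensus factor** per ailment category,
  ``ICF = (nur - nt) / (nur - 1)``, where *nur* is the number of use reports
  in the category and *nt* the number of distinct species cited for it.
  ICF = 1 when every informant converges on a single species, 0 when every
  citation names a different species.

* **Fidelity level** per (species, ailment) pair,
  ``FL = 100 * Np / N``, the share of a species' citations devoted to one
  ailment. A species' FLs partition its citations, so they sum to exactly
  100 at full precision.

Both are computed on deduplicated (informant, species, ailment) triples;
descriptive frequency tabulations (families, plant parts, preparation modes,
administration routes, per-species ailment breadth) round out the survey
summary. All tables are fully sorted so outputs are byte-stable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from ._round import round_half_up
from .errors import DomainError, ValidationError
from .reports import SpeciesRecord, UseReport

__all__ = [
    "compute_icf",
    "category_consensus_table",
    "compute_fl",
    "fidelity_table",
    "fl100_species",
    "family_summary",
    "usage_summary",
    "ailment_breadth",
    "flora_coverage",
]

USAGE_AXES = ("plant_part", "preparation", "route")


def compute_icf(nur: int, nt: int) -> float:
    """Informant consensus factor ``(nur - nt) / (nur - 1)``.

    ``nur = 1`` is the formula's 0/0 degenerate case: a single citation
    carries no consensus evidence, so 0.0 is returned (the table layer
    carries a degenerate flag alongside).
    """
    if nur < 1:
        raise DomainError(f"nur must be >= 1, got {nur}")
    if nt < 1 or nt > nur:
        raise DomainError(f"nt must satisfy 1 <= nt <= nur, got nt={nt}, nur={nur}")
    if nur == 1:
        return 0.0
    return (nur - nt) / (nur - 1)


def category_consensus_table(reports: Sequence[UseReport]) -> pd.DataFrame:
    """Per-category consensus rows (category, nt, nur, icf, icf_2dp,
    degenerate), sorted by ICF descending, ties by nur descending then label.
    """
    uncategorised = sorted({r.ailment for r in reports if r.category is None})
    if uncategorised:
        raise ValidationError(
            f"reports must be categorised first; uncategorised ailments: "
            f"{uncategorised}"
        )
    rows = []
    by_cat: dict[str, list[UseReport]] = {}
    for r in reports:
        by_cat.setdefault(r.category, []).append(r)
    for category, group in by_cat.items():
        nur = len(group)
        nt = len({r.species_id for r in group})
        icf = compute_icf(nur, nt)
        rows.append({
            "category": category,
            "nt": nt,
            "nur": nur,
            "icf": icf,
            "icf_2dp": round_half_up(icf, 2),
            "degenerate": nur == 1,
        })
    frame = pd.DataFrame(
        rows, columns=["category", "nt", "nur", "icf", "icf_2dp", "degenerate"]
    )
    if frame.empty:
        return frame
    return (
        frame.sort_values(
            ["icf", "nur", "category"], ascending=[False, False, True]
        ).reset_index(drop=True)
    )


def compute_fl(np_: int, n: int) -> float:
    """Fidelity level ``100 * Np / N`` as a percentage in (0, 100]."""
    if np_ < 1 or np_ > n:
        raise DomainError(f"need 1 <= np <= n, got np={np_}, n={n}")
    return 100.0 * np_ / n


def fidelity_table(reports: Sequence[UseReport],
                   basis: str = "reports") -> pd.DataFrame:
    """Fidelity records (species_id, ailment, np, n, fl, fl_2dp).

    ``basis="reports"`` (default) counts deduplicated use-report triples:
    the only basis under which each species' FLs partition to exactly 100.
    ``basis="informants"`` counts distinct informants instead; an informant
    citing a species for two ailments then contributes to both numerators
    but once to the denominator, so FLs may sum above 100.
    """
    if basis not in ("reports", "informants"):
        raise DomainError(f"unknown FL basis {basis!r}")
    if not reports:
        return pd.DataFrame(
            columns=["species_id", "ailment", "np", "n", "fl", "fl_2dp"]
        )
    pairs: dict[tuple[str, str], set] = {}
    species_all: dict[str, set] = {}
    for r in reports:
        pairs.setdefault((r.species_id, r.ailment), set()).add(r.informant_id)
        species_all.setdefault(r.species_id, set()).add(
            (r.informant_id, r.ailment)
        )
    rows = []
    for (sid, ailment), informants in pairs.items():
        np_ = len(informants)
        if basis == "reports":
            n = len(species_all[sid])
        else:
            n = len({inf for inf, _ in species_all[sid]})
        fl = compute_fl(np_, n)
        rows.append({
            "species_id": sid, "ailment": ailment, "np": np_, "n": n,
            "fl": fl, "fl_2dp": round_half_up(fl, 2),
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["species_id", "fl", "ailment"], ascending=[True, False, True]
    ).reset_index(drop=True)


def fl100_species(fidelity: pd.DataFrame, min_reports: int = 2) -> set:
    """Species devoted to a single ailment (FL = 100) with at least
    ``min_reports`` total citations; the default excludes singletons."""
    if min_reports < 1:
        raise DomainError("min_reports must be >= 1")
    if fidelity.empty:
        return set()
    out = set()
    for sid, group in fidelity.groupby("species_id"):
        if len(group) == 1 and int(group["n"].iloc[0]) >= min_reports:
            out.add(sid)
    return out


def _frequency_frame(counts: Mapping[str, int]) -> pd.DataFrame:
    denominator = sum(counts.values())
    rows = [
        {
            "key": key,
            "count": count,
            "pct": 100.0 * count / denominator if denominator else 0.0,
            "denominator": denominator,
        }
        for key, count in counts.items()
    ]
    frame = pd.DataFrame(rows, columns=["key", "count", "pct", "denominator"])
    if frame.empty:
        return frame
    return frame.sort_values(
        ["count", "key"], ascending=[False, True]
    ).reset_index(drop=True)


def family_summary(reports: Sequence[UseReport],
                   species_table: Mapping[str, SpeciesRecord]) -> pd.DataFrame:
    """Per-family summary on both counting bases.

    Emits distinct-species counts (share of the total species mentioned) and
    use-report counts (share of all citations); survey write-ups mix the two
    bases, so both are labelled explicitly.
    """
    cited = sorted({r.species_id for r in reports})
    unknown = [sid for sid in cited if sid not in species_table]
    if unknown:
        raise ValidationError(f"species missing from species table: {unknown}")
    species_by_family: dict[str, set] = {}
    reports_by_family: dict[str, int] = {}
    for sid in cited:
        fam = species_table[sid].family
        species_by_family.setdefault(fam, set()).add(sid)
    for r in reports:
        fam = species_table[r.species_id].family
        reports_by_family[fam] = reports_by_family.get(fam, 0) + 1
    n_species = len(cited)
    n_reports = len(reports)
    rows = []
    for fam in species_by_family:
        ns = len(species_by_family[fam])
        nr = reports_by_family.get(fam, 0)
        rows.append({
            "family": fam,
            "n_species": ns,
            "pct_species": 100.0 * ns / n_species if n_species else 0.0,
            "n_reports": nr,
            "pct_reports": 100.0 * nr / n_reports if n_reports else 0.0,
        })
    frame = pd.DataFrame(
        rows,
        columns=["family", "n_species", "pct_species", "n_reports",
                 "pct_reports"],
    )
    if frame.empty:
        return frame
    return frame.sort_values(
        ["n_species", "n_reports", "family"], ascending=[False, False, True]
    ).reset_index(drop=True)


def usage_summary(reports: Sequence[UseReport], axis: str) -> pd.DataFrame:
    """Frequency table over attribute occurrences for one descriptive axis.

    Each member of a report's attribute set counts once; the denominator is
    the total number of attribute occurrences on that axis. The number of
    distinct labels is the table's row count.
    """
    attr = {"plant_part": "plant_parts", "preparation": "preparations",
            "route": "routes"}.get(axis)
    if attr is None:
        raise DomainError(f"axis must be one of {USAGE_AXES}, got {axis!r}")
    counts: dict[str, int] = {}
    for r in reports:
        for label in getattr(r, attr):
            counts[label] = counts.get(label, 0) + 1
    return _frequency_frame(counts)


def ailment_breadth(reports: Sequence[UseReport]) -> pd.Series:
    """Distinct-ailment count per species, descending (ties by label)."""
    breadth: dict[str, set] = {}
    for r in reports:
        breadth.setdefault(r.species_id, set()).add(r.ailment)
    series = pd.Series(
        {sid: len(ailments) for sid, ailments in breadth.items()},
        dtype=int,
        name="n_ailments",
    )
    if series.empty:
        return series
    frame = series.rename_axis("species_id").reset_index()
    frame = frame.sort_values(
        ["n_ailments", "species_id"], ascending=[False, True]
    )
    return frame.set_index("species_id")["n_ailments"]


def flora_coverage(n_medicinal: int, n_flora: int) -> float:
    """Share of the local flora used medicinally, as a percentage."""
    if n_flora < 1 or n_medicinal < 0 or n_medicinal > n_flora:
        raise DomainError(
            f"need 0 <= n_medicinal <= n_flora and n_flora >= 1, got "
            f"{n_medicinal}/{n_flora}"
        )
    return 100.0 * n_medicinal / n_flora
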