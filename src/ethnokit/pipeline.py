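"""End-to-end orchestration: validate -> indices -> network -> report.

Every artifact is written deterministically (fully sorted tables, no
timestamps), so rerunning the same configuration over the same inputs
produces byte-identical outputs. The manifest records the package version,
the seed and SHA-256 digests of the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._round import round_half_up
from .errors import EthnokitError, ValidationError
from .indices import (
    ailment_breadth,
    category_consensus_table,
    compute_icf,
    family_summary,
    fidelity_table,
    fl100_species,
    usage_summary,
)
from .network import (
    build_incidence,
    detect_groups,
    layout_spring,
    plot_network,
    project_categories,
    write_edgelist_tsv,
    write_graphml,
    write_ucinet_dl,
)
from .reports import (
    AilmentCategoryMap,
    read_species_table,
    read_use_reports,
    resolve_categories,
    validate_dataset,
    write_use_reports,
)

__all__ = ["RunConfig", "PipelineValidationError", "run_pipeline",
           "icf_from_counts"]

logger = logging.getLogger(__name__)


class PipelineValidationError(EthnokitError):
    """Inputs failed validation and --force was not given."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            f"dataset validation failed with {len(report.issues)} issue(s)")


@dataclass
class RunConfig:
    reports_path: str
    species_path: str
    category_map_path: str
    outdir: str
    seed: int = 0
    node_mode: str = "category"
    fl_basis: str = "reports"
    min_reports_fl100: int = 2
    layout_iterations: int = 100
    force: bool = False
    figure: bool = False
    extra: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, lineterminator="\n")


def _md_table(frame: pd.DataFrame, max_rows: int | None = None) -> str:
    shown = frame if max_rows is None else frame.head(max_rows)
    cols = list(shown.columns)
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in shown.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    if max_rows is not None and len(frame) > max_rows:
        lines.append(f"| ... ({len(frame) - max_rows} more rows) " +
                     "|" * len(cols))
    return "\n".join(lines)


def icf_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """ICF table straight from published (category, nt, nur) counts.

    Lets the consensus computation be checked against printed survey tables
    without the raw use reports.
    """
    for col in ("category", "nt", "nur"):
        if col not in counts.columns:
            raise ValidationError(f"counts table needs column {col!r}")
    out = counts[["category", "nt", "nur"]].copy()
    out["icf_raw"] = [compute_icf(int(nur), int(nt))
                      for nt, nur in zip(out["nt"], out["nur"])]
    out["icf_2dp"] = [round_half_up(v, 2) for v in out["icf_raw"]]
    return out.sort_values(
        ["icf_raw", "nur", "category"], ascending=[False, False, True]
    ).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summaries").mkdir(exist_ok=True)
    (outdir / "network").mkdir(exist_ok=True)

    raw = read_use_reports(config.reports_path, merge_duplicates=False)
    species_table = read_species_table(config.species_path)
    map_path = Path(config.category_map_path)
    if map_path.suffix.lower() in (".yml", ".yaml"):
        category_map = AilmentCategoryMap.from_yaml(map_path)
    else:
        category_map = AilmentCategoryMap.from_csv(map_path)

    validation = validate_dataset(raw, species_table, category_map)
    (outdir / "validation.jsonl").write_text(
        validation.to_json_lines() + ("\n" if validation.issues else ""),
        encoding="utf-8")
    if not validation.ok and not config.force:
        raise PipelineValidationError(validation)

    reports = read_use_reports(config.reports_path)  # merged triples
    if not validation.ok:  # forced: drop rows validation flagged, warn
        before = len(reports)
        reports = [r for r in reports
                   if r.species_id in species_table
                   and r.ailment in category_map]
        logger.warning("--force: dropped %d report(s) that failed validation",
                       before - len(reports))
    reports = resolve_categories(reports, category_map)
    write_use_reports(reports, outdir / "use_reports_normalised.csv",
                      include_category=True)

    consensus = category_consensus_table(reports)
    consensus_out = consensus.rename(columns={"icf": "icf_raw"})
    _write_csv(consensus_out, outdir / "icf_by_category.csv")

    fidelity = fidelity_table(reports, basis=config.fl_basis)
    fidelity_out = fidelity.rename(columns={"fl": "fl_raw"})
    _write_csv(fidelity_out, outdir / "fidelity.csv")
    fl100 = sorted(fl100_species(fidelity,
                                 min_reports=config.min_reports_fl100))
    (outdir / "fl100_species.txt").write_text(
        "\n".join(fl100) + ("\n" if fl100 else ""), encoding="utf-8")

    for axis in ("plant_part", "preparation", "route"):
        _write_csv(usage_summary(reports, axis),
                   outdir / "summaries" / f"{axis}.csv")
    _write_csv(family_summary(reports, species_table),
               outdir / "summaries" / "family.csv")
    breadth = ailment_breadth(reports)
    _write_csv(breadth.reset_index(), outdir / "summaries" /
               "ailment_breadth.csv")

    incidence = build_incidence(reports, node_mode=config.node_mode)
    write_ucinet_dl(incidence, outdir / "network" / "incidence.dl")
    write_graphml(incidence, outdir / "network" / "incidence.graphml")
    write_edgelist_tsv(incidence, outdir / "network" / "edges.tsv")
    projection = project_categories(incidence)
    _write_csv(projection, outdir / "network" / "category_projection.csv",
               index=True)
    partition = detect_groups(projection, seed=config.seed)
    _write_csv(partition.to_frame(), outdir / "network" / "groups.csv")
    layout = layout_spring(incidence, seed=config.seed,
                           iterations=config.layout_iterations)
    layout_rows = []
    for node, (x, y) in layout.items():
        mode = "ailment" if node in incidence.index else "species"
        layout_rows.append({"node": node, "mode": mode,
                            "x": round(float(x), 6), "y": round(float(y), 6)})
    layout_frame = pd.DataFrame(layout_rows).sort_values(
        ["mode", "node"]).reset_index(drop=True)
    _write_csv(layout_frame, outdir / "network" / "layout.csv")
    if config.figure:
        plot_network(incidence, layout, outdir / "network" / "network.png",
                     partition)

    report_md = [
        "# Survey analysis report",
        "",
        f"Seed: {config.seed}. Use reports (deduplicated triples): "
        f"{len(reports)}. Species cited: "
        f"{len({r.species_id for r in reports})}. Ailment categories: "
        f"{consensus.shape[0]}.",
        "",
        "## Informant consensus by ailment category",
        "",
        _md_table(consensus_out[["category", "nt", "nur", "icf_2dp"]]),
        "",
        "## Fidelity levels (top rows)",
        "",
        _md_table(fidelity_out[["species_id", "ailment", "np", "n",
                                "fl_2dp"]], max_rows=20),
        "",
        f"Species with FL = 100 (>= {config.min_reports_fl100} citations): "
        f"{len(fl100)}",
        "",
        "## Category groups (modularity on the shared-species projection)",
        "",
        _md_table(partition.to_frame()),
        "",
        f"Modularity: {partition.modularity:.4f} "
        f"({partition.n_groups} group(s))",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(report_md), encoding="utf-8")

    artifacts = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    manifest = {
        "ethnokit_version": __version__,
        "seed": config.seed,
        "node_mode": config.node_mode,
        "fl_basis": config.fl_basis,
        "inputs": {
            "use_reports": {"path": str(config.reports_path),
                            "sha256": _sha256(config.reports_path)},
            "species": {"path": str(config.species_path),
                        "sha256": _sha256(config.species_path)},
            "category_map": {"path": str(config.category_map_path),
                             "sha256": _sha256(config.category_map_path)},
        },
        "n_use_reports": len(reports),
        "n_validation_issues": len(validation.issues),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
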