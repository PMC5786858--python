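"""Per-module summary rows: disease and symptom enrichment side by side with
target-set overlay counts and the disease/syndrome selection flags, written
as deterministic TSV or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

from modenrich.community import Partition
from modenrich.enrichment import ModuleEnrichment
from modenrich.graph_io import GeneSet

#: column order of the TSV report (one row per disease module)
REPORT_COLUMNS = (
    "module",
    "disease_genes",  # k/n
    "disease_p",
    "symptom_genes",  # k/n
    "symptom_p",
    "ihd_targets",
    "bs_formula_targets",
    "ps_formula_targets",
    "is_disease_module",
    "is_syndrome_module",
)

#: overlay keys recognized by build_report, in report column order
OVERLAY_KEYS = ("ihd_targets", "bs_formula_targets", "ps_formula_targets")


class Selections(NamedTuple):
    disease: Sequence[int]
    syndrome: Sequence[int]


@dataclass(frozen=True)
class ModuleReportRow:
    module: int
    disease_k_over_n: Tuple[int, int]
    disease_p: float
    symptom_k_over_n: Tuple[int, int]
    symptom_p: float
    n_ihd_targets: int
    n_bs_formula_targets: int
    n_ps_formula_targets: int
    is_disease_module: bool
    is_syndrome_module: bool

    def __post_init__(self) -> None:
        if self.is_syndrome_module and not self.is_disease_module:
            raise ValueError("a syndrome module must also be a disease module")


def overlay_targets(
    partition: Partition, targets: GeneSet, modules: Iterable[int]
) -> Dict[int, int]:
    """Per-module count of target genes: |module members ∩ targets|."""
    groups = partition.modules()
    out: Dict[int, int] = {}
    for label in modules:
        if label not in groups:
            raise ValueError(f"unknown module label {label}")
        out[label] = len(groups[label] & targets.members)
    return out


def build_report(
    disease_records: Sequence[ModuleEnrichment],
    symptom_records: Sequence[ModuleEnrichment],
    target_overlays: Mapping[str, Mapping[int, int]],
    selections: Selections,
) -> List[ModuleReportRow]:
    """One row per selected disease module, sorted by ascending disease
    p-value. Overlay keys default to zero counts when absent."""
    disease_by_module = {r.module: r for r in disease_records}
    symptom_by_module = {r.module: r for r in symptom_records}
    unknown = set(target_overlays) - set(OVERLAY_KEYS)
    if unknown:
        raise ValueError(f"unknown overlay keys {sorted(unknown)}; expected {OVERLAY_KEYS}")
    syndrome = set(selections.syndrome)
    rows: List[ModuleReportRow] = []
    for label in selections.disease:
        if label not in disease_by_module:
            raise ValueError(f"disease module {label} has no disease enrichment record")
        if symptom_records and label not in symptom_by_module:
            raise ValueError(f"disease module {label} has no symptom enrichment record")
        d = disease_by_module[label]
        s = symptom_by_module.get(label)
        counts = {
            key: int(target_overlays.get(key, {}).get(label, 0))
            for key in OVERLAY_KEYS
        }
        rows.append(
            ModuleReportRow(
                module=label,
                disease_k_over_n=(d.input.k, d.input.n),
                disease_p=d.p_value,
                symptom_k_over_n=(s.input.k, s.input.n) if s else (0, 0),
                symptom_p=s.p_value if s else 1.0,
                n_ihd_targets=counts["ihd_targets"],
                n_bs_formula_targets=counts["bs_formula_targets"],
                n_ps_formula_targets=counts["ps_formula_targets"],
                is_disease_module=True,
                is_syndrome_module=label in syndrome,
            )
        )
    rows.sort(key=lambda r: (r.disease_p, r.module))
    return rows


def _fmt_p(p: float) -> str:
    return f"{p:.2E}"  # 3 significant digits, scientific notation


def write_report(
    rows: Sequence[ModuleReportRow], path: str | Path, format: str = "tsv"
) -> None:
    """Write report rows; byte-stable for fixed input."""
    if not rows:
        raise ValueError("no rows to write")
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for r in rows:
            lines.append(
                "\t".join(
                    [
                        str(r.module),
                        f"{r.disease_k_over_n[0]}/{r.disease_k_over_n[1]}",
                        _fmt_p(r.disease_p),
                        f"{r.symptom_k_over_n[0]}/{r.symptom_k_over_n[1]}",
                        _fmt_p(r.symptom_p),
                        str(r.n_ihd_targets),
                        str(r.n_bs_formula_targets),
                        str(r.n_ps_formula_targets),
                        str(int(r.is_disease_module)),
                        str(int(r.is_syndrome_module)),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = [rows_to_dict(r) for r in rows]
        path.write_text(
            json.dumps(payload, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown report format {format!r}; use 'tsv' or 'json'")


def rows_to_dict(row: ModuleReportRow) -> dict:
    return {
        "module": row.module,
        "disease_k": row.disease_k_over_n[0],
        "disease_n": row.disease_k_over_n[1],
        "disease_p": row.disease_p,
        "symptom_k": row.symptom_k_over_n[0],
        "symptom_n": row.symptom_k_over_n[1],
        "symptom_p": row.symptom_p,
        "ihd_targets": row.n_ihd_targets,
        "bs_formula_targets": row.n_bs_formula_targets,
        "ps_formula_targets": row.n_ps_formula_targets,
        "is_disease_module": row.is_disease_module,
        "is_syndrome_module": row.is_syndrome_module,
    }


def rows_from_json(path: str | Path) -> List[ModuleReportRow]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        ModuleReportRow(
            module=d["module"],
            disease_k_over_n=(d["disease_k"], d["disease_n"]),
            disease_p=d["disease_p"],
            symptom_k_over_n=(d["symptom_k"], d["symptom_n"]),
            symptom_p=d["symptom_p"],
            n_ihd_targets=d["ihd_targets"],
            n_bs_formula_targets=d["bs_formula_targets"],
            n_ps_formula_targets=d["ps_formula_targets"],
            is_disease_module=d["is_disease_module"],
            is_syndrome_module=d["is_syndrome_module"],
        )
        for d in payload
    ]
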