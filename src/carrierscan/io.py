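"""Readers and writers for the tabular formats the pipeline consumes.

All tables are plain TSV with declared headers. Missing values are
written as ``NA`` and read back as ``None``; ``-`` and ``.`` are also
accepted on input because annotation exports commonly use them.
An optional VCF reader maps INFO keys onto the variant schema.
"""

from __future__ import annotations

import dataclasses
import json
import math
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .types import (
    ALL_TOOLS,
    SPLICE_CLASS_TOOLS,
    AnnotatedVariant,
    CarrierTable,
    ClinicalClass,
    Cohort,
    Consequence,
    CountingUnit,
    GenotypeCall,
    Participant,
    PredictorLabel,
    PredictorPanel,
    PredictorValue,
    Role,
    StudyGroup,
    validate_cohort,
)

MISSING_TOKENS = {"", "NA", "-", ".", "nan", "NaN"}
MISSING_OUT = "NA"

_VARIANT_REQUIRED = [
    "variant_id",
    "gene",
    "genomic_change",
    "protein_change",
    "consequence",
    "maf_reference",
    "clinvar_class",
    "acmg_class",
]


class SchemaError(ValueError):
    """A table is missing a required column."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _is_missing(token: Any) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and math.isnan(token):
        return True
    return str(token).strip() in MISSING_TOKENS


def _parse_float(token: Any, what: str, line: int) -> float | None:
    if _is_missing(token):
        return None
    try:
        return float(token)
    except (TypeError, ValueError):
        raise RowError(f"unparseable {what}: {token!r}", line) from None


def _parse_panel(row: Mapping[str, Any], line: int) -> PredictorPanel:
    entries: dict[str, PredictorValue] = {}
    for tool in ALL_TOOLS:
        score = None
        if tool not in SPLICE_CLASS_TOOLS:
            score = _parse_float(row.get(f"{tool}_score"), f"{tool}_score", line)
        label_token = row.get(f"{tool}_label")
        label = None
        if not _is_missing(label_token):
            try:
                label = PredictorLabel(str(label_token).strip())
            except ValueError:
                raise RowError(f"unknown {tool}_label {label_token!r}", line) from None
        if score is not None or label is not None:
            entries[tool] = PredictorValue(score=score, label=label)
    return PredictorPanel(entries=entries)


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    info_key_map: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Read an annotated variant panel.

    ``dialect="tsv"`` expects a header with the core columns plus
    optional ``<tool>_score`` / ``<tool>_label`` predictor columns.
    ``dialect="vcf_info"`` reads a VCF and maps INFO keys to the same
    schema through ``info_key_map`` (schema field -> INFO key).
    """
    if dialect == "vcf_info":
        return _read_variant_vcf(path, info_key_map or {})
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _VARIANT_REQUIRED if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")

    variants: list[AnnotatedVariant] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2  # 1-based, after the header
        vid = str(row["variant_id"]).strip()
        if vid in seen:
            raise RowError(f"duplicate variant_id {vid!r}", line)
        seen.add(vid)
        maf = _parse_float(row["maf_reference"], "maf_reference", line)
        try:
            variant = AnnotatedVariant(
                variant_id=vid,
                gene=str(row["gene"]).strip(),
                genomic_change=str(row["genomic_change"]).strip(),
                protein_change=(
                    "" if _is_missing(row["protein_change"]) else str(row["protein_change"]).strip()
                ),
                consequence=Consequence(str(row["consequence"]).strip()),
                maf_reference=maf,
                predictor_panel=_parse_panel(row, line),
                clinvar_class=_parse_class(row["clinvar_class"]),
                acmg_class=_parse_class(row["acmg_class"]),
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(str(exc), line) from None
        variants.append(variant)
    return variants


def _parse_class(token: Any) -> ClinicalClass:
    if _is_missing(token):
        return ClinicalClass.NOT_REPORTED
    return ClinicalClass(str(token).strip())


def _read_variant_vcf(path: str | Path, key_map: Mapping[str, str]) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF  # optional dependency, only needed for this dialect

    def info_get(record, fieldname, default=None):
        key = key_map.get(fieldname, fieldname)
        value = record.INFO.get(key)
        return default if value is None else value

    variants: list[AnnotatedVariant] = []
    for i, rec in enumerate(VCF(str(path))):
        line = i + 1
        vid = info_get(rec, "variant_id")
        if vid is None:
            raise RowError("missing variant_id INFO key", line)
        row: dict[str, Any] = {}
        for tool in ALL_TOOLS:
            row[f"{tool}_score"] = info_get(rec, f"{tool}_score")
            row[f"{tool}_label"] = info_get(rec, f"{tool}_label")
        maf = info_get(rec, "maf_reference")
        variants.append(
            AnnotatedVariant(
                variant_id=str(vid),
                gene=str(info_get(rec, "gene", "")),
                genomic_change=str(info_get(rec, "genomic_change", "")),
                protein_change=str(info_get(rec, "protein_change", "") or ""),
                consequence=Consequence(str(info_get(rec, "consequence", "other"))),
                maf_reference=_parse_float(maf, "maf_reference", line),
                predictor_panel=_parse_panel(row, line),
                clinvar_class=_parse_class(info_get(rec, "clinvar_class")),
                acmg_class=_parse_class(info_get(rec, "acmg_class")),
            )
        )
    return variants


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write a panel as TSV; round-trips exactly through read_variant_table."""
    columns = list(_VARIANT_REQUIRED)
    for tool in ALL_TOOLS:
        if tool not in SPLICE_CLASS_TOOLS:
            columns.append(f"{tool}_score")
        columns.append(f"{tool}_label")
    rows = []
    for v in variants:
        row: dict[str, str] = {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "genomic_change": v.genomic_change,
            "protein_change": v.protein_change or MISSING_OUT,
            "consequence": v.consequence.value,
            "maf_reference": MISSING_OUT if v.maf_reference is None else repr(v.maf_reference),
            "clinvar_class": v.clinvar_class.value,
            "acmg_class": v.acmg_class.value,
        }
        for tool in ALL_TOOLS:
            entry = v.predictor_panel.get(tool)
            if tool not in SPLICE_CLASS_TOOLS:
                row[f"{tool}_score"] = (
                    MISSING_OUT if entry.score is None else repr(entry.score)
                )
            row[f"{tool}_label"] = MISSING_OUT if entry.label is None else entry.label.value
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genotype_calls(path: str | Path) -> list[GenotypeCall]:
    """Read per-sample genotype calls (sample_id, variant_id, depth, vaf[, base_quality_pass])."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "variant_id", "depth", "vaf"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    calls = []
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2
        try:
            calls.append(
                GenotypeCall(
                    sample_id=row["sample_id"],
                    variant_id=row["variant_id"],
                    depth=int(row["depth"]),
                    vaf=float(row["vaf"]),
                    base_quality_pass=str(row.get("base_quality_pass", "True")).strip()
                    in {"True", "true", "1", "pass", "PASS"},
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return calls


def write_genotype_calls(calls: Sequence, path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "variant_id": c.variant_id,
            "depth": c.depth,
            "vaf": repr(c.vaf),
            "base_quality_pass": str(c.base_quality_pass),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "variant_id", "depth", "vaf", "base_quality_pass"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort directory: groups.tsv, participants.tsv, carriers.tsv."""
    root = Path(path)
    groups_frame = pd.read_csv(root / "groups.tsv", sep="\t", dtype=str, keep_default_na=False)
    required = ["name", "role", "counting_unit", "n_units", "n_participants"]
    missing = [c for c in required if c not in groups_frame.columns]
    if missing:
        raise SchemaError(f"groups.tsv missing column(s): {', '.join(missing)}")
    groups = [
        StudyGroup(
            name=row["name"],
            role=Role(row["role"]),
            counting_unit=CountingUnit(row["counting_unit"]),
            n_units=int(row["n_units"]),
            n_participants=int(row["n_participants"]),
        )
        for row in groups_frame.to_dict("records")
    ]

    part_frame = pd.read_csv(root / "participants.tsv", sep="\t", dtype=str, keep_default_na=False)
    required = ["participant_id", "group_memberships", "role"]
    missing = [c for c in required if c not in part_frame.columns]
    if missing:
        raise SchemaError(f"participants.tsv missing column(s): {', '.join(missing)}")
    participants = [
        Participant(
            participant_id=row["participant_id"],
            group_memberships=frozenset(row["group_memberships"].split(";")),
            role=Role(row["role"]),
            family_id="" if _is_missing(row.get("family_id")) else row["family_id"],
            is_index=str(row.get("is_index", "False")).strip() in {"True", "true", "1"},
        )
        for row in part_frame.to_dict("records")
    ]

    carrier_frame = pd.read_csv(root / "carriers.tsv", sep="\t", dtype=str, keep_default_na=False)
    required = ["group", "variant_id", "carriers"]
    missing = [c for c in required if c not in carrier_frame.columns]
    if missing:
        raise SchemaError(f"carriers.tsv missing column(s): {', '.join(missing)}")
    table = CarrierTable()
    for i, row in enumerate(carrier_frame.to_dict("records")):
        try:
            table.set_count(row["group"], row["variant_id"], int(row["carriers"]))
        except ValueError as exc:
            raise RowError(str(exc), i + 2) from None

    return validate_cohort(groups, participants, table)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort directory; round-trips exactly through read_cohort."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "name": g.name,
                "role": g.role.value,
                "counting_unit": g.counting_unit.value,
                "n_units": g.n_units,
                "n_participants": g.n_participants,
            }
            for g in cohort.groups
        ]
    ).to_csv(root / "groups.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group_memberships": ";".join(sorted(p.group_memberships)),
                "role": p.role.value,
                "family_id": p.family_id or MISSING_OUT,
                "is_index": str(p.is_index),
            }
            for p in cohort.participants
        ],
        columns=["participant_id", "group_memberships", "role", "family_id", "is_index"],
    ).to_csv(root / "participants.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"group": g, "variant_id": v, "carriers": c}
            for (g, v), c in sorted(cohort.carrier_table.items())
        ],
        columns=["group", "variant_id", "carriers"],
    ).to_csv(root / "carriers.tsv", sep="\t", index=False, lineterminator="\n")


def read_loh_observations(path: str | Path) -> list:
    """Read tumour/normal LOH observations from TSV."""
    from .loh import LOHObservation, Preservation

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["carrier_id", "variant_id", "tissue", "preservation", "normal_vaf",
                "tumour_vaf", "tumour_depth"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    observations = []
    for i, row in enumerate(frame.to_dict("records")):
        try:
            observations.append(
                LOHObservation(
                    carrier_id=row["carrier_id"],
                    variant_id=row["variant_id"],
                    tissue=row["tissue"],
                    preservation=Preservation(row["preservation"]),
                    normal_vaf=float(row["normal_vaf"]),
                    tumour_vaf=float(row["tumour_vaf"]),
                    tumour_depth=int(row["tumour_depth"]),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), i + 2) from None
    return observations


def write_loh_observations(observations, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "carrier_id": o.carrier_id,
                "variant_id": o.variant_id,
                "tissue": o.tissue,
                "preservation": o.preservation.value,
                "normal_vaf": repr(o.normal_vaf),
                "tumour_vaf": repr(o.tumour_vaf),
                "tumour_depth": o.tumour_depth,
            }
            for o in observations
        ],
        columns=["carrier_id", "variant_id", "tissue", "preservation", "normal_vaf",
                 "tumour_vaf", "tumour_depth"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical_table(path: str | Path) -> list:
    """Read per-carrier clinical records from TSV."""
    from .clinical import ClinicalRecord, VitalStatus

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["carrier_id", "variant_id", "age_at_diagnosis"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(frame.to_dict("records")):
        try:
            survival = row.get("survival_months")
            status = row.get("vital_status")
            records.append(
                ClinicalRecord(
                    carrier_id=row["carrier_id"],
                    variant_id=row["variant_id"],
                    age_at_diagnosis=float(row["age_at_diagnosis"]),
                    survival_months=None if _is_missing(survival) else float(survival),
                    vital_status=(
                        VitalStatus.MISSING if _is_missing(status) else VitalStatus(status)
                    ),
                    histopathology=row.get("histopathology", ""),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), i + 2) from None
    return records


def write_clinical_table(records, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "carrier_id": r.carrier_id,
                "variant_id": r.variant_id,
                "age_at_diagnosis": repr(r.age_at_diagnosis),
                "survival_months": (
                    MISSING_OUT if r.survival_months is None else repr(r.survival_months)
                ),
                "vital_status": r.vital_status.value,
                "histopathology": r.histopathology,
            }
            for r in records
        ],
        columns=["carrier_id", "variant_id", "age_at_diagnosis", "survival_months",
                 "vital_status", "histopathology"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Enum):
            return o.value
        if isinstance(o, CarrierTable):
            return {f"{g}\t{v}": c for (g, v), c in sorted(o.items())}
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "item"):  # numpy scalar
            return o.item()
        return super().default(o)


def write_report(results: Any, path: str | Path) -> None:
    """Serialize any stage output deterministically.

    DataFrames become TSV; everything else becomes JSON with sorted
    keys. Re-running on identical inputs yields byte-identical files.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", index=False, lineterminator="\n")
        return
    text = json.dumps(results, cls=_ReportEncoder, sort_keys=True, indent=2)
    path.write_text(text + "\n")
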