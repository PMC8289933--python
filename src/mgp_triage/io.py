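"""Readers and writers for patient cohorts and triage conclusions.

Two on-disk dialects are supported:

* ``json`` — a single document ``{"patients": [...]}`` whose per-patient
  schema mirrors the domain types field-for-field (the canonical format).
* ``tsv`` — three linked tables (``patients.tsv``, ``variants.tsv``,
  ``observations.tsv``) in one directory, keyed by ``patient_id``; this maps
  naturally onto how clinical summaries are tabulated.

Both dialects round-trip: ``read(write(cohort))`` reproduces every field.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from pydantic import ValidationError

from .errors import CohortValidationError, ParseError
from .model import (
    AlleleFraction,
    AFStatus,
    CancerDiagnosis,
    ChemoHistory,
    ClinicalContext,
    Degree,
    FamilyMember,
    PatientRecord,
    Tissue,
    VariantCall,
)

if TYPE_CHECKING:  # pragma: no cover
    from .classify import PatientConclusion
    from .screen import InclusionResult

_DEGREE_CODE = {Degree.FIRST: "FDR", Degree.SECOND: "SDR"}
_CODE_DEGREE = {v: k for k, v in _DEGREE_CODE.items()}

_PATIENT_COLS = [
    "patient_id",
    "sex",
    "ethnicity",
    "diagnoses",
    "family",
    "chemo_history",
    "wbc",
    "heme_malignancy_dx",
    "deceased",
]
_VARIANT_COLS = ["patient_id", "key", "gene", "cdna", "protein", "kind", "pathogenicity"]
_OBS_COLS = [
    "patient_id",
    "variant_key",
    "tissue",
    "af_status",
    "af_value",
    "interval_low",
    "interval_high",
    "age_at_sample",
    "note",
]

REPORT_COLS = [
    "patient_id",
    "variant_key",
    "gene",
    "cdna",
    "tissue",
    "af_percent",
    "category_set",
    "conclusion",
    "evidence",
]


# ---------------------------------------------------------------------------
# patients


def read_patients(path: str | Path, format: str = "json") -> list[PatientRecord]:
    """Read and validate a cohort; ordering is preserved.

    Raises :class:`ParseError` on malformed input and
    :class:`CohortValidationError` when a record violates a domain invariant
    or a ``patient_id`` is duplicated.
    """
    path = Path(path)
    if format == "json":
        raw = _load_json_patients(path)
    elif format == "tsv":
        raw = _load_tsv_patients(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for i, entry in enumerate(raw):
        pid = entry.get("patient_id", f"<record {i}>")
        try:
            rec = PatientRecord.model_validate(entry)
        except ValidationError as exc:
            raise CohortValidationError(f"patient {pid}: {exc}") from exc
        if rec.patient_id in seen:
            raise CohortValidationError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
        patients.append(rec)
    return patients


def write_patients(
    patients: Iterable[PatientRecord], path: str | Path, format: str = "json"
) -> None:
    path = Path(path)
    patients = list(patients)
    if format == "json":
        doc = {
            "patients": [p.model_dump(mode="json", exclude_none=True) for p in patients]
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif format == "tsv":
        _write_tsv_patients(patients, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _load_json_patients(path: Path) -> list[dict]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}, column {exc.colno}: {exc.msg}")
    if not isinstance(doc, dict) or "patients" not in doc:
        raise ParseError(f"{path}: top-level object must contain a 'patients' list")
    if not isinstance(doc["patients"], list):
        raise ParseError(f"{path}: 'patients' must be a list")
    return doc["patients"]


def _fmt_diagnoses(dxs: list[CancerDiagnosis]) -> str:
    parts = []
    for d in dxs:
        age = "?" if d.age_at_dx is None else _num(d.age_at_dx)
        parts.append(f"{d.label}@{age}")
    return "; ".join(parts)


def _parse_diagnoses(cell: str, where: str) -> list[dict]:
    if not cell:
        return []
    out = []
    for part in cell.split("; "):
        if "@" not in part:
            raise ParseError(f"{where}: malformed diagnosis cell {part!r}")
        label, _, age = part.rpartition("@")
        out.append(
            {"label": label, "age_at_dx": None if age == "?" else float(age)}
        )
    return out


def _fmt_family(family: list[FamilyMember]) -> str:
    parts = []
    for m in family:
        inner = "|".join(
            f"{d.label}@{'?' if d.age_at_dx is None else _num(d.age_at_dx)}"
            for d in m.diagnoses
        )
        parts.append(f"{_DEGREE_CODE[m.degree]}[{inner}]")
    return "; ".join(parts)


def _parse_family(cell: str, where: str) -> list[dict]:
    if not cell:
        return []
    out = []
    for part in cell.split("; "):
        if not (part.endswith("]") and "[" in part):
            raise ParseError(f"{where}: malformed family cell {part!r}")
        code, _, inner = part[:-1].partition("[")
        if code not in _CODE_DEGREE:
            raise ParseError(f"{where}: unknown relative degree {code!r}")
        dxs = []
        for item in inner.split("|"):
            label, _, age = item.rpartition("@")
            dxs.append({"label": label, "age_at_dx": None if age == "?" else float(age)})
        out.append({"degree": _CODE_DEGREE[code].value, "diagnoses": dxs})
    return out


def _num(x: float) -> str:
    # shortest representation that round-trips exactly
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def _cell(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return _num(x)
    if hasattr(x, "value"):
        return x.value
    return str(x)


def _write_tsv_patients(patients: list[PatientRecord], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "patients.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PATIENT_COLS)
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    p.sex,
                    _cell(p.ethnicity),
                    _fmt_diagnoses(p.diagnoses),
                    _fmt_family(p.family),
                    p.clinical.chemo_history.value,
                    _cell(p.clinical.wbc),
                    _cell(p.clinical.heme_malignancy_dx),
                    _cell(p.clinical.deceased),
                ]
            )
    with open(outdir / "variants.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VARIANT_COLS)
        for p in patients:
            for v in p.variants:
                w.writerow(
                    [
                        p.patient_id,
                        v.key,
                        v.gene,
                        v.cdna,
                        _cell(v.protein),
                        v.kind.value,
                        v.pathogenicity.value,
                    ]
                )
    with open(outdir / "observations.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_OBS_COLS)
        for p in patients:
            for o in p.observations:
                w.writerow(
                    [
                        p.patient_id,
                        o.variant_key,
                        o.tissue.value,
                        o.af.status.value,
                        _cell(o.af.value),
                        _cell(o.af.interval_low),
                        _cell(o.af.interval_high),
                        _cell(o.age_at_sample),
                        _cell(o.note),
                    ]
                )


def _read_table(path: Path, cols: list[str]) -> list[dict]:
    if not path.exists():
        raise ParseError(f"missing table {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != cols:
            raise ParseError(f"{path}: expected columns {cols}, got {reader.fieldnames}")
        return list(reader)


def _load_tsv_patients(indir: Path) -> list[dict]:
    prows = _read_table(indir / "patients.tsv", _PATIENT_COLS)
    vrows = _read_table(indir / "variants.tsv", _VARIANT_COLS)
    orows = _read_table(indir / "observations.tsv", _OBS_COLS)

    out: list[dict] = []
    by_id: dict[str, dict] = {}
    for row in prows:
        pid = row["patient_id"]
        entry = {
            "patient_id": pid,
            "sex": row["sex"],
            "ethnicity": row["ethnicity"] or None,
            "diagnoses": _parse_diagnoses(row["diagnoses"], f"patient {pid}"),
            "family": _parse_family(row["family"], f"patient {pid}"),
            "clinical": {
                "chemo_history": row["chemo_history"] or ChemoHistory.UNKNOWN.value,
                "wbc": float(row["wbc"]) if row["wbc"] else None,
                "heme_malignancy_dx": row["heme_malignancy_dx"] or None,
                "deceased": row["deceased"] == "true",
            },
            "variants": [],
            "observations": [],
        }
        out.append(entry)
        by_id[pid] = entry
    for row in vrows:
        pid = row["patient_id"]
        if pid not in by_id:
            raise ParseError(f"variants.tsv: unknown patient_id {pid!r}")
        by_id[pid]["variants"].append(
            {
                "key": row["key"],
                "gene": row["gene"],
                "cdna": row["cdna"],
                "protein": row["protein"] or None,
                "kind": row["kind"],
                "pathogenicity": row["pathogenicity"],
            }
        )
    for row in orows:
        pid = row["patient_id"]
        if pid not in by_id:
            raise ParseError(f"observations.tsv: unknown patient_id {pid!r}")
        af = {
            "status": row["af_status"],
            "value": float(row["af_value"]) if row["af_value"] else None,
            "interval_low": float(row["interval_low"]) if row["interval_low"] else None,
            "interval_high": float(row["interval_high"])
            if row["interval_high"]
            else None,
        }
        by_id[pid]["observations"].append(
            {
                "variant_key": row["variant_key"],
                "tissue": row["tissue"],
                "af": af,
                "age_at_sample": float(row["age_at_sample"])
                if row["age_at_sample"]
                else None,
                "note": row["note"] or None,
            }
        )
    return out


# ---------------------------------------------------------------------------
# conclusions

_CONCLUSION_COLS = [
    "patient_id",
    "role",
    "variant_key",
    "label",
    "cbc_flag",
    "evidence",
    "primary_label",
    "follow_up",
]


def _fmt_evidence(evidence: list[tuple[str, str]]) -> str:
    parts = []
    for rid, text in evidence:
        if "=" in rid or "||" in text or "\t" in text or "\n" in text:
            raise ValueError(f"evidence item not TSV-safe: {(rid, text)!r}")
        parts.append(f"{rid}={text}")
    return "||".join(parts)


def _parse_evidence(cell: str) -> list[tuple[str, str]]:
    if not cell:
        return []
    out = []
    for part in cell.split("||"):
        rid, _, text = part.partition("=")
        out.append((rid, text))
    return out


def write_conclusions(
    conclusions: "list[PatientConclusion]", path: str | Path, format: str = "json"
) -> None:
    """Write patient conclusions; both formats round-trip field-for-field."""
    path = Path(path)
    conclusions = list(conclusions)
    if format == "json":
        doc = {
            "conclusions": [
                c.model_dump(mode="json", exclude_none=True) for c in conclusions
            ]
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CONCLUSION_COLS)
        for c in conclusions:
            follow = ",".join(f.value for f in sorted(c.follow_up, key=lambda f: f.value))
            for role, vcs in (("primary", c.primary_variants), ("co_finding", c.co_findings)):
                for vc in vcs:
                    w.writerow(
                        [
                            c.patient_id,
                            role,
                            vc.variant_key,
                            vc.label.value,
                            _cell(vc.cbc_flag),
                            _fmt_evidence(vc.evidence),
                            c.primary_label.value,
                            follow,
                        ]
                    )


def read_conclusions(path: str | Path, format: str = "json") -> "list[PatientConclusion]":
    from .classify import PatientConclusion, VariantConclusion

    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}")
        return [PatientConclusion.model_validate(c) for c in doc.get("conclusions", [])]
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _CONCLUSION_COLS:
            raise ParseError(f"{path}: unexpected columns {reader.fieldnames}")
        rows = list(reader)
    out: list[PatientConclusion] = []
    current: Optional[dict] = None
    for row in rows:
        pid = row["patient_id"]
        if current is None or current["patient_id"] != pid:
            current = {
                "patient_id": pid,
                "primary_label": row["primary_label"],
                "primary_variants": [],
                "co_findings": [],
                "follow_up": row["follow_up"].split(",") if row["follow_up"] else [],
            }
            out.append(current)  # type: ignore[arg-type]
        vc = VariantConclusion(
            patient_id=pid,
            variant_key=row["variant_key"],
            label=row["label"],
            evidence=_parse_evidence(row["evidence"]),
            cbc_flag=row["cbc_flag"] == "true",
        )
        key = "primary_variants" if row["role"] == "primary" else "co_findings"
        current[key].append(vc)
    return [PatientConclusion.model_validate(c) for c in out]


# ---------------------------------------------------------------------------
# flat report


def write_report(
    patients: "list[PatientRecord]",
    inclusions: "list[InclusionResult]",
    conclusions: "list[PatientConclusion]",
    path: str | Path,
) -> None:
    """Write the fixed-column per-observation report (lossy, for reading)."""
    inc_by_id = {r.patient_id: r for r in inclusions}
    conc_by_id = {c.patient_id: c for c in conclusions}
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLS)
        for p in patients:
            conc = conc_by_id.get(p.patient_id)
            if conc is None:
                continue
            inc = inc_by_id.get(p.patient_id)
            cats = ",".join(str(c) for c in sorted(inc.categories)) if inc else ""
            labels = {
                vc.variant_key: vc.label.value
                for vc in conc.primary_variants + conc.co_findings
            }
            evidence = {
                vc.variant_key: "; ".join(f"{r}: {t}" for r, t in vc.evidence)
                for vc in conc.primary_variants + conc.co_findings
            }
            for o in p.observations:
                v = p.variant(o.variant_key)
                rep = o.af.representative
                if o.af.status is AFStatus.ABSENT:
                    af_txt = "0"
                elif rep is None:
                    af_txt = "present"
                else:
                    af_txt = _num(rep)
                w.writerow(
                    [
                        p.patient_id,
                        v.key,
                        v.gene,
                        v.cdna,
                        o.tissue.value,
                        af_txt,
                        cats,
                        labels.get(v.key, ""),
                        evidence.get(v.key, ""),
                    ]
                )
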