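"""Descriptive cohort statistics over screened and classified patients.

Counts are exact; percentages are carried at full precision and only
formatted on output (clinical reports mix rounding conventions, so the
stored values never pre-round). Percentages are ``None`` whenever their
denominator is zero.
"""

from __future__ import annotations

from typing import Optional

from .classify import CH_FAMILY, ConclusionLabel, PatientConclusion
from .errors import ConsistencyError
from .evidence import PresenceLevel, TissueEvidence
from .model import ACTIONABLE, ChemoHistory, PatientRecord, StrictModel, Tissue
from .screen import InclusionResult

LABEL_DISPLAY = {
    ConclusionLabel.FULL_GERMLINE: "full germline",
    ConclusionLabel.LIKELY_GERMLINE: "likely germline",
    ConclusionLabel.MOSAIC: "mosaic",
    ConclusionLabel.CONFIRMED_CH: "confirmed CH",
    ConclusionLabel.LIKELY_CH: "likely CH",
    ConclusionLabel.HEME_MALIGNANCY_RELATED: "hematologic malignancy-related",
    ConclusionLabel.UNRESOLVED: "unresolved",
}


def _pct(count: int, denom: int) -> Optional[float]:
    return 100.0 * count / denom if denom else None


class CohortSummary(StrictModel):
    n_included: int
    label_counts: dict[ConclusionLabel, int]
    label_pct: dict[ConclusionLabel, Optional[float]]
    ch_combined_count: int
    ch_combined_pct: Optional[float]
    category_counts: dict[int, int]
    category_pct: dict[int, Optional[float]]
    gene_counts: dict[str, int]
    gene_pct: dict[str, Optional[float]]
    multi_gene_count: int
    multi_gene_pct: Optional[float]
    chemo_ch_count: int
    chemo_fraction_among_ch: Optional[float]
    n_direct_skin: int
    pct_direct_skin: Optional[float]
    n_paired_cultured: int
    pct_paired_cultured: Optional[float]
    n_contamination_pattern: int
    pct_contamination_pattern: Optional[float]
    n_tumour_tested: int
    pct_tumour_tested: Optional[float]


def summarize_cohort(
    patients: list[PatientRecord],
    inclusions: list[InclusionResult],
    conclusions: list[PatientConclusion],
    evidence: dict[tuple[str, str], TissueEvidence],
) -> CohortSummary:
    """Compute every cohort-level count and fraction.

    Denominators follow clinical reporting practice: label, gene, skin- and
    tumour-testing fractions are over included patients; the paired-culture
    and contamination fractions are over direct-skin-tested patients; the
    chemotherapy fraction is over the combined (confirmed + likely) clonal
    hematopoiesis group.
    """
    ids = {p.patient_id for p in patients}
    included_ids = {r.patient_id for r in inclusions if r.included}
    conc_ids = {c.patient_id for c in conclusions}
    if not included_ids <= ids:
        raise ConsistencyError("inclusion results reference unknown patients")
    if conc_ids != included_ids:
        raise ConsistencyError(
            f"conclusions cover {sorted(conc_ids)} but the screen included "
            f"{sorted(included_ids)}"
        )

    n = len(included_ids)
    included = [p for p in patients if p.patient_id in included_ids]
    by_id = {p.patient_id: p for p in patients}

    label_counts = {label: 0 for label in ConclusionLabel}
    for c in conclusions:
        label_counts[c.primary_label] += 1
    label_pct = {label: _pct(cnt, n) for label, cnt in label_counts.items()}
    ch_count = sum(label_counts[label] for label in CH_FAMILY)

    category_counts = {
        cat: sum(1 for r in inclusions if cat in r.categories) for cat in (1, 2, 3)
    }
    category_pct = {cat: _pct(cnt, n) for cat, cnt in category_counts.items()}

    gene_counts: dict[str, int] = {}
    multi_gene = 0
    for p in included:
        genes = {v.gene for v in p.variants if v.pathogenicity in ACTIONABLE}
        for g in sorted(genes):
            gene_counts[g] = gene_counts.get(g, 0) + 1
        if len(genes) > 1:
            multi_gene += 1
    gene_pct = {g: _pct(cnt, n) for g, cnt in gene_counts.items()}

    ch_patients = [c.patient_id for c in conclusions if c.primary_label in CH_FAMILY]
    chemo_ch = sum(
        1
        for pid in ch_patients
        if by_id[pid].clinical.chemo_history is ChemoHistory.YES
    )

    skin_tested = {
        p.patient_id
        for p in included
        if any(o.tissue is Tissue.DIRECT_SKIN for o in p.observations)
    }
    paired = {
        p.patient_id
        for p in included
        if p.patient_id in skin_tested
        and any(o.tissue is Tissue.CULTURED_FIBROBLAST for o in p.observations)
    }
    tumour_tested = {
        p.patient_id
        for p in included
        if any(o.tissue is Tissue.TUMOUR for o in p.observations)
    }
    contamination = set()
    for (pid, _key), ev in evidence.items():
        skin = ev.calls.get(Tissue.DIRECT_SKIN)
        fib = ev.calls.get(Tissue.CULTURED_FIBROBLAST)
        if (
            skin is not None
            and skin.contamination_suspected
            and fib is not None
            and fib.level is PresenceLevel.ABSENT
        ):
            contamination.add(pid)

    return CohortSummary(
        n_included=n,
        label_counts=label_counts,
        label_pct=label_pct,
        ch_combined_count=ch_count,
        ch_combined_pct=_pct(ch_count, n),
        category_counts=category_counts,
        category_pct=category_pct,
        gene_counts=gene_counts,
        gene_pct=gene_pct,
        multi_gene_count=multi_gene,
        multi_gene_pct=_pct(multi_gene, n),
        chemo_ch_count=chemo_ch,
        chemo_fraction_among_ch=_pct(chemo_ch, len(ch_patients)),
        n_direct_skin=len(skin_tested),
        pct_direct_skin=_pct(len(skin_tested), n),
        n_paired_cultured=len(paired),
        pct_paired_cultured=_pct(len(paired), len(skin_tested)),
        n_contamination_pattern=len(contamination),
        pct_contamination_pattern=_pct(len(contamination), len(skin_tested)),
        n_tumour_tested=len(tumour_tested),
        pct_tumour_tested=_pct(len(tumour_tested), n),
    )


def format_summary(summary: CohortSummary, style: str = "fraction") -> str:
    """Render a stable, diff-friendly text report.

    ``fraction`` prints "count/denominator"; ``percent_1dp`` prints one
    decimal place.
    """
    if style not in ("fraction", "percent_1dp"):
        raise ValueError(f"unknown style {style!r}")
    n = summary.n_included

    def fmt(count: int, pct: Optional[float], denom: int) -> str:
        if style == "fraction":
            return f"{count}/{denom}"
        return "n/a" if pct is None else f"{pct:.1f}"

    lines = [f"included patients: {n}"]
    lines.append("-- primary classification --")
    for label in ConclusionLabel:
        if label is ConclusionLabel.UNRESOLVED and summary.label_counts[label] == 0:
            continue
        lines.append(
            f"{LABEL_DISPLAY[label]}: "
            f"{fmt(summary.label_counts[label], summary.label_pct[label], n)}"
        )
    lines.append(
        f"CH combined (confirmed + likely): "
        f"{fmt(summary.ch_combined_count, summary.ch_combined_pct, n)}"
    )
    lines.append("-- inclusion categories --")
    for cat in (1, 2, 3):
        lines.append(
            f"category {cat}: "
            f"{fmt(summary.category_counts[cat], summary.category_pct[cat], n)}"
        )
    lines.append("-- genes (patient level) --")
    for gene in sorted(summary.gene_counts, key=lambda g: (-summary.gene_counts[g], g)):
        lines.append(
            f"{gene}: {fmt(summary.gene_counts[gene], summary.gene_pct[gene], n)}"
        )
    lines.append(
        f"multi-gene patients: {fmt(summary.multi_gene_count, summary.multi_gene_pct, n)}"
    )
    lines.append("-- clinical context --")
    lines.append(
        "chemotherapy among CH: "
        f"{fmt(summary.chemo_ch_count, summary.chemo_fraction_among_ch, summary.ch_combined_count)}"
    )
    lines.append("-- secondary tissue testing --")
    lines.append(
        f"direct skin tested: {fmt(summary.n_direct_skin, summary.pct_direct_skin, n)}"
    )
    lines.append(
        "paired fibroblast culture: "
        f"{fmt(summary.n_paired_cultured, summary.pct_paired_cultured, summary.n_direct_skin)}"
    )
    lines.append(
        "blood-contamination pattern: "
        f"{fmt(summary.n_contamination_pattern, summary.pct_contamination_pattern, summary.n_direct_skin)}"
    )
    lines.append(
        f"tumour tested: {fmt(summary.n_tumour_tested, summary.pct_tumour_tested, n)}"
    )
    return "\n".join(lines) + "\n"
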