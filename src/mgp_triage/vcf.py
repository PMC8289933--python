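"""Minimal VCF ingestion: extract per-sample allele fractions.

Laboratories report allele fractions directly, but a VCF with per-sample
``AD``/``DP`` (or ``AF``) FORMAT fields is the standard machine-readable
carrier, so one observation is built per ALT allele of the named sample:
``af = 100 * alt_depth / total_depth`` (or the direct ``AF`` value times
100). Multi-allelic records are split per ALT.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from cyvcf2 import VCF

from .errors import SampleLookupError, VcfFormatError
from .model import AlleleFraction, Tissue, TissueObservation


def _variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def ingest_vcf(
    path: str | Path,
    sample_id: str,
    tissue: Tissue,
    age_at_sample: Optional[float] = None,
) -> list[TissueObservation]:
    """Extract one :class:`TissueObservation` per ALT allele for one sample.

    Depth precedence: ``AD`` (+ ``DP`` for the total when present, else the
    summed ``AD``), then a direct per-sample ``AF`` field. A record with zero
    total depth, or zero supporting reads, yields status ``ABSENT``.
    """
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        if sample_id not in samples:
            raise SampleLookupError(
                f"sample {sample_id!r} not in VCF (has {samples})"
            )
        si = samples.index(sample_id)
        out: list[TissueObservation] = []
        for rec in vcf:
            fmt_keys = rec.FORMAT or []
            ad = rec.format("AD") if "AD" in fmt_keys else None
            dp = rec.format("DP") if "DP" in fmt_keys else None
            af_field = rec.format("AF") if "AF" in fmt_keys else None
            for ai, alt in enumerate(rec.ALT):
                key = _variant_key(rec.CHROM, rec.POS, rec.REF, alt)
                if ad is not None:
                    depths = [max(int(d), 0) for d in ad[si]]
                    alt_depth = depths[ai + 1] if len(depths) > ai + 1 else 0
                    if dp is not None and int(dp[si][0]) >= 0:
                        total = int(dp[si][0])
                    else:
                        total = sum(depths)
                    if total <= 0 or alt_depth <= 0:
                        af = AlleleFraction.absent()
                    else:
                        af = AlleleFraction.quantified(100.0 * alt_depth / total)
                elif af_field is not None:
                    frac = float(af_field[si][ai])
                    if frac <= 0:
                        af = AlleleFraction.absent()
                    else:
                        af = AlleleFraction.quantified(100.0 * frac)
                else:
                    raise VcfFormatError(
                        f"{key}: record carries neither AD/DP nor AF FORMAT "
                        "fields; cannot extract an allele fraction"
                    )
                out.append(
                    TissueObservation(
                        variant_key=key,
                        tissue=tissue,
                        af=af,
                        age_at_sample=age_at_sample,
                    )
                )
        return out
    finally:
        vcf.close()
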