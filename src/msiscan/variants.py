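"""Multi-sample VCF reading, SNP/indel classification and variant filtering.

The working unit is a :class:`VariantSite`: one VCF record with one call per
culture condition (control, low stress, high stress).  Filters mirror a
standard hard-filter + group-comparison workflow for three-condition
designs: drop low-confidence sites (depth, mapping quality), drop variants
shared identically by all conditions, keep sites where at least one treated
condition differs from the control, and finally restrict to indels.

All filters are pure subset operations: they never mutate records and
preserve input order, so composing them can only shrink the record count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

SNP = "SNP"
INDEL = "INDEL"

DEFAULT_CONDITIONS = ("control", "low", "high")

#: GATK-style hard-filter floors: minimum per-sample read depth and site
#: mapping quality, applied as inclusive thresholds (fail when below).
DEFAULT_DP_MIN = 6
DEFAULT_MQ_MIN = 30.0


class VcfConfigurationError(ValueError):
    """Input VCF lacks a required sample column."""


class VcfFormatError(ValueError):
    """Input VCF record lacks a required FORMAT/INFO field."""


Genotype = tuple  # tuple of allele indices, possibly containing None


@dataclass(frozen=True)
class SampleCall:
    """Per-sample genotype call: GT, per-allele AD (reference first), DP."""

    genotype: Genotype | None
    allelic_depths: tuple[int, ...] | None
    total_depth: int | None

    @property
    def variant_depth(self) -> int | None:
        """Sum of non-reference allelic depths; None when AD is missing."""
        if self.allelic_depths is None:
            return None
        return sum(self.allelic_depths[1:])

    def genotype_key(self) -> tuple | None:
        """Order-insensitive genotype (0/1 == 1/0); None when any allele missing."""
        if self.genotype is None or any(a is None for a in self.genotype):
            return None
        return tuple(sorted(self.genotype))


def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """INDEL when any alt differs in length from ref; length-preserving
    substitutions (SNPs and symmetric MNPs) stay out of the indel stream."""
    return INDEL if any(len(a) != len(ref) for a in alts) else SNP


@dataclass(frozen=True)
class VariantSite:
    """One VCF record with calls for each culture condition."""

    scaffold: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    site_mq: float | None
    calls: Mapping[str, SampleCall]
    variant_class: str = field(default="")

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError(f"{self.scaffold}:{self.position} has no alt allele")
        if self.variant_class == "":
            object.__setattr__(
                self, "variant_class", classify_variant(self.ref_allele, self.alt_alleles)
            )

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive interval occupied by the REF allele."""
        return self.position, self.position + len(self.ref_allele) - 1

    def call(self, condition: str) -> SampleCall:
        return self.calls[condition]


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, condition_names: Sequence[str] = DEFAULT_CONDITIONS
) -> list[VariantSite]:
    """Read a VCF 4.x with GT:AD:DP FORMAT and site MQ into VariantSites.

    Multi-allelic records are kept un-split.  Missing AD/DP values are
    recorded as missing (None), never coerced to zero.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [c for c in condition_names if c not in samples]
        if missing:
            raise VcfConfigurationError(
                f"sample column(s) {missing} not in VCF (has {samples})"
            )
        fmt_keys = set(vcf.header.formats.keys())
        for need in ("GT", "AD", "DP"):
            if need not in fmt_keys:
                raise VcfFormatError(f"VCF FORMAT lacks {need}")
        for rec in vcf:
            if rec.alts is None:
                continue  # monomorphic reference block, nothing to score
            mq = rec.info.get("MQ")
            calls = {}
            for cond in condition_names:
                s = rec.samples[cond]
                gt = s.get("GT")
                if gt is not None and all(a is None for a in gt):
                    gt = None
                ad = s.get("AD")
                if ad is not None:
                    ad = None if any(a is None for a in ad) else tuple(int(a) for a in ad)
                if ad is not None and len(ad) != 1 + len(rec.alts):
                    raise VcfFormatError(
                        f"{rec.chrom}:{rec.pos} AD length {len(ad)} != "
                        f"{1 + len(rec.alts)} alleles"
                    )
                dp = s.get("DP")
                calls[cond] = SampleCall(
                    genotype=tuple(gt) if gt is not None else None,
                    allelic_depths=ad,
                    total_depth=int(dp) if dp is not None else None,
                )
            sites.append(
                VariantSite(
                    scaffold=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts),
                    site_mq=float(mq) if mq is not None else None,
                    calls=calls,
                )
            )
    return sites


def write_vcf(
    sites: Iterable[VariantSite],
    path: str | Path,
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write VariantSites as VCF 4.2 with FORMAT GT:AD:DP and INFO MQ."""
    sites = list(sites)
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    contigs: dict[str, int | None] = {}
    for site in sites:
        contigs.setdefault(site.scaffold, None)
    if contig_lengths:
        contigs.update({k: v for k, v in contig_lengths.items()})
    for name, length in contigs.items():
        if length is None:
            header.add_line(f"##contig=<ID={name}>")
        else:
            header.add_line(f"##contig=<ID={name},length={length}>")
    for cond in condition_names:
        header.add_sample(cond)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.scaffold,
                start=site.position - 1,
                alleles=(site.ref_allele, *site.alt_alleles),
            )
            if site.site_mq is not None:
                rec.info["MQ"] = site.site_mq
            for cond in condition_names:
                call = site.calls[cond]
                s = rec.samples[cond]
                s["GT"] = call.genotype if call.genotype is not None else (None, None)
                if call.allelic_depths is not None:
                    s["AD"] = call.allelic_depths
                if call.total_depth is not None:
                    s["DP"] = call.total_depth
            out.write(rec)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def hard_filter(
    sites: Sequence[VariantSite],
    dp_min: int = DEFAULT_DP_MIN,
    mq_min: float = DEFAULT_MQ_MIN,
    per_sample_dp: bool = True,
) -> list[VariantSite]:
    """Drop sites below the depth/mapping-quality floors (inclusive minima).

    With ``per_sample_dp`` (default) every condition must reach ``dp_min``;
    otherwise the summed depth across conditions is used.  Sites with
    missing MQ or missing depth fail the corresponding check.
    """
    kept = []
    for site in sites:
        if site.site_mq is None or site.site_mq < mq_min:
            continue
        depths = [c.total_depth for c in site.calls.values()]
        if per_sample_dp:
            if any(d is None or d < dp_min for d in depths):
                continue
        else:
            if sum(d or 0 for d in depths) < dp_min:
                continue
        kept.append(site)
    return kept


def drop_group_shared(
    sites: Sequence[VariantSite],
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[VariantSite]:
    """Remove sites where all conditions share one identical non-reference genotype.

    These are fixed differences from the reference assembly, not
    treatment-induced variation.  A missing genotype is never treated as
    identical: such sites are retained and logged.
    """
    kept = []
    hom_ref = (0, 0)
    for site in sites:
        keys = [site.calls[c].genotype_key() for c in condition_names]
        if any(k is None for k in keys):
            logger.debug(
                "retaining %s:%d with missing genotype (missing != identical)",
                site.scaffold,
                site.position,
            )
            kept.append(site)
            continue
        if len(set(keys)) == 1 and keys[0] != hom_ref:
            continue
        kept.append(site)
    return kept


def keep_treatment_differs(
    sites: Sequence[VariantSite],
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[VariantSite]:
    """Keep sites where at least one treated condition's genotype differs
    from the control's; a missing genotype counts as a difference we cannot
    rule out, so the site is retained."""
    control, *treated = condition_names
    kept = []
    for site in sites:
        ctrl = site.calls[control].genotype_key()
        gts = [site.calls[t].genotype_key() for t in treated]
        if ctrl is None or any(g is None for g in gts) or any(g != ctrl for g in gts):
            kept.append(site)
    return kept


def select_indels(sites: Sequence[VariantSite]) -> list[VariantSite]:
    """Restrict to indel records (any allele-length difference vs REF)."""
    return [s for s in sites if s.variant_class == INDEL]
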