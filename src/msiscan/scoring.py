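"""Mutation scores, relative scores and the candidate-MSI filter cascade.

The mutation score of a sample call is the fraction of reads supporting any
non-reference allele, in percent:

    m = 100 * (sum of non-reference allelic depths) / (total depth)

capped at 100.  Relative scores subtract the control:

    r_low  = m_low  - m_control
    r_high = m_high - m_control

A candidate MSI locus is an indel that (1) responds more strongly to the
high dose than the low dose (r_high > r_low), (2) has a positive relative
score, (3) falls inside a perfect microsatellite, and (4) has a genotype
that differs from the control with strictly fewer variant reads in the
control than in each treated sample.  Candidates are ranked by summed read
depth: with scores built from allelic depths, deeply covered loci carry
more evidence than shallow ones.

Scores are held as exact rationals internally so that filter comparisons
never depend on decimal rounding; rounding to two decimals happens only at
output boundaries.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .repeats import MicrosatelliteLocus
from .variants import DEFAULT_CONDITIONS, SampleCall, VariantSite

logger = logging.getLogger(__name__)

#: cascade stage names, in execution order
STAGE_INDELS = "indels"
STAGE_DOSE = "dose_dependent"
STAGE_POSITIVE = "positive_relative_score"
STAGE_MSAT = "microsatellite_confirmed"
STAGE_CONTROL = "control_differs"


class ScoreUndefinedError(ValueError):
    """Mutation score undefined: zero/missing depth or missing AD."""


def mutation_score(call: SampleCall) -> Fraction:
    """Percent of reads supporting a non-reference allele, capped at 100.

    Raises :class:`ScoreUndefinedError` when the total depth is zero or
    missing, or AD is missing; callers exclude such loci from the cascade.
    """
    if call.total_depth is None or call.total_depth <= 0:
        raise ScoreUndefinedError("total depth missing or zero")
    if call.allelic_depths is None:
        raise ScoreUndefinedError("allelic depths missing")
    score = Fraction(100 * call.variant_depth, call.total_depth)
    return min(score, Fraction(100))


@dataclass(frozen=True)
class ScoredLocus:
    """A variant site with per-condition mutation scores (percent)."""

    site: VariantSite
    m_control: Fraction
    m_low: Fraction
    m_high: Fraction
    msat: MicrosatelliteLocus | None = None

    @property
    def r_low(self) -> Fraction:
        return self.m_low - self.m_control

    @property
    def r_high(self) -> Fraction:
        return self.m_high - self.m_control

    @property
    def total_depth_sum(self) -> int:
        return sum(c.total_depth or 0 for c in self.site.calls.values())


def relative_scores(scored: ScoredLocus) -> tuple[Fraction, Fraction]:
    """(treated minus control) scores for the low and high doses."""
    return scored.r_low, scored.r_high


def score_sites(
    sites: Sequence[VariantSite],
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[ScoredLocus]:
    """Score every site; loci with undefined scores are excluded and logged."""
    control, low, high = condition_names
    scored = []
    for site in sites:
        try:
            scored.append(
                ScoredLocus(
                    site=site,
                    m_control=mutation_score(site.calls[control]),
                    m_low=mutation_score(site.calls[low]),
                    m_high=mutation_score(site.calls[high]),
                )
            )
        except ScoreUndefinedError as err:
            logger.warning(
                "excluding %s:%d from cascade: %s", site.scaffold, site.position, err
            )
    return scored


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def dose_dependence_filter(loci: Sequence[ScoredLocus]) -> list[ScoredLocus]:
    """Keep loci whose high-dose relative score strictly exceeds the low-dose one."""
    return [l for l in loci if l.r_high > l.r_low]


def positivity_filter(
    loci: Sequence[ScoredLocus], require_both: bool = True
) -> list[ScoredLocus]:
    """Keep loci with positive relative scores.

    Standalone use (default) requires both r_low > 0 and r_high > 0; inside
    the cascade, after the dose-dependence filter, r_low > 0 already implies
    r_high > 0, so ``require_both=False`` checks r_low only.
    """
    if require_both:
        return [l for l in loci if l.r_low > 0 and l.r_high > 0]
    return [l for l in loci if l.r_low > 0]


def intersect_with_msats(
    loci: Sequence[ScoredLocus], msats: Sequence[MicrosatelliteLocus]
) -> list[ScoredLocus]:
    """Keep loci whose REF-allele interval overlaps a microsatellite by >= 1 bp.

    The indel occupies the 1-based inclusive interval
    [position, position + len(ref) - 1] (an insertion occupies only its
    anchor base).  A locus overlapping several microsatellites is annotated
    with the largest overlap, ties to the leftmost.
    """
    msats = list(msats)
    if any(
        (a.scaffold, a.start) > (b.scaffold, b.start)
        for a, b in zip(msats, msats[1:])
    ):
        logger.info("microsatellite table unsorted; sorting internally")
        msats.sort(key=lambda m: (m.scaffold, m.start))
    trees: dict[str, IntervalTree] = {}
    for m in msats:
        trees.setdefault(m.scaffold, IntervalTree()).addi(m.start, m.end + 1, m)
    kept = []
    for locus in loci:
        start, end = locus.site.ref_span
        tree = trees.get(locus.site.scaffold)
        if tree is None:
            continue
        hits = tree.overlap(start, end + 1)
        if not hits:
            continue
        best = max(
            (iv.data for iv in hits),
            key=lambda m: (min(m.end, end) - max(m.start, start) + 1, -m.start),
        )
        kept.append(replace(locus, msat=best))
    return kept


def control_differs_filter(
    loci: Sequence[ScoredLocus],
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
) -> list[ScoredLocus]:
    """Keep loci where the treated genotypes depart from the control and the
    control has strictly fewer variant reads than each treated sample.

    Loci with any missing genotype are removed and logged: without a
    genotype the departure from the control cannot be established.
    """
    control, *treated = condition_names
    kept = []
    for locus in loci:
        calls = locus.site.calls
        ctrl_gt = calls[control].genotype_key()
        treated_gts = [calls[t].genotype_key() for t in treated]
        if ctrl_gt is None or any(g is None for g in treated_gts):
            logger.warning(
                "removing %s:%d: missing genotype in control-differs filter",
                locus.site.scaffold,
                locus.site.position,
            )
            continue
        ctrl_vd = calls[control].variant_depth
        treated_vd = [calls[t].variant_depth for t in treated]
        if ctrl_vd is None or any(v is None for v in treated_vd):
            continue
        if any(g != ctrl_gt for g in treated_gts) and all(
            ctrl_vd < v for v in treated_vd
        ):
            kept.append(locus)
    return kept


@dataclass
class FilterTrace:
    """Locus counts remaining after each cascade stage, in stage order."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, stage: str, remaining: int) -> None:
        if self.stages and remaining > self.stages[-1][1]:
            raise ValueError(
                f"stage {stage!r} increased locus count "
                f"({self.stages[-1][1]} -> {remaining})"
            )
        self.stages.append((stage, remaining))

    @property
    def counts(self) -> list[int]:
        return [n for _, n in self.stages]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([{"stage": s, "remaining": n} for s, n in self.stages], indent=2)
            + "\n"
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tremaining"] + [f"{s}\t{n}" for s, n in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class CandidateMSILocus:
    """A fully filtered, microsatellite-confirmed indel locus with its rank."""

    scored: ScoredLocus
    msat: MicrosatelliteLocus
    rank: int
    total_depth_sum: int


def rank_candidates(loci: Sequence[ScoredLocus]) -> list[CandidateMSILocus]:
    """Order passed loci by summed depth (desc), then r_high (desc), then
    genomic coordinate, and assign ranks 1..n."""
    ordered = sorted(
        loci,
        key=lambda l: (
            -l.total_depth_sum,
            -l.r_high,
            l.site.scaffold,
            l.site.position,
        ),
    )
    return [
        CandidateMSILocus(
            scored=l,
            msat=l.msat,
            rank=i + 1,
            total_depth_sum=l.total_depth_sum,
        )
        for i, l in enumerate(ordered)
    ]


def run_cascade(
    scored_indels: Sequence[ScoredLocus],
    msats: Sequence[MicrosatelliteLocus],
    condition_names: Sequence[str] = DEFAULT_CONDITIONS,
) -> tuple[list[CandidateMSILocus], FilterTrace]:
    """Run the full filter cascade over scored indel loci.

    Stage order mirrors the discovery workflow: dose dependence, positive
    relative score, microsatellite confirmation, control departure.  The
    final candidate set is order-invariant (all stages are pure
    predicates); only the trace counts depend on the order.
    """
    trace = FilterTrace()
    trace.add(STAGE_INDELS, len(scored_indels))
    loci = dose_dependence_filter(scored_indels)
    trace.add(STAGE_DOSE, len(loci))
    loci = positivity_filter(loci, require_both=False)
    trace.add(STAGE_POSITIVE, len(loci))
    loci = intersect_with_msats(loci, msats)
    trace.add(STAGE_MSAT, len(loci))
    loci = control_differs_filter(loci, condition_names)
    trace.add(STAGE_CONTROL, len(loci))
    return rank_candidates(loci), trace


# ---------------------------------------------------------------------------
# Score-table replay (pre-computed per-condition scores, no genotypes)
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("score_control", "score_10mM", "score_30mM")


def cascade_on_scores(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterTrace]:
    """Run the cascade on a table of pre-computed per-condition scores.

    Expects columns ``score_control``, ``score_10mM``, ``score_30mM``
    (percent).  With no genotypes available, the control-departure stage
    uses its score-level surrogate: the control score must lie strictly
    below both treated scores.  Microsatellite membership is taken as given
    (such tables are produced downstream of the intersection).
    """
    for col in SCORE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"score table lacks column {col!r}")
    frac = {
        col: table[col].map(lambda v: Fraction(str(v))) for col in SCORE_COLUMNS
    }
    r_low = frac["score_10mM"] - frac["score_control"]
    r_high = frac["score_30mM"] - frac["score_control"]

    trace = FilterTrace()
    trace.add(STAGE_INDELS, len(table))
    keep = r_high > r_low
    trace.add(STAGE_DOSE, int(keep.sum()))
    keep &= r_low > 0
    trace.add(STAGE_POSITIVE, int(keep.sum()))
    trace.add(STAGE_MSAT, int(keep.sum()))
    keep &= (frac["score_control"] < frac["score_10mM"]) & (
        frac["score_control"] < frac["score_30mM"]
    )
    trace.add(STAGE_CONTROL, int(keep.sum()))
    return table[keep].copy(), trace


def load_candidate_fixture() -> pd.DataFrame:
    """The packaged reference table of 124 published candidate MSI loci
    (CHO cells under ammonia stress), with per-condition scores in percent."""
    ref = importlib.resources.files("msiscan.data").joinpath("candidate_msi_loci.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def candidates_to_table(candidates: Sequence[CandidateMSILocus]) -> pd.DataFrame:
    """Render ranked candidates as the output table (scores in 2-decimal percent)."""
    rows = []
    for c in candidates:
        s = c.scored
        rows.append(
            {
                "Scaffold": s.site.scaffold,
                "Position": s.site.position,
                "Motif": c.msat.notation if c.msat else "",
                "Score10": round(float(s.m_low), 2),
                "Score30": round(float(s.m_high), 2),
                "ScoreControl": round(float(s.m_control), 2),
                "RelScore10": round(float(s.r_low), 2),
                "RelScore30": round(float(s.r_high), 2),
                "DepthSum": c.total_depth_sum,
                "Rank": c.rank,
            }
        )
    columns = [
        "Scaffold",
        "Position",
        "Motif",
        "Score10",
        "Score30",
        "ScoreControl",
        "RelScore10",
        "RelScore30",
        "DepthSum",
        "Rank",
    ]
    return pd.DataFrame(rows, columns=columns)
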