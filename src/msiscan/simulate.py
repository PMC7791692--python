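"""Synthetic study generator: reference with planted microsatellites and a
three-condition variant-call set with configurable dose response.

The generator emulates the input side of an ammonia-stress genome study:
a small reference assembly carrying perfect di-/tri-/tetranucleotide
repeats, and one multi-sample VCF with a control, a low-stress and a
high-stress sample.  Chosen repeat loci receive single-unit
insertions/deletions whose variant-read fraction rises with dose
(dose-dependent MSI), stays flat (shared), or falls from low to high dose
(non-dose); background SNPs and sites planted to fail the hard filters
complete the picture.  Per-sample allelic depths are binomial draws at the
locus's true variant-allele fraction with Poisson total depth, the simplest
model consistent with read sampling.

Everything is driven by one integer seed: identical config + seed gives
byte-identical FASTA, VCF and truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeats import (
    MicrosatelliteLocus,
    RepeatThresholds,
    find_microsatellites,
    is_primitive,
    write_msat_table,
)
from .variants import SampleCall, VariantSite, write_vcf

BASES = "ACGT"

# locus classes in the truth manifest
CLASS_DOSE = "dose_dependent_msi"
CLASS_NON_DOSE = "non_dose"
CLASS_SHARED = "shared"
CLASS_NEUTRAL = "neutral"
CLASS_LOW_MQ = "low_mq"
CLASS_LOW_DP = "low_dp"


class SimulationSizingError(ValueError):
    """Requested planted loci do not fit in the configured genome."""


class CoordinateError(ValueError):
    """A truth position falls outside its scaffold."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome and variant calls.

    Defaults give a compact desk-scale study: three ~120 kb scaffolds, 160
    planted microsatellites of which 50 carry dose-dependent indels
    (variant fraction 0 / 0.2 / 0.5 in control / low / high), 50 carry
    non-dose indels, 50 carry condition-shared indels, plus 500 neutral
    SNPs and a handful of sites planted to fail the DP/MQ hard filters.
    """

    n_scaffolds: int = 3
    scaffold_length: int = 120_000
    n_planted_msats: int = 160
    motif_pool: tuple[str, ...] = (
        "AC", "AG", "GT", "TC", "AAC", "AAT", "TTG", "AAAC", "AGAT", "TTGT",
    )
    repeat_count_range: tuple[int, int] = (6, 20)
    n_dose_dependent: int = 50
    n_non_dose: int = 50
    n_shared: int = 50
    n_neutral_snps: int = 500
    mean_depth: float = 200.0
    mq_clean: float = 60.0
    mq_low: float = 20.0
    n_low_mq: int = 5
    n_low_dp: int = 5
    low_dp_max: int = 5
    vaf_triplet: tuple[float, float, float] = (0.0, 0.2, 0.5)
    non_dose_vaf: tuple[float, float, float] = (0.0, 0.4, 0.2)
    shared_vaf: tuple[float, float, float] = (0.3, 0.3, 0.3)
    condition_names: tuple[str, str, str] = ("control", "low", "high")
    guard_bp: int = 30
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_scaffolds=self.n_scaffolds,
            scaffold_length=self.scaffold_length,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in (
            "n_planted_msats", "n_dose_dependent", "n_non_dose", "n_shared",
            "n_neutral_snps", "n_low_mq", "n_low_dp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.repeat_count_range
        if lo < 2 or hi < lo:
            raise ValueError(f"bad repeat_count_range {self.repeat_count_range}")
        for motif in self.motif_pool:
            if not (2 <= len(motif) <= 4):
                raise ValueError(f"motif {motif!r} must have length 2-4")
            if set(motif) - set(BASES):
                raise ValueError(f"motif {motif!r} has non-ACGT characters")
            if not is_primitive(motif):
                raise ValueError(f"motif {motif!r} is not primitive")
        for trip in (self.vaf_triplet, self.non_dose_vaf, self.shared_vaf):
            if any(not 0 <= v <= 1 for v in trip):
                raise ValueError(f"variant-allele fractions must be in [0,1]: {trip}")
        c, l, h = self.vaf_triplet
        if not c < l < h:
            raise ValueError(
                f"dose-dependent vaf_triplet must be strictly increasing: {self.vaf_triplet}"
            )
        if self.non_dose_vaf[2] > self.non_dose_vaf[1]:
            raise ValueError("non_dose_vaf must not increase from low to high")
        n_variant = self.n_dose_dependent + self.n_non_dose + self.n_shared
        if self.n_planted_msats < n_variant:
            raise ValueError(
                f"n_planted_msats ({self.n_planted_msats}) < variant msat loci ({n_variant})"
            )

    @property
    def n_variant_msats(self) -> int:
        return self.n_dose_dependent + self.n_non_dose + self.n_shared


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated variant locus."""

    scaffold: str
    position: int  # 1-based, equals the VCF POS of the record
    locus_class: str
    true_vaf: tuple[float, float, float]  # (control, low, high)
    in_msat: bool
    motif: str = ""
    repeat_count: int = 0


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

_MAX_CLEANUP_ROUNDS = 50


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(BASES), size=length))


def _fix_flanks(seq: list[str], rng: np.random.Generator, locus_start0: int,
                length: int, motif: str) -> None:
    """Break period continuation immediately left and right of a planted run."""
    left = locus_start0 - 1
    if left >= 0 and seq[left] == motif[-1]:
        seq[left] = rng.choice([b for b in BASES if b != motif[-1]])
    right = locus_start0 + length
    if right < len(seq) and seq[right] == motif[0]:
        seq[right] = rng.choice([b for b in BASES if b != motif[0]])


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[MicrosatelliteLocus]]:
    """Build the synthetic reference and its planted microsatellites.

    Planted repeats are spaced in per-scaffold segments with a guard margin;
    the background is post-screened with the package's own repeat finder and
    re-randomised wherever an accidental qualifying repeat appears, so the
    returned locus list is the complete microsatellite annotation of the
    genome at default thresholds.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    thresholds = RepeatThresholds()
    lo, hi = config.repeat_count_range

    per_scaffold = [config.n_planted_msats // config.n_scaffolds] * config.n_scaffolds
    for k in range(config.n_planted_msats % config.n_scaffolds):
        per_scaffold[k] += 1

    reference: dict[str, str] = {}
    planted: list[MicrosatelliteLocus] = []
    max_len = 4 * hi
    for idx in range(config.n_scaffolds):
        name = f"scaffold_{idx + 1}"
        n_slots = per_scaffold[idx]
        seq = _random_seq(rng, config.scaffold_length)
        slots: list[tuple[str, int, int]] = []  # (motif, count, start0)
        if n_slots:
            seg = config.scaffold_length // n_slots
            if seg < max_len + 2 * config.guard_bp + 2:
                raise SimulationSizingError(
                    f"{n_slots} repeats of up to {max_len} bp plus {config.guard_bp} bp "
                    f"guards do not fit in {config.scaffold_length} bp ({name})"
                )
            for s in range(n_slots):
                motif = str(rng.choice(config.motif_pool))
                # clamp below the detection floor so every planted repeat is findable
                floor = max(lo, thresholds.min_repeats[len(motif)])
                count = int(rng.integers(floor, max(hi, floor) + 1))
                length = len(motif) * count
                span = seg - 2 * config.guard_bp - length - 2
                start0 = s * seg + config.guard_bp + 1 + int(rng.integers(0, max(span, 1)))
                seq[start0 : start0 + length] = list(motif * count)
                _fix_flanks(seq, rng, start0, length, motif)
                slots.append((motif, count, start0))
        expected = {
            (s0 + 1, s0 + len(m) * c, m): (m, c) for m, c, s0 in slots
        }
        # screen background: re-randomise accidental repeats, keep planted intact
        protected = np.zeros(config.scaffold_length, dtype=bool)
        for m, c, s0 in slots:
            a = max(0, s0 - 1)
            b = min(config.scaffold_length, s0 + len(m) * c + 1)
            protected[a:b] = True
        for _ in range(_MAX_CLEANUP_ROUNDS):
            found = find_microsatellites("".join(seq), name, thresholds)
            extras = [
                f for f in found if (f.start, f.end, f.motif) not in expected
            ]
            if not extras and len(found) == len(expected):
                break
            if not extras:
                raise SimulationSizingError(
                    f"planted repeat lost during screening on {name}"
                )
            for f in extras:
                for p in range(f.start - 1, f.end):
                    if not protected[p]:
                        seq[p] = rng.choice(list(BASES))
            for m, c, s0 in slots:
                _fix_flanks(seq, rng, s0, len(m) * c, m)
        else:
            raise SimulationSizingError(
                f"could not screen accidental repeats from {name} "
                f"in {_MAX_CLEANUP_ROUNDS} rounds"
            )
        reference[name] = "".join(seq)
        for m, c, s0 in slots:
            planted.append(
                MicrosatelliteLocus(
                    scaffold=name, start=s0 + 1, end=s0 + len(m) * c,
                    motif=m, repeat_count=c,
                )
            )
    planted.sort(key=lambda l: (l.scaffold, l.start))
    return reference, planted


# ---------------------------------------------------------------------------
# Variant-call simulation
# ---------------------------------------------------------------------------


def _draw_call(
    rng: np.random.Generator,
    vaf: float,
    mean_depth: float,
    dp_override: int | None = None,
) -> SampleCall:
    dp = dp_override if dp_override is not None else max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(dp, vaf))
    if alt == 0:
        gt = (0, 0)
    elif alt / dp >= 0.85:
        gt = (1, 1)
    else:
        gt = (0, 1)
    return SampleCall(genotype=gt, allelic_depths=(dp - alt, alt), total_depth=dp)


def simulate_variant_calls(
    reference: Mapping[str, str],
    msat_truth: Sequence[MicrosatelliteLocus],
    config: SimulationConfig,
) -> tuple[list[VariantSite], list[TruthRecord]]:
    """Simulate the multi-sample variant calls and their truth manifest.

    Dose-dependent, non-dose and shared loci are single-unit
    insertions/deletions of the motif placed inside planted
    microsatellites (the replication-slippage mutation MSI produces);
    neutral/low-MQ/low-DP loci are background SNPs.
    """
    config.validate()
    for m in msat_truth:
        if m.scaffold not in reference or m.end > len(reference[m.scaffold]):
            raise CoordinateError(f"microsatellite {m} outside reference")
    rng = np.random.default_rng([config.seed, 2])

    order = rng.permutation(len(msat_truth))
    roles: dict[int, str] = {}
    cursor = 0
    for cls, n in (
        (CLASS_DOSE, config.n_dose_dependent),
        (CLASS_NON_DOSE, config.n_non_dose),
        (CLASS_SHARED, config.n_shared),
    ):
        for i in order[cursor : cursor + n]:
            roles[int(i)] = cls
        cursor += n

    vaf_by_class = {
        CLASS_DOSE: config.vaf_triplet,
        CLASS_NON_DOSE: config.non_dose_vaf,
        CLASS_SHARED: config.shared_vaf,
    }
    sites: list[VariantSite] = []
    truth: list[TruthRecord] = []
    used: set[tuple[str, int]] = set()

    for i, msat in enumerate(msat_truth):
        cls = roles.get(i)
        if cls is None:
            continue
        seq = reference[msat.scaffold]
        unit = len(msat.motif)
        pos = msat.start  # anchor on the first repeat base
        anchor = seq[pos - 1]
        if rng.random() < 0.5:  # contraction: drop one motif unit
            ref_allele = seq[pos - 1 : pos - 1 + unit + 1]
            alts = (anchor,)
        else:  # expansion: gain one motif unit
            ref_allele = anchor
            alts = (anchor + msat.motif,)
        vaf = vaf_by_class[cls]
        calls = {
            cond: _draw_call(rng, vaf[k], config.mean_depth)
            for k, cond in enumerate(config.condition_names)
        }
        sites.append(
            VariantSite(
                scaffold=msat.scaffold, position=pos, ref_allele=ref_allele,
                alt_alleles=alts, site_mq=config.mq_clean, calls=calls,
            )
        )
        truth.append(
            TruthRecord(
                scaffold=msat.scaffold, position=pos, locus_class=cls,
                true_vaf=vaf, in_msat=True, motif=msat.motif,
                repeat_count=msat.repeat_count,
            )
        )
        used.add((msat.scaffold, pos))

    # background SNP positions: outside microsatellites, unique
    blocked: dict[str, np.ndarray] = {
        name: np.zeros(len(seq) + 1, dtype=bool) for name, seq in reference.items()
    }
    for m in msat_truth:
        a = max(1, m.start - config.guard_bp)
        b = min(len(reference[m.scaffold]), m.end + config.guard_bp)
        blocked[m.scaffold][a : b + 1] = True

    scaffold_names = sorted(reference)

    def _snp_site(vaf: tuple[float, float, float], mq: float,
                  dp_override: bool = False) -> tuple[VariantSite, int, str]:
        for _ in range(1000):
            name = scaffold_names[int(rng.integers(0, len(scaffold_names)))]
            pos = int(rng.integers(1, len(reference[name]) + 1))
            if blocked[name][pos] or (name, pos) in used:
                continue
            used.add((name, pos))
            ref_base = reference[name][pos - 1]
            alt_base = str(rng.choice([b for b in BASES if b != ref_base]))
            calls = {}
            for k, cond in enumerate(config.condition_names):
                dp = int(rng.integers(1, config.low_dp_max + 1)) if dp_override else None
                calls[cond] = _draw_call(rng, vaf[k], config.mean_depth, dp_override=dp)
            site = VariantSite(
                scaffold=name, position=pos, ref_allele=ref_base,
                alt_alleles=(alt_base,), site_mq=mq, calls=calls,
            )
            return site, pos, name
        raise SimulationSizingError("could not place a background SNP")

    def _neutral_vaf() -> tuple[float, float, float]:
        while True:
            trip = tuple(0.5 * float(b) for b in rng.integers(0, 2, size=3))
            if any(v > 0 for v in trip):
                return trip  # type: ignore[return-value]

    for cls, n, mq, dp_override in (
        (CLASS_NEUTRAL, config.n_neutral_snps, config.mq_clean, False),
        (CLASS_LOW_MQ, config.n_low_mq, config.mq_low, False),
        (CLASS_LOW_DP, config.n_low_dp, config.mq_clean, True),
    ):
        for _ in range(n):
            vaf = _neutral_vaf() if cls != CLASS_LOW_MQ else (0.0, 0.5, 0.5)
            site, pos, name = _snp_site(vaf, mq, dp_override)
            sites.append(site)
            truth.append(
                TruthRecord(
                    scaffold=name, position=pos, locus_class=cls,
                    true_vaf=vaf, in_msat=False,
                )
            )

    key = lambda x: (x[0].scaffold, x[0].position)
    paired = sorted(zip(sites, truth), key=key)
    sites = [s for s, _ in paired]
    truth = [t for _, t in paired]
    return sites, truth


# ---------------------------------------------------------------------------
# File IO and one-call convenience
# ---------------------------------------------------------------------------


def write_reference_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


TRUTH_COLUMNS = (
    "scaffold", "position", "locus_class", "vaf_control", "vaf_low", "vaf_high",
    "in_msat", "motif", "repeat_count",
)


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    lines = ["\t".join(TRUTH_COLUMNS)]
    for t in truth:
        lines.append(
            "\t".join(
                [
                    t.scaffold, str(t.position), t.locus_class,
                    repr(t.true_vaf[0]), repr(t.true_vaf[1]), repr(t.true_vaf[2]),
                    "1" if t.in_msat else "0", t.motif, str(t.repeat_count),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(
            TruthRecord(
                scaffold=f[0], position=int(f[1]), locus_class=f[2],
                true_vaf=(float(f[3]), float(f[4]), float(f[5])),
                in_msat=f[6] == "1", motif=f[7], repeat_count=int(f[8]),
            )
        )
    return out


@dataclass
class SimulationResult:
    reference: dict[str, str]
    msats: list[MicrosatelliteLocus]
    sites: list[VariantSite]
    truth: list[TruthRecord]


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Generate reference, microsatellites, variant calls and truth in one call."""
    reference, msats = generate_reference(config)
    sites, truth = simulate_variant_calls(reference, msats, config)
    return SimulationResult(reference=reference, msats=msats, sites=sites, truth=truth)


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  config: SimulationConfig) -> dict[str, Path]:
    """Write FASTA, VCF, truth manifest and microsatellite table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fasta",
        "vcf": out / "calls.vcf",
        "truth": out / "truth.tsv",
        "msats": out / "msats.tsv",
    }
    write_reference_fasta(result.reference, paths["fasta"])
    write_vcf(
        result.sites, paths["vcf"], config.condition_names,
        contig_lengths={k: len(v) for k, v in result.reference.items()},
    )
    write_truth(result.truth, paths["truth"])
    write_msat_table(result.msats, paths["msats"], dialect="misa")
    return paths
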