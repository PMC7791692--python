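# Methods

## Scope and model

`msiscan` identifies candidate microsatellite-instability (MSI) loci from
a three-condition variant-call experiment: one control sample and two
stress doses (named `low`/`high`; in the motivating CHO-culture setting,
10 mM and 30 mM ammonia). The package does not call variants: it consumes
a VCF with per-sample GT, AD and DP and site-level MQ — the standard
output of a germline caller run per condition — plus a reference FASTA
for the microsatellite scan.

The core statistic is the per-sample **mutation score**
`m = 100·(Σ alt AD)/DP`, a variant-read fraction in percent, and its
control-subtracted **relative scores** `r_low`, `r_high`. The underlying
assumption is that a stress-responsive slippage locus shows a read
fraction that rises with dose, while clonal background differences from
the reference assembly appear equally in all three samples and
sequencing noise shows no consistent dose ordering. No significance test
is attached to the scores; ranking by summed depth is a proxy for
evidence strength, not a calibrated probability.

At multi-allelic sites "variant reads" is the sum of all non-reference
allelic depths: the score measures departure from the reference, not
support for one particular allele. External VCFs can carry AD sums
exceeding DP (uninformative reads are excluded from some callers' AD);
scores are therefore capped at 100.

## Filter semantics

* **Hard filter** — site MQ ≥ 30 and DP ≥ 6, both inclusive minima
  (hard-filter convention: fail when below threshold). DP is enforced
  per sample by default, since a condition's score is meaningless at
  negligible depth; a site-level (summed) mode is available via
  `per_sample_dp=False` / `--site-level-dp`.
* **Group-shared removal** — a site is dropped when all three conditions
  carry one identical non-reference genotype. Genotype comparison is
  unphased and order-insensitive (`0/1 ≡ 1/0`). Missing genotypes are
  never treated as identical: absence of evidence is not agreement, so
  such sites are retained (and logged).
* **Treatment-differs** — a site is kept when at least one treated
  genotype differs from the control (or a relevant genotype is missing,
  since equality then cannot be established).
* **Indel selection** — a record is an indel when any ALT length differs
  from the REF length. Length-preserving MNPs are classed with SNPs and
  excluded: the cascade is defined over length-changing events, which is
  what repeat slippage produces.
* **Dose dependence** — `r_high > r_low`, strict; ties carry no dose
  signal.
* **Positivity** — inside the cascade `r_low > 0` suffices (after the
  dose filter it implies `r_high > 0`); standalone calls check both.
* **Microsatellite confirmation** — the indel's REF interval,
  1-based `[POS, POS + len(REF) − 1]`, must share ≥ 1 bp with a repeat
  locus (BED-tools-style any-overlap). An insertion occupies only its
  anchor base. Among several overlapping repeats the largest overlap
  wins, ties to the leftmost. Unsorted repeat tables are sorted
  internally with a log notice.
* **Control departure** — a treated genotype differs from the control
  AND the control's variant-read count is strictly below each treated
  sample's. The conjunction combines the two published descriptions of
  the final stage (genotype variation; fewer-to-no control variant
  reads) into one well-defined predicate. Loci with missing genotypes
  are removed here (and logged): the departure cannot be established.

All cascade stages are pure predicates, so the final candidate set is
invariant to stage order (verified by a permutation test); only the
filter-trace counts depend on the order, which follows the workflow
order above. Loci whose score is undefined (zero or missing depth,
missing AD) are excluded from the cascade and logged.

Scores are exact `Fraction`s internally; two-decimal rounding happens
only in output tables. This matters at near-ties such as
`r_high − r_low = 0.15` points, where float accumulation could flip a
strict comparison.

### Ranking

Candidates are ordered by summed DP across the three samples
(descending), then by `r_high` (descending), then by scaffold and
position for a deterministic total order.

## Microsatellite scanner

A microsatellite is a maximal perfect tandem run of a primitive 2–4 bp
motif. Default minimum repeat counts are di ≥ 6, tri ≥ 5, tetra ≥ 5 —
standard SSR-scanner defaults, consistent with every motif class the
packaged 124-locus reference table contains (minimum observed: (GT)6,
(AAC)5, (CCTC)5) — with mononucleotide runs disabled. All thresholds are
configurable per motif length.

Definitions and edge rules:

* *Primitive motif*: not a power of a shorter string, so a (CA)8 run is
  reported once, never additionally as (CACA)4.
* *Maximality*: the run cannot be extended one base on either side
  keeping the motif period. A trailing partial unit is trimmed: the
  repeat count is ⌊run/unit⌋ and the reported span covers complete units
  only (so reverse-complement symmetry holds up to a sub-unit coordinate
  shift).
* The motif is reported as spelled at the locus start, matching the
  common `(AAC)5` table notation, not canonicalised across rotations or
  strands; `canonical_motif()` provides a grouping key when needed.
* Runs are broken at `N`; any other non-ACGTN character is an error
  naming its position.
* Compound/interrupted repeats are not merged; only perfect runs are
  reported.

Coordinates are 1-based inclusive internally (the SSR-table convention);
conversion to 0-based half-open occurs only when writing BED. The
scanner is checked against an exhaustive brute-force enumeration in both
the test suite and the acceptance script.

## Synthetic data generator

The generator emulates the *statistical* structure of a dose-response
genome study, not its raw reads: no FASTQ simulation, no alignment
artifacts, no subclonal structure, no CNV/ploidy effects. Consequences:
passing recovery tests demonstrate that the cascade isolates
dose-responsive loci under binomial read sampling at the configured
depths, not that it is robust to alignment error or caller idiosyncrasy
around real repeat tracts (where depth drops and AD is noisier).

Defaults (one deliberate desk-scale study configuration):

| parameter | default | meaning |
|---|---|---|
| `n_scaffolds`, `scaffold_length` | 3 × 120 000 bp | genome size |
| `n_planted_msats` | 160 | perfect repeats planted with guard margins |
| `repeat_count_range` | (6, 20) | units per planted repeat, clamped per motif class to the scanner's detection floor |
| `n_dose_dependent` | 50 | vaf (0, 0.2, 0.5) — control/low/high |
| `n_non_dose` | 50 | vaf (0, 0.4, 0.2): responds, but not dose-increasing |
| `n_shared` | 50 | vaf (0.3, 0.3, 0.3): clonal background |
| `n_neutral_snps` | 500 | random per-condition 0/0.5 fraction patterns |
| `n_low_mq`, `n_low_dp` | 5, 5 | planted hard-filter failures (MQ 20; DP 1–5) |
| `mean_depth` | 200 | Poisson mean per sample per site (floor 1) |

The dose-dependent fractions (0, 0.2, 0.5) sit in the range the
published per-condition scores span (roughly 10–100 %) while keeping the
control clean, the pattern the final cascade stage expects. Mean depth
200 is deliberately below the ~30× genome coverage of a production
study's *genome-wide* average only in the sense that simulated sites are
variant sites with healthy coverage; it keeps binomial noise realistic
without making recovery trivial.

Mechanics: per sample, DP ~ Poisson(mean_depth) with floor 1 and
alt-reads ~ Binomial(DP, vaf); genotypes follow the sampled fraction
(0 alt → 0/0, ≥ 0.85 → 1/1, else 0/1). Variant repeat loci receive
single-unit insertions or deletions of their motif — the slippage event
MSI describes — anchored at the first repeat base. The background
sequence is screened with the package's own scanner and re-randomised
wherever an accidental qualifying repeat appears, and planted flanks are
set to break period continuation, so the planted list is the complete
repeat annotation of the genome and the truth manifest is exact. The
dinucleotide lower repeat bound is clamped to the scanner floor (6) so
every planted repeat is discoverable by the genome scan; otherwise the
microsatellite-confirmation stage would silently drop truth loci.

All randomness flows from one integer seed through separate named
substreams for reference and variant generation; identical config + seed
reproduces byte-identical FASTA, VCF and truth files.

## Entry points

Three stages of entry accommodate different available inputs: a raw VCF
(full pipeline), a pre-filtered indel set (`assume_prefiltered=True`),
and a pre-computed per-condition score table (`cascade_on_scores` /
`msiscan score`). A score table carries no genotypes or depths, so the
control-departure stage uses its score-level surrogate there: the
control score must lie strictly below both treated scores. The packaged
124-locus reference table replays through this entry point unchanged.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale: the default
synthetic study (160 planted repeats, 650 variant records, ~360 kb
genome), 200 random 1 kb sequences for scanner/oracle equivalence, 1000
random intervals for intersection equivalence, the 27-case genotype
truth table, and a 1000-site depth-calibration study at depth 500. A
production genome (~2.3 Gb, hundreds of thousands of variants) is
handled by the same code paths but was not profiled here; the scanner is
pure Python and would be the first thing to optimise.

## Known limitations

* The cascade is deterministic hard filtering; no FDR or significance
  attaches to the candidate list, mirroring the depth-ranking rationale.
* Indels are not left-normalised; inputs are assumed normalised by the
  caller. Multi-allelic records are scored jointly, never split.
* The score-table surrogate for control departure is weaker than the
  genotype + read-count predicate the full pipeline applies.
* The scanner reports perfect runs only; interrupted microsatellites are
  invisible to the confirmation stage.
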