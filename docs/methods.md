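# Methods

## Scope and model

`svunify` addresses deletion detection from short-read whole-genome
sequencing, where no single calling algorithm covers the full size range.
The package does not run any caller; it integrates *call sets* (VCF or BED)
and provides the simulation/emulation apparatus needed to calibrate and
validate the integration with known ground truth. Internally every span is
a 0-based half-open interval (BED convention); VCF's 1-based padding-base
records are converted at the I/O boundary and nowhere else. A 1-bp deletion
is a length-1 interval; zero-length intervals are invalid.

## Evaluation metric

A called deletion *a* and a prepared (truth) deletion *b* are compared
through their **effective regions**: the actual spans extended by a margin
*m* on both sides (clamped at the contig edges when a contig length is
supplied). The pair quality is the Jaccard index

    q(a, b) = |eff(a) ∩ eff(b)| / |eff(a) ∪ eff(b)|  ∈ [0, 1].

The margin absorbs small breakpoint deviations, which are expected where
mapping is ambiguous (interspersed repeats, low-complexity sequence). With
the default *m* = 50 bp, a 1-bp call placed 10 bp from a 1-bp truth scores
91/111 ≈ 0.82; the margin's influence decays with event size and is < 0.01
by 100 kb (asserted in the tests). *q* is symmetric and translation
invariant away from position 0.

Per size bin, **precision** is the mean over calls in the bin of each
call's best quality against *any* truth deletion (any size); **recall**
mirrors this over truth deletions. Matching is independent per record — a
single truth may be the best match of several calls — so no assignment
problem is solved, exactly as the per-record max-sum formulas require.
Insertion truth records are excluded from deletion evaluation, and
`quality` rejects them outright. The **F-measure** is the harmonic mean,
defined as 0 when precision = recall = 0. Bins with an empty denominator
report the statistic as missing (`NA` in the TSV), not 0, so plots skip
them.

The per-call max is computed with per-contig interval trees over effective
regions. Restricting the max to tree hits is exact, not approximate: a
truth whose effective region does not intersect the call's has q = 0, which
can only be the max when all qualities are 0, and 0 is then returned
anyway. The brute-force all-pairs oracle in the test suite checks this
equivalence on random instances.

Default size bins are decade-edged, {1, 10, 100, 10³, 10⁴, 10⁵, 10⁶},
matching the log-scale size axes standard in SV benchmarking; the scheme is
configurable and a bin scheme must tile its range without gaps. Sizes
outside the scheme are ignored in binned reports. Ties in the per-record
max need no tie-break: only the value enters the sum.

## Filtering and merging

`FilterSpec` maps each caller to an inclusive size range; calls outside
their caller's range are dropped, and a call from an unlisted caller is an
error unless `allow_unlisted` is set (silent passing of an uncalibrated
caller would defeat the purpose). Default ranges reflect where each
algorithm family holds >90% precision: HC 1–100 bp, Pindel 100–30,000 bp,
BD 1,000–1,000,000 bp. These are calibration defaults, fully overridable in
the `[filter]` config section.

Merging pools the filtered call sets and removes duplicated entries. Two
calls are duplicates when they overlap **each other** by strictly more than
`overlap_fraction` (default 2/3) of *both* called regions — the reciprocal
reading, matching the BEDTools reciprocal-overlap idiom; an `either`-sided
mode is available via `reciprocal = false`. Of a duplicated pair, the call
with the lower precision prior is discarded. Priors come from a
`PrecisionProfile` (per caller, per size bin; the package defaults are
HC 0.97 at 1–100 bp, Pindel 0.95 at 100 bp–30 kb, BD 0.93 at 1 kb–1 Mb,
with default 0.0 — plausible simulation-calibration values, configurable
through `[merge] precision_table`). The surviving call's coordinates are
never adjusted; duplicates are removed, not averaged.

Determinism: candidate pairs are processed in a fixed order (largest
overlap first, then coordinates); a discarded call takes part in no further
comparisons; precision ties are broken by caller priority (default
HC > Pindel > BD — the lower-size specialist wins), then smaller start,
then larger size. The pooled input is canonically sorted first, so the
result is invariant to the order in which call sets are supplied. The
merged output provably contains no duplicated pair (if both members of an
enumerated pair survived, the pair would have been processed), merging is
idempotent, and a brute-force fixed-point oracle checks equivalence in the
tests. Calls on different contigs never interact.

## Simulator

`inject_svs` places `n_sv` events at positions uniform over the reference,
rejecting placements that would overlap a previous event (with a 1-bp
guard), cross a contig boundary, or land in an N-run; it fails with advice
after a bounded number of rejections rather than looping forever. Deletions
remove their span; insertions add a random A/C/G/T string after a 1-bp
anchor. Truth coordinates are *reference* coordinates, because caller
output is mapped back against the original reference. Events are
non-overlapping and homozygous (one haplotype) — overlapping or
heterozygous events would make truth sizes ill-defined and are out of
scope.

SV sizes default to a synthetic mixture over [1, 10⁶) bp: 60% log-uniform,
25% Normal(300, 30), 15% Normal(6000, 600), rounded and clamped. The two
Gaussian components emulate the Alu and LINE peaks that dominate human
deletion spectra; the weights are a declared stand-in, not an empirical
fit, and any empirical spectrum can be supplied as a `size_table` of
(size, weight) rows, which replaces the mixture entirely.

`simulate_reads` emits FR-oriented 100-bp read pairs at the requested fold
coverage: the pair count is `round(depth · genome_length / (2 ·
read_length))`, allocated across contigs by a length-weighted multinomial
(so the total is exact). Fragment lengths are Normal(350, 50), rounded,
redrawn while below 2·read_length (clamped after 100 redraws) and capped at
the contig length; starts are uniform given the fragment fits. Each base is
substituted with probability `error_rate` (default 0.001) to a uniformly
chosen *different* base, so every substitution is detectable and the
observed mismatch rate estimates `error_rate` directly. Base qualities are
constant; read names encode the true fragment coordinates
(`frag:contig:start-end:index`) for debugging and for the statistical
tests. Note the redraw rule makes the insert distribution a truncated
normal; at the defaults the truncation moves the mean by +0.22 bp and the
sd to 49.67 bp, which is resolvable at ~10⁵ pairs — the tests therefore
check the empirical moments against the truncated-normal values.

Contigs shorter than one fragment are skipped with a warning. Reads are
emitted for any external mapper; the in-repo pipeline consumes call sets,
not alignments, so no SAM/BAM handling exists here.

## Caller emulator

Real callers are out of scope, so end-to-end testing uses a generative
stand-in: each truth deletion is emitted with a per-size-bin probability
(`recall_by_bin`), its start and size jittered by rounded Gaussians; false
calls are Poisson-placed per bin at `fp_per_mb`, with sizes uniform within
the bin so per-bin counts are controllable independently. False calls are
rejection-sampled to keep a 100-bp guard (twice the default margin) from
every truth span: a "false" call overlapping a truth would not be false,
and uncontrolled accidental matches would make the configured per-bin
precision unrecoverable. With zero jitter and false-call rate λ per bin,
the evaluated call set has per-bin precision ≈ TP/(TP+FP) and recall ≈ the
configured probability — the parameter-recovery property that validates the
whole metric stack in the tests.

`emulate_depth_series` produces a coverage series (default reference depth
30×) in which the miss probability and false-call rate scale with
`reference_depth / depth` and the jitter sd with its square root. All
depths share one set of random draws (common random numbers): a truth
detected at depth *d* is detected at every higher depth, and the false-call
pool is generated once at the noisiest depth and thinned as depth grows.
Per-bin precision, recall and F-measure are then non-decreasing in depth by
construction — the qualitative shape expected of evidence-consuming
callers — rather than only in expectation; an uncoupled series would
violate monotonicity by sampling noise.

## Pipeline, configuration, reproducibility

`run_end_to_end` chains simulate → emulate (per caller) → filter → merge →
evaluate, writing all artifacts under one run directory plus a JSON
manifest (tool version, seed, per-stage seed labels, config snapshot,
SHA-256 of every output). A single global seed feeds stage-name-salted
generators (`stage_rng`), so adding a stage never shifts another stage's
stream, and rerunning a config + seed reproduces the deterministic outputs
byte-identically. Any stage failure is re-raised as `StageError` naming the
stage. No subcommand mutates its inputs.

Default scaled-down problem sizes (5-Mb reference, 300 SVs capped at
100 kb, three emulated callers) keep a full run around a second while
populating five of the six size bins; all sizes are configurable, and the
acceptance-style tests use a 5-Mb genome with 500 deletions and a
size spectrum chosen to fill every evaluated bin.

## Known limitations

- Only deletions are filtered/merged/evaluated; insertions exist in the
  simulator truth (and are correctly ignored downstream) but are not
  called. Inversions, duplications and translocations are out of scope.
- The emulator models per-size recall, false calls and breakpoint jitter,
  not mapping artifacts, repeat-context error, or caller-specific
  biases — conclusions from emulated runs are about the integration
  machinery, not about any real caller.
- Native BreakDancer/Pindel text outputs are not parsed; convert to
  VCF/BED first. Contig names are never normalized.
- The simulator is haploid/homozygous, with substitution errors only (no
  indel errors, quality profiles, or PCR duplicates).
- Symbolic-VCF writing places a padding base before the deleted span and
  therefore cannot represent a deletion starting at position 0 exactly.
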