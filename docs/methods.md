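# Methods

`pufascreen` reimplements, as a tested pipeline, a two-arm analysis for
mapping the amino-acid positions that make *Drosophila* TRPL (and TRPγ)
channels activatable by polyunsaturated fatty acids (PUFAs) while the
paralogous TRP channel is not: a differential paralog-conservation screen
over sequence alignments, and a ratiometric Fura-2 calcium-imaging
quantification of mutant constructs, joined by a membrane-topology mapper.
This note documents the models, the parameters that matter, and the design
choices made where the protocol leaves the definition open.

## Differential paralog-conservation screen

Given an alignment of the three TRPC-subfamily paralogs (optionally across
many insect species), a column is a **candidate specificity-determining
position** iff

1. every sequence of the sensitive group (TRPL, TRPγ) carries one identical
   non-gap residue, and
2. every sequence of the insensitive paralog (TRP) carries a residue
   different from it.

Comparison is case-insensitive exact identity — the rule is about identity,
not physico-chemical similarity, so no substitution matrix is involved.
Gap handling follows from reading the rule over residues present in the
sensitive channels: a gap in the insensitive group counts as "different"
(the residue is physically absent there), while a gap anywhere in the
sensitive group disqualifies the column.  Columns are numbered by the
designated reference sequence (TRPL numbering by convention): the *k*-th
non-gap reference column is position *k* (1-based); columns gapped in the
reference carry no residue number and are skipped.

### Region filtering

Candidates are labelled (never dropped) against the channel topology:

* `excluded_pore` — inside the pore-proximity interval (default 595–670 in
  the shipped topology); pore-proximal substitutions confound gating with
  permeation and serve as negative controls rather than candidates;
* `excluded_distal` — in the distal C-terminus, which is excluded because of
  its role in channel multimerization;
* `outside_window` — outside the analysis window, by default from 10
  residues before S1 to the end of the proximal C-terminus (365–800 with the
  shipped topology);
* `candidate` — everything else.

Precedence is pore → distal → window → candidate, so the label partition is
exhaustive and counts always conserve the candidate total.

### Cross-species conservation profile

For each position the profiler reports, per paralog group, the consensus
residue (most frequent non-gap residue; ties broken alphabetically) and the
fraction of group sequences carrying it (gapped sequences count in the
denominator).  Classes: `fully_conserved_both_groups` iff both fractions
equal 1.0 with distinct group consensus residues; `partially_conserved` iff
both fractions reach the `partial` threshold (default 0.7); otherwise
`not_conserved`.  The four-colour conservation display this emulates is not
numerically defined anywhere, so the thresholds are explicit configuration
with these stated defaults.  Positions that do not map into an ortholog
alignment are reported per-position with an error rather than aborting the
profile.

## Topology mapping

A topology annotation is an ordered, gap-free partition of the reference
span into 14 closed 1-based intervals (N-term, S1…S6 with linkers, pore,
proximal and distal C-terminus).  Exact helix boundary residues for TRPL
are not published; the shipped `trpl_topology.json` is therefore a
**calibrated fixture** — boundaries chosen once so that every printed
per-position statement holds (positions 438–522 fall in the S2–S4 span with
465/471 in S3, 631 in the pore, 742–794 in the proximal C-terminus, 833
distal) — and is labelled as such in the file and fully overridable.
Position sets are summarized per region plus two aggregate flags: the S2–S4
span (S2 through S4 including linkers) and the proximal C-terminus.

## Calcium-imaging quantification

The pipeline starts from per-cell two-channel fluorescence series (excitation
340/380 nm, arbitrary units) plus one no-cell background ROI per recording
and a per-cell YFP expression-marker intensity.

1. **Ratio.** `R(t) = (F340(t) − bg340(t)) / (F380(t) − bg380(t))`.
   Timepoints with corrected F380 ≤ ε (default 10⁻⁶) are flagged invalid and
   excluded from feature windows; cells with no valid timepoint are dropped
   with a log entry.  The ratio is invariant to common scaling of both
   channels and backgrounds (illumination intensity), which is tested as a
   property.
2. **Expression gating.** Cells whose YFP lies in the construct's
   20th–80th percentile window (default; an absolute window is available)
   are retained, emulating selection of a defined range of expression
   levels.  Fewer than `min_cells` (default 60) survivors is a QC warning,
   not an error, so small test fixtures remain processable; zero survivors
   is an error.
3. **Amplitude.** The recordings show sustained plateau responses but no
   published amplitude operator, so one had to be defined: baseline = mean
   ratio over `[t_stim − 60 s, t_stim)`; response = maximum of a 5-point
   centered moving-median-smoothed ratio over `(t_stim, end]`; amplitude =
   response − baseline.  The median filter makes the extremum robust to
   single-frame artefacts; a `plateau_mean` mode (mean instead of maximum,
   unbiased under the null) is available, with `peak` the default.  Cells
   with fewer than 3 valid points in either window are excluded with a
   recorded reason.  Amplitudes may be negative and are *not* floored at
   zero, so null constructs stay unbiased.
4. **Construct statistics** (`PufaResponseModel.fit()` →
   `PufaScreenResults`): per construct and ligand, mean amplitude ± SEM
   (sd/√n, cells pooled per construct), the WT-normalized percentage
   (`100 × mean / WT mean`; the WT is 100 exactly by construction, and
   normalization against a non-positive WT mean is refused), and a
   two-sided unpaired t test against WT — pooled-variance by default,
   matching the era's default in desktop statistics software, with Welch
   available via `equal_var=False`.  Zero variance in both samples with
   equal means gives p = 1 by convention.  Significance is flagged at
   p ≤ 0.05 inclusive; no multiple-testing correction is applied by default
   (none was applied in the emulated protocol).
5. **Classification.** A construct is *required for PUFA activation* iff its
   reduction `100 − normalized%` strictly exceeds the threshold (default
   50%).  "More than 50%" is read literally: a reduction of exactly 50% is
   not called.
6. **Ligand discrimination.** For constructs measured under both agonists,
   the score is `normalized%(ETI) − normalized%(ETYA)` in percentage
   points; a construct *discriminates* iff the difference ≥ 30 points
   (configurable) and the ETYA response is lost (reduction > 50%) while the
   ETI response is retained (reduction ≤ 50%).  The qualitative published
   criteria ("blunted under ETYA, fully responsive to ETI") are made
   explicit by these thresholds.

`run_screen_report` drives the chain end to end, parses positions out of
single-mutant labels (`F467Y` → 467), joins them onto the topology, and
tabulates required positions, per-region counts and the discriminating set.

## Synthetic data generator

The generator defines the study conditions under which everything is
tested; it emulates the structure of the real data, not its biophysics.

**Alignments.**  An ancestor sequence of i.i.d. residues is copied into
`n_species × paralogs` descendants.  Planted differential positions are held
fixed — one residue across the sensitive group, a distinct one across the
insensitive paralog — and all other (non-frozen) sites substitute
independently per terminal lineage with probability
`per_site_substitution_rate` (star phylogeny; no indels, so column *i* is
position *i*+1).  At rate 0 the screen must recover the planted set exactly;
at positive rates the screen is validated against an independent brute-force
column scan rather than the planted truth, since substitutions can in
principle create or destroy differential columns.

**Traces.**  Per cell, the true ratio is `baseline_ratio` (default 1.0)
until the stimulus and, for responder cells, rises linearly over
`rise_time` (default 30 s) to a sustained plateau `wt_delta_ratio ×
amplitude_scale` above baseline (WT delta default 0.8 ratio units) — the
simplest kinetic whose peak equals the configured amplitude.  F380 is a
constant cellular signal (200 a.u.), F340 = ratio × F380; both measured
channels add a constant channel-specific background (default 10 a.u., 5% of
the cellular signal) and i.i.d. Gaussian noise (default sd 2 a.u., ~1% of
signal).  Responder status is per-cell Bernoulli (default fraction 0.9);
YFP intensities are log-normal so gating has a distribution to gate on.
Recordings run 0–360 s sampled every 2 s with the stimulus at 60 s,
annotated with the 40 µM supramaximal ligand application.  Per-cell
response variance and responder fractions are not reported for the real
experiments; these defaults are stated assumptions, not measured values.
All randomness flows from the config's single seed (NumPy PCG64); identical
configs give byte-identical outputs.

Not emulated: microscope images, photobleaching, Fura-2 saturation or
calibration to absolute [Ca²⁺], channel cross-talk between F340 and F380
(real calcium rises move both channels in opposite directions; here F380 is
flat), coverslip-to-coverslip batch effects, and any dependence of response
on expression level.  Passing tests therefore validate the quantification
arithmetic and decision rules, not robustness to those real-data features.

**Calibrated fixture bundle** (`pufascreen.fixtures`).  Four trace panels
plus one alignment, with per-construct amplitude scales fixed once against
the printed per-construct statements: the 18 known sensitivity positions at
scales 0.02–0.40 of WT (N522M, which lacked any response, at 0.02), the 16
tolerated single mutants at 0.70–1.25 (V766I, which over-responded, at
1.25); 15 stretch mutants with the four excluded ones above 0.5; TRP
variants at 0.02/0.20/0.20/0.40 of TRPL-WT; and the 13-mutant two-ligand
panel where only I465V (1.0) and S471M (0.9) retain their ETI scale.  The
alignment plants the 50 candidate positions (all mutated positions, the
five pore-proximal and one distal exclusions, and the extra stretch-mutant
positions) across 3 paralogs × 10 insect species at substitution rate 0.01.
The bundle manifest records every generator parameter, derived seed and
file checksum; identical seeds reproduce identical checksums.  The
characterized single-mutant list is shipped as 34 constructs.

## Numerical and statistical notes

* One background ROI per recording means background noise is shared across
  that recording's cells, so per-cell amplitudes within a recording are
  positively correlated; null-behaviour checks are therefore run across
  independent recordings, not across cells of one recording.
* The post-stimulus maximum of a smoothed noisy trace is biased upward by a
  few times the smoothed noise sd (~0.01–0.02 ratio units at default noise).
  The bias enters numerator and denominator of the WT normalization alike,
  leaving low-amplitude constructs reading ~2–3 percentage points above
  their generating scale — visible in the worked examples and well inside
  the ±5-point recovery tolerance; `plateau_mean` avoids it at the cost of
  sensitivity to slow drift.
* Normalized percentages of a single recording inherit the Bernoulli
  responder sampling noise of both the construct and the WT (~2–4 points sd
  at 120 gated cells); recovery checks and the acceptance script therefore
  average a handful of independent recordings (5 in the script) and state
  the across-recording mean.
* Problem sizes: trace panels use 200 cells per construct (120 after
  default gating), 181 timepoints per cell; the brute-force screen
  equivalence suite runs 1000 random alignments of ≤ 20 columns.  These
  sizes keep the whole suite and the acceptance script in the tens of
  seconds on one CPU while leaving comfortable statistical margins.

## Known limitations

* The screen is identity-based; it cannot rank near-conservative
  substitutions or weight by physico-chemical similarity.
* The topology is a calibrated stand-in, validated only against the printed
  per-position statements; region counts depend on it and any user-supplied
  topology overrides it.
* The 50-candidate total from the alignment arm depends on alignment and
  window boundaries; the fixture reproduces it by construction, and the
  number should not be read as independently derived.
* The generator's star phylogeny has no shared internal branches, so
  cross-species conservation fractions on synthetic panels are not
  phylogenetically realistic — adequate for testing the tally, not for
  evolutionary inference.
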