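# Methods

This note documents the models and procedures behind `pupalyze`: what the
synthetic-data generator emulates and deliberately does not, the analysis
definitions and their numerical conventions, the parameters that matter,
and the design choices made where the design was genuinely open.

## The behavioral model

Pupal ecdysis is treated as a four-phase motor sequence executed by a
fixed hemisegmental muscle roster (abdominal segments A1–A7, left and
right, with muscles tagged dorsal/lateral/ventral and — at the A4/A5
boundary — anterior/posterior; M12 and M5 are absent from posterior
segments). The behavioral hierarchy has four levels:

1. **Muscles** — individual activation events with onset/offset frames
   (half-open, 0-based) at 2 Hz.
2. **Syllables** — pupal muscle ensembles (PMEs; sets of ≥ 2 muscles
   reliably co-active ≥ 3 consecutive frames) and reliably
   movement-associated single muscles.
3. **Movements** — the eight canonical actions (Lift, RollCon, Swing,
   Brace, Crunch, AntComp, PostCon, PostSwing), each drawing on a fixed
   syllable vocabulary and carrying a propagation direction along the
   body axis.
4. **Phases** — P0 (stochastic twitching), P1 (Lift/RollCon), P2
   (Swing/Brace), P3 (compartmentalized blocks), executed as bouts
   separated by rests.

PME1–PME4 memberships follow published anatomy (PME1 = M8/M13/M26,
PME2 = M21–M23, PME3 = M2/M3, PME4 = M1–M3; PME3 is genuinely nested in
PME4). **PME5–PME8 memberships are not anatomically established**; the
defaults ({M5,M9}, {M9,M10}, {M5,M10}, {M8,M21}) are synthetic
placeholders, flagged as such in `syllabary.py`, and configurable.

## The synthetic generator

`simulate_recording` plants bouts per phase; each bout realizes its
movements' syllable vocabularies and emits an event table, per-muscle-cell
ΔF/F traces, and a `GroundTruth` (phase intervals, bout boundaries,
planted catalog, recruitment orders, frame-wise movement labels).

**Compartmental program with variable recruitment.** A movement executes
its syllables in a fixed compartmental stage order (ventral → dorsal →
lateral), while the order of syllables *within* a stage is permuted anew
every bout, and every occurrence's onset receives integer Gaussian jitter
(`recruitment_jitter_sd`, default 3 frames — comparable to the 3-frame
inter-syllable stagger, consistent with the low muscle-order similarity
the method is designed to detect). Occurrences march through segments
along the movement's direction (row 0 = anterior), so the anatomical wave
is organized even when recruitment order is not. This separation is what
produces the characteristic stereotypy hierarchy: compartment order ≥
syllable order ≥ muscle order. At `recruitment_jitter_sd = 0` the
permutation is disabled too, giving the fully stereotyped limit (pairwise
similarity exactly 1.0), which tests rely on.

**Ensemble realization.** PME members share their occurrence's onset up
to ± `within_ensemble_jitter` frames (default 1); with the default
5-frame event duration this guarantees ≥ 3 frames of common overlap, the
detection window. Perturbation modes deliberately violate this
(member-staggered "desynchronized" ensembles).

**Idiosyncratic activity.** A binomial number of off-syllable activations
(expected fraction = `idiosyncratic_rate`, default 0.1) is injected per
bout, drawn from roster muscles that are not single-muscle syllables and
placed so the activation cannot be mistaken for ensemble membership (no
overlap with same-muscle activity; < 3 frames of overlap with the joint
activity of all other members of any shared ensemble). This makes the
annotated off-syllable fraction an unbiased readout of the planted rate.

**Bout integrity.** After jitter, an order-preserving "gap repair" pulls
onsets together so no intra-bout onset-free gap reaches the 2-frame bout
criterion; planted bout boundaries are therefore exactly recoverable by
the segmentation rule at any jitter level. Inter-bout rests are log-normal
(medians 15–30 frames per phase). P2 carries the least duration noise
(lowest tempo/interbout sigmas, recruitment jitter halved): its execution
is modeled as the most tightly regulated phase, and its duration CVs come
out lowest.

**Kinetics and movies.** Traces are sums of instant-rise,
exponential-decay kernels (τ = 6 frames ≈ 3 s at 2 Hz, GCaMP6s-like) with
amplitude equal to the event's planted ΔF/F, plus Gaussian noise. Movies
paint each cell's trace into its rectangular hemisegment ROI
(`background + gain · ΔF/F`), 16-bit multi-page TIFF, rows anterior→
posterior.

**Mechanics.** Per contraction, (ΔF/F %, ΔL/L %) are bivariate normal
with correlation −0.54 (the reported coupling strength, used as the
emulated structure), phase-dependent shortening means (P0 ≈ 15 %, P1–P3
≈ 30–35 %), and an extra posterior > anterior shortening gradient
(+5 %/segment) for the lateral transverse muscles. Note the *pooled*
correlation across phases attenuates to ≈ −0.43 because between-phase
mean differences add variance uncorrelated with ΔF/F; restricted to the
measurement protocol (hemisegments A3–A5, ecdysis phases) it is ≈ −0.52.

**Perturbation modes** reproduce the silencing phenotypes:
`ethrb_suppressed` removes Lifts and all M1/M15 activity from P1 and
desynchronizes PME1; `ccap_suppressed` truncates the recording after P1
with a single partial swing confined to posterior segments and
D-V-desynchronized; `burs_suppressed` yields one full-length
desynchronized swing plus sparse P3-like movements; `class1da_suppressed`
makes P0 sustained and widespread and terminates before P1. These
contracts hold for every seed (tested over 20).

**What the generator does not emulate:** real optics (motion,
photobleaching, occlusion, scattering), hydrostatics and body-wall
deformation, per-hemisegment simultaneous ensemble activity (each
syllable occurrence occupies one hemisegment), tracheal dynamics, or head
eversion. Passing tests therefore demonstrate correctness of the
*analyses* under the assumed statistical structure, not performance on
raw imaging data.

## Analysis definitions and numerical choices

- **ΔF/F**: (F − F₀)/F₀ with F₀ the mean of the first 50 frames; F₀ = 0
  raises a degenerate-baseline error. Per-contraction ΔF/F instead uses
  the onset value as baseline.
- **Peak detection**: local maxima above threshold with a minimum
  separation; the default threshold is 3 × MAD above a 200-frame running
  median (published recordings used unpublished manual thresholds), fully
  configurable.
- **Peak coupling**: Pearson r of binarized peak indicator vectors,
  optionally dilated ± a tolerance; a constant indicator raises an
  undefined-statistic error rather than returning a number.
- **Bouts**: maximal runs of onset-bearing frames flanked by ≥ 2
  onset-free frames, on onsets only (an event may stay above baseline
  across a gap). CV uses the sample SD (n−1).
- **Co-activity**: a muscle set qualifies in a bout when all members are
  simultaneously active for ≥ 3 consecutive frames, read as a common
  interval (the stricter interpretation) rather than pairwise-chained
  overlap. Within a bout, a maximal co-active set suppresses its subsets
  over overlapping intervals.
- **PME discovery**: candidate sets are maximal co-active sets; support
  counts a set in every unit where its members are co-active ≥ 3 frames;
  retention needs support ≥ 80 % of units in ≥ 80 % of animals. A
  retained strict subset of another retained set must show *independent
  evidence*: it is kept only if co-active in ≥ half of the pooled units
  where the superset is not. This keeps genuinely nested ensembles (the
  PME3 ⊂ PME4 case) while pruning subsets that merely ride along. The
  support unit (bouts vs movements) is a parameter, default bouts.
- **Annotation**: PME occurrences are maximal runs of joint member
  activity ≥ 3 frames; larger ensembles claim activations first, so a
  nested ensemble's phantom occurrence inside a superset window annotates
  nothing; an activation joins an occurrence only with ≥ 3 frames of
  overlap with its co-active window. Each activation is assigned at most
  once; the unassigned fraction is the off-syllable measure.
- **Gestalt similarity**: `difflib.SequenceMatcher` with junk heuristics
  disabled — ratio 2M/T via recursive longest-common-block matching, ties
  broken by earliest start in the first then the second sequence. The
  score is a pure function of the *ordered* pair; it is provably
  order-dependent for some pairs (e.g. ("A","B") vs ("B","A","C","B")),
  so sequences are always compared in a fixed order. Verified exactly
  against an independent brute-force implementation on the exhaustive
  suite of all ordered pairs of length ≤ 6 over a 3-token alphabet.
- **Sequence levels**: muscle sequences order all activations by (onset,
  natural label collation — M2 < M12); syllable sequences order annotated
  syllable events; compartment sequences order contiguous activation runs
  of the six D-V × A-P compartments, holding a compartment "on" for 4
  frames past event offsets (indicator decay) and requiring ≥ 2
  contributing muscles per run — a lone stray twitch is not a
  compartment-level activation.
- **Permutation null**: each permutation independently reorders every
  sequence's own tokens; p = (1 + #{null means ≥ observed})/(n_perm + 1).
- **Directionality**: per-frame column-MIP profiles; the mode is the
  argmax row (ties → lowest index), frames below an activity floor are
  excluded. The default decision rule is a Theil–Sen fit of mode row vs
  frame (negative slope = posterior-to-anterior); the historical
  mode-count-ratio rule is retained as `method="mode_ratio"` but is
  near-degenerate by construction (counts around a median balance) and is
  not the default. Whole-bout calls on bouts mixing opposite-direction
  movements (P2's Swing + Brace) are genuinely ambiguous — a known
  limitation; single-movement windows disambiguate.
- **Mechanics**: ΔL/L = 100·(L_onset − L_min)/L_onset at the
  minimum-length frame (anchor configurable to the peak-fluorescence
  frame); lengthening events are flagged, not clipped. The
  fluorescence–shortening correlation is reported under both sign codings
  (vs positive shortening, and vs signed length change).
- **Classifier**: 25-frame sliding windows (12 + center + 12) labeled by
  the center frame, nine classes; features are block-mean-pooled,
  time-strided, per-window standardized pixels; the model is a small MLP
  trained epoch-wise with Adam on categorical cross-entropy, early-stopped
  when an animal-held-out validation loss fails to improve for `patience`
  (default 10) epochs, best weights restored. Edge frames take the
  nearest valid window's prediction. The architecture is a desk-scale
  substitution; the windowing, loss, early stopping, and per-frame argmax
  decoding are the contract. For chance-level controls the
  calibration-free statistic is balanced accuracy (macro recall), whose
  chance level is exactly 1/9 under any class imbalance.

## Problem sizes used in the validation suite

The test and acceptance runs use desk-scale cohorts chosen to make each
property statistically decisive: ensemble recovery uses 10 animals × 20
bouts with planted support 0.9 (a per-bout inclusion quota, so recovery
is a property of the rules, not of binomial luck) over 20 seeds; the
jitter sweep uses 50 seeds per level; level ordering 20 seeds × 2
animals; directionality 100 rendered wave movies with pixel noise up to a
third of the signal amplitude; the classifier benchmark 4 animals of
~400-frame movies at 28 × 28 px.

## Known limitations

- The generator's hemisegment occupancy is one segment per syllable
  occurrence; segment-resolved analyses (e.g. the shortening gradient)
  therefore sample mid-segments sparsely within any single movement.
- Compartment-level and idiosyncratic structure are stylized; the
  sub-threshold (≥ 2 muscles) compartment rule and the capture-avoiding
  idiosyncratic placement are generator/analysis conventions, stated
  here, not measured properties of real pupae.
- The figshare-deposited annotations of the original study are not
  bundled; `read_events` with a column map is the supported path for
  analyzing them.
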