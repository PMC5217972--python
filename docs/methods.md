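# Methods

`pacwave` models, simulates and infers the packaging of bacterial DNA by a
temperate phage whose genome occasionally recombines into the host
chromosome at the att site during productive replication. This note
records the model, its assumptions, the estimators, the numerical choices,
and what the synthetic data do and do not establish.

## The packaging model

A phage of genome length `L_p` packages DNA by the headful mechanism: a
terminase recognises a *pac* site, makes a first cut, and fills each
capsid with a fixed length

    H = round(L_p * (1 + r))

where `r` is the terminal redundancy (default `r = 0.10`, so
`H = 71,664` bp for the 65,149-bp genome modelled here). Packaging is
processive: after each completed headful the machinery continues with
probability `1 - 1/m`, giving a geometric series-length law

    P(k headfuls) = (1/m) (1 - 1/m)^(k-1),   k = 1, 2, ...

with mean `m` (default 3). The geometric law is the minimal one-parameter
choice consistent with a mean of ~3 and an observed tail of 10–12
headfuls: under it `P(k >= 11) = (2/3)^10 ≈ 0.017`.

Three packaging substrates are modelled:

* **Episomal** (the usual case): an unbounded concatemer of the phage
  circle. Molecules are circularly permuted and terminally redundant;
  successive headful starts drift by `H mod L_p ≈ 0.1 L_p` around the
  circle, which over-represents the region downstream of *pac* and puts
  the coverage maximum there.
* **Integrated**: with probability `f_int` a series initiates on a phage
  copy recombined into the host chromosome at the att core (Campbell
  crossover, reverse orientation by default — see below). The first
  headful contains `d` bp of phage (`d` = distance from the pac cut to
  the attL junction along the packaging walk; 39,250 bp at the default
  geometry) plus `H - d` bp of host; headfuls 2, 3, ... are pure host
  DNA from one flank. This is the att-linked, lateral-transduction-like
  mode the package exists to analyse.
* **Background**: with probability `bg_rate` a series instead packages a
  single uniformly positioned host fragment of length `H` — classical
  generalized transduction, producing the flat coverage floor.

The first cut position carries Normal(0, `pac_jitter_sd`) jitter
(default sd 2 kb, truncated at ±3 sd), reflecting imprecise cleavage
initiation; all boundaries of one series shift coherently with its first
cut. Every headful is complete: capsids fill fully, series end only at
headful boundaries.

### Orientation and geometry

The att core (17 bp, `TGGTGCGGACGGAGAGA`) occurs once in each frame. The
prophage sits in **reverse** orientation relative to the host by default:
the phage is reverse-complemented before Campbell crossover. With that
orientation, walking from the pac cut toward the attL junction traverses
`(attP - pac) mod L_p = 62,750 - 23,500 = 39,250` bp of phage, and the
packaged host DNA extends into the **left** flank of attB — so hybrid
junction reads are all attL-type. A forward-orientation flag produces the
mirrored geometry. Coordinates are 0-based half-open everywhere; circular
frames use arithmetic modulo length; the attL core copy is attributed to
the host frame and the attR copy to the phage frame (the core is
identical in all frames and carries no origin information).

### What the generator emulates — and what it does not

Emulated: att-site integration during replication, processive headful
series with jittered initiation, circular permutation/terminal redundancy
of episomal genomes, a uniform generalized-transduction floor, paired-end
sequencing (900 ± 100 bp fragments, 250-bp mates, substitution errors at
0.1%, constant Phred-40 qualities).

Not emulated: replication kinetics and copy-number gradients, burst-size
variation, indels and quality-dependent errors, GC-coverage bias,
chimeric library artefacts, partial capsids, excision-defective
(P22-like) prophage packaging, and packaging-in-trans of mobile elements.
Passing tests therefore demonstrate correctness of the inference on the
mechanistic model, not robustness to every artefact of real libraries;
the SAM input path exists so real alignments can replace the internal
mapper.

### Condition presets

The induction and infection presets set (`f_int`, `bg_rate`) =
(0.018, 0.022) and (0.0054, 0.0049). These are calibrated from the
closed-form expectation of the packaged host-base fraction,

    E[host] / E[total] = [b H + (1-b) f (mH - d)] / [b H + (1-b) m H],

so that the presets reproduce the observed burdens: ~2.2% packaged host
DNA with ~67% of it att-linked after prophage induction, and ~0.6% with
~73% att-linked after lytic infection. The two conditions differ in how
often packaging initiates on an integrated copy (about three-fold) and in
their background rate.

## Read classification

Reads are classified against the two frames by exact canonical k-mer
seeding (k = 31; sorted uint64 code array queried with binary search; in
batch mode every 4th k-mer is seeded, which is lossless for anchors of at
least `stride + k - 1 = 34` matching bases) followed by ungapped
verification of each (frame, strand, diagonal) chain over the whole read.
Matches in runs shorter than 8 bases are discarded as chance identity
(random sequence matches ~25% of positions); anchors count matched bases
outside the att core. A read is:

* **hybrid-left / hybrid-right** — host and phage anchors both ≥
  `min_anchor` (default 20 bp, chosen to exceed the 17-bp core) on
  opposite sides of the core; the side is the host flank the host anchor
  occupies;
* **phage / host** — one frame only; a read whose matches stop at the
  core boundary while ≥ 7 bases continue unmatched is *ambiguous* rather
  than a clean single-frame read (it is a junction whose second anchor is
  sub-threshold);
* **ambiguous** — conflicting or sub-anchor placements (including
  equal-best multi-mappers);
* **unmapped** — no alignment.

Mates are classified independently; the classifier is an idealisation for
low-error reads, which is exactly what the simulator produces.

## Inference

All estimators work on 1-kb-binned mean depth (so values read directly as
fold-coverage). The host-flank profile left of attB is the primary
object; with geometric continuation its expected shape is a staircase
with plateau ratios `(1 - 1/m)^(j-1)` and step spacing `H`.

* **Background**: median of per-bin depth outside an exclusion zone
  around attB (1 Mb on the packaging side, 50 kb on the other), after
  pooling 5 consecutive bins — the raw per-bin median at a few reads per
  bin is biased low by count quantisation; the median keeps robustness to
  the enrichment tail.
* **Flank extent**: walk away from attB over a 15-bin moving median and
  stop after more than 3 consecutive values at or below 2× background.
  The median filter keeps short sampling dips from truncating the walk
  while leaving step edges sharp; the run rule handles longer excursions. Note the quantity is
  intrinsically knife-edged: with first-window coverage `c0` and
  background `b`, window `j` survives the threshold iff
  `c0 (2/3)^(j-1) > b`, so the estimate snaps to window boundaries
  (..., 677, 749, 821 kb at the default geometry) and the reported reach
  moves a full window when `c0/b` crosses ~58.
* **Wave period**: log(depth + 0.5) is detrended by subtracting a
  centered 100-kb moving average; the autocorrelation of the residual,
  normalised at lag 0, is maximised over lags in [20 kb, 120 kb] and the
  peak refined by quadratic interpolation. The global maximum is used
  (sampling ripples make "first local maximum" rules unstable), the upper
  lag bound excludes the 2T harmonic, and within the pipeline the span is
  clipped to the enriched flank (extent + 50 kb) because background-only
  bins only dilute the signal. No peak above autocorrelation 0.1 →
  "no period detected". Terminal redundancy follows as
  `r̂ = (T - L_p)/L_p`.
* **Processivity**: window means over successive headful-sized windows
  (the first window is the `H - d` host tail of the first headful), then
  `m̂ = Σ_j max(w_j - b, 0) / (w_1 - b)` with 12 windows. Truncation at
  zero biases `m̂` slightly upward when windows sit at background; the
  12-window cap loses `(2/3)^12 ≈ 0.8%` of the geometric mass.
* **pac position**: the phage-frame profile is circularly smoothed
  (2-kb moving average). The *maximum* sits mid-plateau — jittered
  initiation makes the over-represented region one headful-drift wide —
  so the pipeline reports the half-rise crossing on the rising side of
  the maximum ("where the maximum starts"), which is unbiased under
  symmetric jitter; both positions are exposed, with the down-slope sign
  over the following quarter genome as a consistency check.
* **Directionality**: exact two-sided binomial test at P = 0.5 on the
  (attL, attR) hybrid-read counts.

Statistics use the Wilson score interval for proportions, the uncorrected
Pearson chi-square (closed form, `p = erfc(sqrt(x/2))`) for the 2×2
condition comparison — both corrected and uncorrected variants underflow
double precision on the study-scale table, reported as "< 2.2e-16" by
convention — and the exact two-sided binomial test elsewhere.

## Problem sizes and numerical choices

Simulated checks use a 2-Mb circular host (attB at 1.2 Mb) and the
65,149-bp phage. Wave-period and directionality checks run 6,000 series
with every series integrated (the signal-concentrating regime) at ~0.06
pairs per molecule-kb (~180× first-window coverage); flank-extent checks
run 16,823 series at `f_int = 0.2`, `bg_rate = 0.0703`, ~0.05 pairs/kb,
which reproduces the induced-lysogen run's coverage scale. That scale is
calibrated from its reported read counts: 55,000 att-linked reads over the
effective flank area `mH - d = 175,742` bp give a first-window coverage
`c0 = 55,000 × 250 / 175,742 ≈ 78×`, and 26,578 background reads over a
6.26-Mb genome give `b ≈ 1.06×` — a ratio `c0/b ≈ 74`, for which the
2×-background staircase crossing sits at `δ + 10H = 749` kb. (The rounded
coverage quotes, 60–70× vs 1.3×, imply a ratio of ~50 and a crossing at
677 kb, below the 700–800-kb reach described for the same data; the
count-based calibration is internally consistent and is the one used.)
Many series at low per-series read depth, rather than few series at high
depth, match the fine granularity of a real virion population. At this
depth the threshold walk still stops 40–70 kb before the ideal crossing
(the last window sits ~14% above threshold, within sampling noise of it),
so realised extents straddle 680–710 kb across seeds.

Degenerate inputs are flagged rather than guessed at: flat phage profiles
yield no pac estimate, a flat flank yields "no period detected", zero
host reads skip the flank stages, and a zero background falls back to an
absolute 0.1× floor in the extent rule.

## Known limitations

* The flank-extent estimate quantises to window boundaries (677/749/821
  kb at the default geometry) and carries a 40–70-kb negative noise bias
  at study-scale depth; see above.
* The internal mapper assumes ungapped, low-error alignments; indel-rich
  data needs the SAM path.
* `m̂` assumes the background is position-independent across the windows.
* The closed-form host-fraction expectation assumes the host flank is
  much longer than a typical series (`m H ≪ L_h`); on toy hosts long
  series wrap back into the prophage and the realised fraction falls
  below the formula.
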