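# Methods

`pauselimit` estimates the kinetics of RNA polymerase II promoter-proximal
pausing — gene-wise elongation velocity *v*, pause site *m\**, pause
duration *d*, and productive initiation frequency *I* — from paired TT-seq
and mNET-seq coverage measured before and after acute CDK9 inhibition, and
evaluates the steric "pause-initiation limit" per gene.  This note records
the model, every tunable constant, the synthetic-data generator and its
relation to real data, the numerical choices, and known limitations.

## Kinetic model

A transcription unit (TU) is the per-gene union of annotated isoforms, with
TU-local coordinates anchored at the TSS (position 0, increasing 5'→3').
Polymerases initiate at rate *I* (cell⁻¹ min⁻¹), transcribe to a pause site
*m\** (~50–150 bp downstream of the TSS), dwell there for *d* minutes, and
— once released by CDK9 activity — elongate at velocity *v* (bp/min).

**TT-seq** reads out RNA synthesized during a short 4sU pulse
(*t_lab* = 5 min).  Acute CDK9 inhibition for *t\** = 15 min blocks pause
release, so labeled signal is lost in a 5'-proximal *response window* whose
width is *v·(t\*−t_lab)*; the fractional loss in the first 10 kbp
(excluding 200 bp) is the response ratio *r*.

**mNET-seq** maps the RNA 3'-end held by engaged polymerase; its coverage
is occupancy: *I/v* per base in the gene body plus *I·d* polymerase
equivalents at the pause.

### Estimators

All signal enters as the number of transcribed bases *tb*: the
antisense-bias-corrected (per base, `s = (S − cA)/(1 − c²)`, clamped at 0),
size-factor-scaled coverage sum over a TU-local window, averaged over
replicates.

* **Response ratio** `r = 1 − tb_inh/tb_ctrl` on [200 bp, 10 kbp), floored
  at 0 (TUs > 10 kbp, unique TSS).
* **Common velocity**: minimize
  `median_i |1 − tb_inh/tb_ctrl − r_i·v·(t*−t_lab)/L_i|` for *v* in
  [0, 10000] bp/min over TUs of 25–200 kbp (first 200 bp excluded, 5 kbp
  trimmed from the 3' end).  Minimized by a 10-bp/min grid refined by a
  unit-step scan; tests check equality with a full unit grid.
* **Gene-wise velocity**
  `v_i = (tb_ctrl − tb_inh)/(tb_ctrl·r_i) · L_i/(t*−t_lab)` for TUs
  > 35 kbp with r > 0.25.  `L_i` is the full TU length while tb is summed
  on the trimmed window, as the formula is conventionally written; this
  carries a small `L/(L − 5.2 kbp)` upward factor.
* **Response-window velocity (ratio-free)**: with `S_n` the cumulative
  per-base control−inhibited difference, the window edge maximizes
  `gain(n) = S_n·L/max(S) − n + 1` (the cumulative curve "rotated 45°");
  ties break to the smallest n (conservative window).  `v̂ = L_rw/(t*−t_lab)`.
* **Pause site**: argmax of the corrected, scaled control mNET-seq track on
  [TSS, first-exon end − 5 bp), accepted when it exceeds 5× the window
  median (zeros included); ties break 5'-most.  The same site is reused for
  the inhibited condition so the two conditions are compared in one window.
* **Initiation frequency** `I = (1/κ)·tb/(t_lab·L_exonic)` over non-first
  constitutive exons (exonic bases common to all isoforms, first exon
  excluded), where κ converts signal to RNA per cell via labeled spike-ins:
  `κ = mean_samples(median_spikes tb/(L·N))`, `N = m·N_A/(M·n)` with the
  molar mass `M` from per-nucleotide masses (329.2/306.2/305.2/345.2, 4sU
  322.26 at fraction τ = 0.1 for labeled spikes, + 159 for the
  5'-triphosphate).
* **Pause duration** `d = (Σ_±100bp p)/I · scale`, window = first 200 bp
  when m\* < 100; `scale = median_i I_i·(t*−t_lab)/Σ_rw p` over TUs above
  the median mNET response-window signal (the robustness quantile is
  applied to per-TU response-window sums).  This is the dimensional reading
  of the printed scale expression, in which v_i cancels.
* **Ratio-free pause duration** `d̂ = Σ_±100 p · L_rw/(Σ_rw p · v̂)`,
  aligned to d for display by the single constant `median(d)/median(d̂)`.
* **Pause-initiation limit**: `margin = (200 bp/(d·I))/50 bp`; margin < 1
  flags combinations requiring initiating and paused polymerase active
  sites closer than 50 bp.

### Normalization

Antisense bias *c* per sample is the median spike-in antisense/sense count
ratio.  TT-seq size factors are median-of-ratios over TUs > 125 kbp trimmed
50 kbp per side (so the CDK9 response cannot leak in); mNET-seq size
factors are anchored on non-responder TUs (r < 0.05, multi-TSS TUs
admitted).  If a cohort contains no non-responder below the threshold the
pipeline falls back to all candidate TUs with a warning rather than
aborting.  The mNET antisense bias is estimated from the same spike-in
table as TT-seq (real experiments would use unannotated genomic regions; at
the coverage contract level the two estimators are interchangeable).

## Synthetic-data generator

The generator emulates the complete experiment: TU annotations (exon/intron
structure, packed onto chromosomes with alternating strands), TT-seq and
mNET-seq bedGraph pairs for control/inhibited × 2 replicates, spike-in FASTA
and counts, a genome FASTA with a planted C at each pause site (the
conserved RNA 3'-end base), and a ground-truth JSON.

**TT-seq.**  The expected coverage profile is the exact polymerase-age
integral: a polymerase of age *s* contributes a labeled span
[τ(max(s−t_lab,0)), τ(s)) where τ integrates the piecewise-constant
velocity profile (the pause is a 1-bp segment of velocity 1/d), weighted by
the uracil-dependent labeling bias `1 − (1−p_lab)^{#u}` with
`#u = round(0.28·len)` and a logistic size-selection weight (midpoint
80 bp, scale 10 bp — results are insensitive to these).  This reproduces,
among other things, the depletion of signal between TSS and pause site that
grows with pause duration: polymerases that sit paused through the whole
labeling window synthesize no labeled RNA.

Sampled tracks draw **reads, not polymerases**: the labeled-RNA population
of >10⁷ cells is effectively infinite, so the only sampling noise that
matters is library sampling.  Sequenced fragments (200 bp, the experiment's
average) arrive as a Poisson process whose start intensity is the expected
profile scaled by the depth constants.  An earlier design that deposited
one fragment per simulated polymerase left window sums dominated by
polymerase-counting noise with a 10–25 kbp correlation length — nothing a
pooled-cell library exhibits — and ruined velocity recovery; the read
process matches both the mean and the noise structure of real coverage.

**Inhibition.**  Initiation into productive elongation during the final t\*
minutes is thinned by the TU's response ratio *r*.  Two modes:

* `sharp` (default): fragment mass inside [0, m\* + v(t\*−t_lab)) is removed
  with probability r.  This is the data-generating process of the
  response-window model that all estimators are built on.
* `kinetic`: whole polymerases are thinned by release age, which smears the
  window edge linearly over one labeling duration.  Under this mode the
  deficit integrates to r·v·t_lab(t\*−t_lab/2) rather than
  r·v·t_lab(t\*−t_lab), so the velocity estimators acquire a ≈ +25%
  systematic bias — a genuine property of the estimator worth knowing, kept
  available but not the default for estimator validation.

**mNET-seq.**  Expected occupancy I/v(x) plus the pause mass (I·d control;
under inhibition the dwell rises to `d/max(1−r, 0.125)` capped at the
steric ceiling 4/I, and the gene-body flux within reach of the treatment
drops to I(1−r)) deposited with a Gaussian spread (sd 20 bp, approximating
the empirical ±100 bp pause window); per-base Poisson counts.  Antisense
bleed-through is simulated at rate c on both assays.

**Truth sampling.**  Per TU: length log-uniform 10–200 kbp; velocity
log-normal (median 2.4 kbp/min, σ_log 0.49, giving mean ≈ 2.7); initiation
frequency log-normal with the mean pinned at 2.7 cell⁻¹min⁻¹ and σ_log 1.2
(spanning ~2.5 decades as in measured cohorts); response ratio Beta(2.9,
2.1) (median ≈ 0.58) with a 7% non-responder admixture (r < 0.04), which
also feeds the mNET normalization; pause position Normal(84, 25) clipped
into the first exon.  Pause durations are drawn as a log-uniform fraction
u ∈ [0.08, 0.9] of the steric ceiling (200/50)/I, so the (I, d) cloud lies
along — and, with the constraint flag on, below — the pause-initiation
limit and is strongly anti-correlated, the structure observed for human
genes.  With the constraint off, u ranges up to 1.8 and impossible
combinations occur.  Per-sample depth factors (0.93–1.12) exercise the size
factors; κ_true = 20 coverage units per (molecule/cell) puts the median TU
at coverage ≈ 130, deep enough that the expression filter (RPK ≥ 100)
keeps all but the weakest percent of TUs.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: alignment and duplication artifacts, mappability
gaps, splicing-intermediate contamination of mNET-seq 3' ends, termination
within the pause window, multi-pause genes, transcript-isoform switching,
batch effects beyond scalar depth factors, and genuine biological
between-replicate variability (replicates differ only by sampling and
depth).

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open throughout; GTF converts on read.
Negative corrected signal clamps to 0 (logged).  TUs with a zero in any
sample are excluded from size-factor medians.  Isoform TSS equality is
exact (no fuzz window).  The common-velocity loss is minimized by coarse
grid + local unit scan (validated against a full unit grid).  The
DMS-seq depth adjustment scales the denatured reference by the largest
α ∈ (0, 1] leaving ≤ 5% negative positions (bisection, validated against a
grid); α is capped at 1 because the denatured track is the reference and is
only ever scaled down.  Melting temperatures use nearest-neighbor
thermodynamics (DNA/DNA unified table; Sugimoto RNA/DNA hybrid table) at
1 M monovalent salt and 1 µM strand concentration; ambiguous bases yield
NaN positions.  Bootstrap confidence bands resample TUs (1000 draws,
seeded).  Group comparisons use the two-sided Wilcoxon rank-sum test with
raw p-values, as is conventional for these cohort-scale descriptive
reports.

## Problem sizes used in tests and the acceptance script

Parameter recovery and the directional-inhibition checks run on a 200-TU
cohort at the default study conditions.  The pause-initiation-limit
contrast runs on an 800-TU cohort restricted to velocity-eligible lengths
(35–200 kbp): the shuffled-null criterion |ρ| < 0.1 is a statement about
the null sampling distribution of the rank correlation and needs several
hundred TU pairs before its own sampling noise fits inside the bound.
Violations are flagged with the primary d estimator for the intact cohort;
the reassignment null uses d̂, the initiation-free estimator — with the
primary estimator the product d·I is invariant under reassignment by
construction (I cancels), so no contrast is possible there.

## Known limitations

* v_i inherits the full-length-over-trimmed-window factor (+5–15%) and is
  undefined for weak responders (r ≤ 0.25) and short TUs.
* d carries the pause-window transit time 200 bp/v in its numerator
  (occupancy integrates to I·(d + transit)); for fast, briefly-pausing
  genes this inflates d by up to ~25% and is the main driver of its
  residual error.
* κ assumes perfect RNA extraction; a lower true efficiency scales all I
  down and all d up by one global factor (the limit margins scale
  accordingly).
* The pipeline reuses control-called pause sites for the inhibited
  condition; genes whose pause site moves under inhibition are summed in a
  slightly off-center window.
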