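# Methods

## Scope and model

The package implements the computational chain of a noncoding-RNA study of
NaF-exposed HOS cells: array-based screening of ~5,600 mature noncoding-RNA
probes across three dose groups, sequence-level characterization of the
C/D-box snoRNA subset, qPCR validation of selected miRNAs and osteogenic
genes, and canonical seed-site scanning of miRNAs against UTRs. Each stage
is a library module; the `analysis/` scripts and the `pipeline` module only
compose them.

## Array screening (`arraydx`)

Linear intensities are background-adjusted per sample by subtracting a low
intensity percentile (default the 2nd) and flooring at 1.0 so log2 is
defined. This percentile shift is a deliberate simplification of the RMA
normal+exponential background convolution: every quantity this package
reports downstream depends on quantile normalization and the ANOVA screen,
not on the convolution model, and the background stage is pluggable
(`background=False` disables it).

Quantile normalization maps each sample onto the across-sample mean of
order statistics; tied input values receive the mean of the target values
at the ranks they occupy, which makes the transform idempotent. With ties
present, per-sample sorted vectors can differ by the tie-averaging itself;
for continuous intensities they are identical to floating tolerance.

Summarization uses Tukey median polish (≤ 10 sweeps or sweep magnitude
< 0.01 on the log2 scale); the summarized value per sample is the overall
effect plus that sample's column effect. The default screening path treats
each probe as its own probeset, as appropriate for a mature-RNA array.

Each probe is tested with a classical one-way ANOVA over all groups
(F = MS_between / MS_within, upper-tail F probability). Degenerate
within-group variance yields p = 0 (unequal means) or p = 1 (equal means)
with a warning. P-values are raw — no multiple-testing correction — to
match the screening convention the pipeline reproduces; this inflates the
expected false-positive count to 0.05 × n_probes, which the worked example
makes visible. Fold changes are per contrast (each dose vs control) on the
signed scale: r = 2^Δlog2, reported as r if r ≥ 1 else −1/r, so |fc| ≥ 1
and down-regulation is negative. The screen keeps p < p_cut (strict) and
|fc| ≥ fc_cut (defaults 0.05 and 1.5).

## snoRNA features (`snofeat`)

Sequences are normalized to upper-case RNA (T→U); any other character is
rejected with its position (N optionally tolerated and never matched).
Motif scanning reports every occurrence of UGAUGA (C box) and CUGA (D box),
overlapping or adjacent ones included — the counting rule is the brute-force
substring definition, which the tests enforce by oracle equivalence. An
occurrence starting within `terminal_window` (default 15 nt) of the 5' end
is classed `terminal_5p`; one ending within the window of the 3' end is
`terminal_3p` (5' precedence when both apply, relevant only for sequences
shorter than two windows); otherwise `internal`. The window is a free
parameter because "near the terminus" has no canonical width; it is
reported with the output.

Length outliers use the Tukey fences LL = q25 − 1.5·IQR,
UL = q75 + 1.5·IQR. The quartile estimator defaults to linear interpolation
between order statistics (Hyndman–Fan type 7, numpy's default) and is
selectable among numpy's estimator family, because the fences are sensitive
to the estimator near the cut; the GEO recipe sweeps all estimators and
reports which one reproduces a given pair of published fences. Outlier
flagging is upper-side by default (long snoRNAs are the objects of
interest); when an explicit threshold is supplied instead of fences, the
comparison is inclusive (length ≥ threshold), matching how a published
threshold like "l ≥ 112.87" is applied.

The Kimura two-parameter distance separates transition (P) and transversion
(Q) proportions: d = −½ ln(1−2P−Q) − ¼ ln(1−2Q). Unequal-length sequences
are first aligned globally (match +1, mismatch −1, gap −2, scores pinned
for reproducibility) and gap columns are excluded; if the log arguments are
non-positive the pair is reported as saturated (`SaturationError`) rather
than given an arbitrary large distance. The mean pairwise distance excludes
saturated pairs and reports how many were excluded. Note that unrelated
random sequences sit at or beyond saturation; a finite small mean is itself
evidence of homogeneity.

The D-box/regulation summary is a 2×2 table over {≥ 2 D boxes, < 2} ×
{down, not down}, restricted to length outliers, with the down-regulated
fraction per stratum.

## qPCR (`qpcr`)

dCt = mean Ct(target) − reference aggregate per condition, where the
aggregate is the arithmetic mean of per-reference-gene mean Cts (equivalent
to the geometric mean of relative quantities — the standard multi-reference
rule). ddCt = dCt(treated) − dCt(control); FC = 2^−ddCt, reported signed.
Amplification efficiency is fixed at 2 per cycle; no efficiency correction.
Dispersion is implementation-defined as the SD (ddof 1) of the linear
fold-change magnitudes obtained by re-evaluating ddCt once per treated
replicate; a single replicate reports 0 with a warning. LC50 is the dose at
which viability crosses 0.5, by linear interpolation on log10(dose) between
the bracketing observations (first crossing wins); a 4-parameter logistic
fit was deliberately not used since the value is supporting context, not an
analysis surface.

## Seed scanning (`seedscan`)

The seed is miRNA positions 2–8 (1-based, 5' end). Sites are anchored on
exact Watson–Crick reverse complements of positions 2–7 (6mer core) on the
UTR as given, extended to 7mer-m8 (match to position 8, on the site's 5'
side), 7mer-A1 (an A opposite position 1, on the site's 3' side — an A
regardless of the miRNA's first base, per the canonical definition), and
8mer (both). Each core position is reported once with its maximal type;
overlapping cores are all reported. No G:U wobble, no thermodynamic or
conservation scoring: affinity-scored target prediction (miRANDA-style) is
out of scope, and the scanner makes the pairing logic exact and testable by
brute-force enumeration instead.

## Synthetic data (`synthio`)

The generators define the study conditions every test and the acceptance
run operate under:

- **snoRNA sets** — core lengths from a clipped normal at the centre of
  [48, 112] nt (sd = width/5), emulating a concentrated main length mode;
  outliers uniform on [114, 237] nt. Defaults in the demo: 332 core + 15
  outliers = 347 sequences, one C box each, 0–5 D boxes. Background bases
  are uniform ACGU with a first-order Markov upweighting of G after U
  (`ug_enrichment`, demo default 2.0), making UG-dinucleotide enrichment
  controllable without claiming a composition model. Motifs are planted in
  random non-overlapping slots and the whole sequence is re-scanned with
  the `snofeat` scanner; background is redrawn until the found counts equal
  the planted counts, so the scanner is the planting oracle. Regulation
  calls follow the D-box rule (≥ 2 D boxes → down, else up, both doses),
  emulating the association the downstream contingency table measures;
  `regulation_rule="none"` disables it.
- **outlier families** — `pipeline.mutate_family` derives homologous
  variants by per-site substitution (rate 0.08, transition:transversion
  odds 2:1), giving expected pairwise divergence ≈ 0.15–0.16 and a mean K2P
  near 0.18, the homogeneity regime of a real snoRNA family. Independent
  random sequences would sit at saturation and carry no homogeneity signal.
- **probe matrices** — probe baselines uniform on log2 [6, 12], Gaussian
  noise (sd 0.25), exponentiated; a fraction of probes (10%) shifted by
  ±effect_log2 (2.0) in both treated groups, sign random per probe. Demo
  scale is 500 probes × 3/3/3 samples; the null-calibration check uses
  2,000 probes with no effect.
- **Ct tables** — reference genes constant across conditions; target genes
  shifted by −log2(linear FC) cycles in the treated condition, so the ddCt
  stage recovers the generating signed fold change exactly at zero noise.
  Demo truth values are the validated fold changes of the assayed genes
  (e.g. miR-124 +3.24, RUNX2 −3.25 at 8 mg/L), with replicate noise
  sd 0.1 cycles.
- **UTRs** — 8mer windows planted in uniform background, scanner-verified
  like the motif planting.
- **viability** — a Hill curve with LC50 40 mg/L over 10–250 mg/L.

What the generators do **not** emulate: probe-level chemistry and scanner
artifacts, probe–probe correlation, heavy-tailed array noise, sequence
homology between core (non-outlier) snoRNAs, partial or bulged seed sites,
and qPCR efficiency drift. Passing tests therefore demonstrate correctness
of the computations and calibration under idealized noise, not robustness
to every artifact of real array or qPCR data.

## Numerical choices and degenerate inputs

Quantile normalization uses a stable mergesort and explicit tie averaging;
ANOVA returns exact 0/1 p-values for zero within-group variance instead of
NaN; the K2P domain boundary raises rather than clamps; fences require ≥ 4
lengths; LC50 requires a bracketing crossing; `de_screen` rejects unknown
contrasts; generators validate their specs (disjoint length ranges, motif
load vs length, |fc| ≥ 1, disjoint reference genes) before drawing.
All stochastic code takes explicit integer seeds; the pipeline derives
stage seeds from one master seed recorded in the report, and equal seeds
give byte-identical reports and FASTA/TSV outputs.

## Problem sizes

The demo and the acceptance run use 500-probe matrices (3 samples/group),
347 snoRNAs with 15 outliers (105 K2P pairs), 3 qPCR replicates × 2 doses,
and 400-nt UTRs — sizes chosen so the planted-truth comparisons are
well-powered while the whole chain completes in seconds.

## Known limitations

Raw p-values only (BH correction is available in statsmodels if a user
wants it, but the screening convention reproduced here does not apply it);
the ANOVA assumes equal group variances; the percentile background is not
the RMA convolution; K2P alignment scores are pinned rather than tuned;
seed scanning ignores site context (AU flanking, 3'-supplementary pairing);
dispersion semantics of fold changes are implementation-defined as
documented above.
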