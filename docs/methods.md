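# Methods

This note documents the models and procedures implemented in
`promotermine`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Candidate mining

Genes are ranked per condition by abundance; the unit is treated as a
TPM-like within-condition normalized value, which is rank-preserving —
the ranking metric is carried as a label only, since any within-sample
monotone normalization yields the same top-N sets. Ties are broken by
gene id (ascending), which is deterministic and data-independent.

The promoter window is fixed at 1000 bp upstream of the translational
start codon (not a transcription start site). Windows are taken
regardless of overlap with an upstream neighbouring gene; an optional
warning reports overlaps. At a contig edge the available portion is
returned with a `truncated` flag rather than erroring, so toy genomes
remain usable. Internally coordinates are 0-based half-open; GFF3 I/O
(1-based inclusive) converts at the boundary. Minus-strand windows are
the reverse complement of the genomic slice just above the start codon,
so every promoter is 5'→3' on its gene's coding strand and concatenating
it with the coding sequence reconstructs a contiguous transcript-oriented
string.

Cloning failure is an experimental label, not a computed property: in the
pipeline a candidate is counted as a cloning failure when it is absent
from the plate table (never assayed). The screening ledger is pure
arithmetic with consistency checks: assayed = candidates − clone
failures; strong = assayed − null − very weak; controls add to the
strong tally.

## Element and splice-risk scanning

All scans are forward-strand (promoters are transcript-oriented).

* **Motifs.** The CAAT motif is scanned as literal `CAAT` anywhere in the
  window and the GC box as literal `GGGCGGG`; both patterns are
  configurable and accept IUPAC ambiguity codes (standard codes only).
  Matching is a naive O(n·m) scan, deliberately independent of the regex
  oracle used in the tests; overlapping matches are all reported.
* **CT box.** "Pyrimidine-rich" is operationalized as the maximal C+T
  fraction of a 20 bp sliding window within −90..−10 from the start
  codon, called present at ≥ 0.6. The threshold is descriptive rather
  than discriminative: the maximum over ~60 windows of random sequence
  frequently exceeds 0.6, so the call separates planted/biological CT
  boxes (≥ 0.8 C+T) from pyrimidine-poor sequence, not from arbitrary
  random background. Ties go to the 5'-most window; promoters shorter
  than the scan region are scanned over what exists and flagged.
* **Splice risk.** Donor and acceptor are the literal trigrams `GGT`
  (G|GT) and `AGG` (AG|G); no position-weight scoring is attempted. The
  junction string is the last 25 bp of the promoter (configurable) plus
  the reporter head — bundled as the first 22 bp of the EGFP coding
  sequence, which contains AG|G acceptors. Risk is flagged iff a donor
  whose G lies in the promoter portion has any acceptor strictly
  downstream in the junction; the 5'-most such donor and its nearest
  acceptor are reported. The rule is monotone: extending the reporter
  head can only add acceptors, never un-flag a junction.

## Strength quantification

Blank subtraction precedes the fluorescence/OD ratio (plate fluorescence
background is additive); each replicate is normalized separately and
replicates are aggregated as the arithmetic mean of per-replicate ratios.
Negative normalized signals are clipped to zero with a warning; a sample
OD at or below the blank OD is a non-growth error. Folds are ratios of
within-condition signals, hence invariant to the plate gain and to any
uniform rescaling of raw fluorescence, and robust to per-plate exposure
differences.

The detection limit is the blank mean + 3 sd of blank fluorescence (the
standard limit-of-detection convention). Class cut points 0.1 / 0.5 / 2 /
5 × reference operationalize the qualitative labels very weak → extreme;
they are configurable, and chosen so the reference promoter itself is
*medium*. The overall class is the modal per-condition class with ties
resolved toward the lower class. A promoter is phase-responsive when any
stationary/logarithmic fold ratio is ≥ 2 or ≤ 0.5, and medium-variable
when the CV of folds across media within a phase is ≥ 0.5 (sample sd).
Fold uncertainty is reported descriptively (per-condition sd over
replicates); no hypothesis testing is performed.

The fold estimator is a ratio of noisy means and therefore carries a
small positive Jensen bias of order cv²/n (≈ 0.1% at cv = 0.05, n = 3) —
negligible against the replicate noise, but worth knowing when averaging
many plates.

## Pathway scoring and sugar summary

The two desaturation steps are treated as a bottleneck-limited series:
score = min(sat(f₉), sat(f₁₂)), sat(f) = f/(f+K) with K = 1 (folds are
dimensionless, so K is too). min-of-saturations was preferred over a
product because a sequential pathway is limited by its weaker stage; the
score only ranks designs — measured titers need no model. Scoring uses
logarithmic-phase folds in the matching medium by default (expression
during growth drives desaturase levels); this is configurable. Note that
with ordered pairs and repetition allowed, the model's exhaustive argmax
doubles the single strongest promoter; among designs built from distinct
promoters the two strongest win.

Percent improvements are rounded half-away-from-zero to one decimal.
Sugar utilization is summarized at a 30 h horizon (linear interpolation);
a sugar is exhausted when it first drops below 5% of its initial
concentration (an instrument-floor proxy — no cut-off is canonical), and
the mixed-sugar flag requires ≥ 80% of summed sugars consumed.

## The synthetic world

The generator is a pure function of its seed (identical configs give
byte-identical files) and plants the structure the pipeline must recover:

* **Genome/annotation.** Uppercase ACGT only, genes on both strands with
  ≥ 100 bp intergenic clearance and a full 1000 bp upstream window
  reserved per gene; 200 genes over 6 contigs by default. Gene bodies are
  plain random sequence behind an ATG — no introns, codon structure or
  realistic GC content beyond what the diagnostics need.
* **Expression.** Gamma-Poisson (negative-binomial) counts, lognormal
  gene means, shared dispersion (size 50), scaled TPM-like per condition.
  Exactly 52 designated candidate genes receive condition-specific mean
  boosts (~30 000 vs a background mean of ~30) so each of the 8
  conditions' top-15 lists equals its designated member set with
  overwhelming probability; the union is exactly the candidate set.
* **Classes and elements.** 3 clone-fail, 11 null, 7 very weak and 31
  strong candidates, plus a reference (fold ≡ 1) and two controls (0.75×
  and 1.2×). Strong/reference/control promoters get a planted CT box
  (20 bp, ≥ 80% C/T inside −90..−10) and, with probability 0.5/0.4, a
  CAAT motif or GC box; null promoters get a G|GT donor in their final
  25 bp while all assayable promoters have accidental donors scrubbed
  from that tail, so junction risk tracks class truth.
* **Strengths.** Planted folds span 0.1–19.0× the reference: the weakest
  promoter sits at 0.1 in minimal medium, the strongest at 19.0 in the
  xylose medium stationary phase with a 9.0 stationary/log ratio in the
  glucose-rich medium; two promoters are extreme (> 5×) in every
  condition and slightly stronger during growth; the remaining strong
  promoters draw lognormal folds capped at 4.8 so the extreme pair stays
  unique. Wells follow F = blank_F + (OD − blank_OD)·gain·fold·(1+ε),
  ε ~ N(0, cv), cv = 0.05, triplicates; blank wells carry plate constants
  with jitter proportional to cv, so cv = 0 makes the whole plate exact
  and the estimator inverts the forward model perfectly.
* **Titers and sugars.** C18:2 titer = base(medium) + gain·min-saturated
  log-phase fold + 2% multiplicative noise; the gain (≈ 199.7 mg/L) is
  solved so the strongest pair reproduces the study-scale endpoints
  (164.3 → 350.3 mg/L glucose-rich, 79.08 → 248.5 mg/L minimal, a 214.2%
  improvement) at zero noise. A separate mixed-sugar fold table makes the
  double high-strength design win on hydrolysate. The sugar series is a
  deterministic set of decay curves: xylose starts higher than glucose
  but glucose exhausts first (~19 h vs ~30 h), arabinose is consumed
  slowly, and ~89% of summed sugars are gone by 30 h.

What passing tests on this world demonstrate: the pipeline's arithmetic,
strand handling, scanning rules and estimators are correct and invert the
generator's forward models within the stated tolerances. What they do not
demonstrate: performance on real transcriptomes (library-composition
biases, unannotated TSSs, overlapping genes), real plate data (drift,
autofluorescence, growth-dependent quenching) or real fermentations — the
titer model is a ranking heuristic, not kinetics.

## Problem sizes and runtime

Default analyses run on 200 genes × 8 conditions, 1272 plate wells, and
16 enumerated designs; the recovery properties average 20 regenerated
plates at cv = 0.05. The full test suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

* The CAAT/GC-box calls are presence/absence of short literals; no
  positional model, strand search or enrichment statistics.
* The detection limit uses blank fluorescence only; autofluorescence of
  non-expressing cells is not modelled (the generator's null promoters
  emit exactly blank-level signal).
* The bottleneck score ignores promoter–gene context effects (5' UTR,
  terminator choice) and any saturation of the downstream pathway.
* Candidate numbering (`P_<gene>`) assumes gene ids are unique across the
  genome.
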