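# Methods

This note documents the models, conventions and design choices behind each
stage of `kininmine`, and what the synthetic-data studies do and do not
demonstrate.

## Prohormone processing model

A neuropeptide precursor is processed in three conceptual steps, applied in
order to every fragment the cleavage step produces.

**Cleavage.** Maximal runs of K/R are evaluated as single candidate sites,
cleaved after the last residue of the run. A run is cut when its final
ordered pair is KR or RR (always), KK or RK (only with
`optional_pairs_enabled`), or when it is a lone Arg with another basic
residue 4, 6 or 8 positions upstream (`monobasic_upstream_offsets`,
counting residues from the Arg itself; offset −4 means four residues
N-terminal). A site whose following residue is Pro is suppressed
(convertases cleave X-Pro bonds poorly), as is any site inside an
externally supplied signal peptide (`signal_end`). These rules are the
classical dibasic/monobasic picture of prohormone-convertase specificity;
since the precise monobasic counting convention varies in the literature,
the offsets are configurable and the whole rule set is a value object
(`CleavageRuleSet`). Signal peptides are never predicted internally — the
boundary is an optional input annotation, default absent.

**Trimming and amidation.** Each fragment loses all trailing K/R
(carboxypeptidase E step); if the trimmed fragment then ends in Gly and
amidation is enabled, that Gly is removed as the amide donor and the
peptide is marked amidated (PAM step). Fragments that trim to nothing are
discarded. The untrimmed fragments tile the precursor exactly, and each
peptide records its untrimmed 1-based span.

**Core detection and mass.** An amidated peptide whose last five residues
are F,·,·,W,G carries the kinin core; the two interior residues are X₁ and
X₂. Masses are *average* (not monoisotopic): the sum of standard average
residue masses plus one water (18.0153 Da), minus 0.9848 Da (OH→NH₂) when
amidated, rounded half away from zero. This is the one convention that
reproduces the published tick kinin mass table; the five identical
DTFGPWG-amide rows printed there at 768 Da compute to 778 Da and appear to
be a propagated transcription error from the preceding DTFGSWG-amide row —
the package reports the computed value and flags the discrepancy rather
than arbitrating it.

**ORF conventions.** Six-frame translation uses the standard code with `*`
for stops and `X` for codons containing N; trailing partial codons are
dropped. ORFs start at ATG; `coding_length_nt` excludes the stop codon
(an ORF running off the end of its frame is flagged `partial`), with the
stop-inclusive length also exposed. Ranking is by protein length, then
earlier forward-strand start, then frame order +1..+3, −1..−3.

## Conservation logos

Kinin paracopies differ in length N-terminally but share the amidated
C-terminal Gly, so the family alignment right-justifies sequences on their
final residue — no gap model is needed. Per column, over the n non-padding
residues, `H = −Σ p log₂ p`, the small-sample correction
`eₙ = 19/(2·n·ln 2)` (on by default, matching the standard logo tools;
exposed as a flag), and `R = max(0, log₂20 − H − eₙ)`. Letter heights are
`R·p`. All-padding columns report R = 0 with n = 0, letting downstream
plots start where the signal does. Residue colour classes (polar-amide,
polar, basic, acidic, hydrophobic) are exported as plot metadata.

## Gene-structure inference

The spliced aligner targets the regime it is used in — a cloned mRNA
against near-identical genomic sequence (reported identity ~99%) — and
therefore uses exact k-mer anchor chaining rather than full dynamic
programming. Anchors (default k = 15; seeds occurring > 64 times in the
genomic sequence are skipped) are collapsed into maximal co-diagonal
segments; a colinear chain maximising matched length is selected; diagonal
jumps of at least the minimum intron length (default 30 bp) become
introns, smaller jumps are treated as mismatch patches within one exon.
Because the intron length equals the diagonal jump, the cut point within
the junction ambiguity window does not change intron length, only its
placement: the window (±k around the anchor gap) is scanned preferring a
GT..AG interpretation, then GC..AG, then the leftmost candidate —
deterministic output by construction. Terminal exons are extended to the
cDNA ends along their diagonals. A chain covering < 50% of the cDNA is an
alignment failure. Coordinates are 1-based inclusive everywhere, matching
GFF3. Limitations: no indel model within exons (point mutations only are
assumed between strains), single-gene scope, and no ab initio prediction.

## Assay analytics

**Endpoint screen.** A 384-well plate read in forward and reverse
orientations maps reverse well (r, c) to forward well (R+1−r, C+1−c); the
two reads are averaged per well. Responses are percent of the
positive-control (blank solvent + agonist) mean. A compound is an
antagonist when any dose's percent drops to ≤ 50% of control, and a *full*
antagonist when the minimum reaches ≤ 20%; the 20% cutoff is a package
convention (the source screen labels full/partial without a numeric rule).

**4PL fitting.** The GraphPad "log(inhibitor) vs. response — variable
slope" model, `y = bottom + (top − bottom)/(1 + 10^((log IC₅₀ − log c)·hill))`,
fitted by unweighted least squares (scipy `curve_fit`). Initialisation:
bottom/top from the response extremes, log IC₅₀ from the dose nearest
half-range, and the Hill sign taken from the observed trend (inhibition
curves converge with hill < 0 in this parameterisation). The reported IC₅₀
is the fitted midpoint — explicitly *not* the 50%-of-control dose. The 95%
CI is t-based on the asymptotic SE of log IC₅₀ (df = n − 4); flat or
degenerate data return `converged = False` with a diagnostic instead of
raising. Near-flat data may converge with an extremely wide CI — the CI,
not the point estimate, carries that information.

**Kinetics.** Traces are 65 samples at 1 s; the compound addition at 2 s
and agonist addition at 32 s define two half-open 30-sample windows,
[2, 32) and [35, 65) (equal width; whether the source quantified 35–65
inclusively is not decidable, so the half-open convention is fixed here).
Window means are normalised to the positive control's second-window mean,
which is 100% by construction. The prolonged-preincubation variant is the
same normalisation with a single 30-s window.

**Replicate statistics.** The experimental unit is the independent assay:
pseudo-replicate wells are averaged first, and one-way ANOVA (scipy) with
Tukey HSD (statsmodels) runs on assay-level means, n ≥ 2 per group.
The compact letter display uses the insert-and-absorb algorithm; groups
sharing a letter do not differ at α = 0.05.

## Synthetic data: what it emulates, and what it does not

Generators draw from `numpy.random.default_rng([stage_tag, seed])` — the
per-stage tag decorrelates streams so, e.g., a cDNA and the intron planted
into it never share bases by seed coincidence; same seed ⇒ bit-identical
output.

* **Precursors** — spacer + body blocks ending F-X₁-X₂-W-G + amide-donor G
  + a dibasic pair, from residue pools chosen so no unplanned cleavage
  site, Pro-block or core can arise; X₂ is Pro with weight 15/17,
  mirroring the cloned precursor's composition. Defaults follow the
  17-paracopy architecture.
* **Genes** — one GT..AG intron planted into a cDNA; the intron interior
  is scrubbed of GT near its start and AG near its end (20-base guard) so
  the planted junction is the unique canonical interpretation within the
  refinement window; point mutations spare only the two splice
  dinucleotides.
* **Endpoint plates** — one compound per row, doses across columns, PC
  wells in the four edge columns (the published layout concept);
  noiseless well value `PC_level · 4PL(c)/100`, multiplicative Gaussian
  noise independent per orientation.
* **Kinetic traces** — baseline plus the transient
  `A·(t−t₀)·exp(−(t−t₀)/τ)` from t₀ = 32 s (τ = 5 s), amplitude scaled by
  the 4PL truth, additive Gaussian noise per sample. The transient shape
  is a modelling convenience; only its window means matter downstream.

These generators reproduce the *statistical structure* each stage assumes,
not real data: no plate gradients or edge effects, no compound
precipitation, no receptor kinetics, no sequencing error model beyond
uniform substitutions. Passing the recovery studies therefore certifies
the analysis code, not instrument behaviour.

## Validation studies and problem sizes

The seeded studies in `kininmine.validation` (also run by
`scripts/acceptance.py`) use: 500 simulated plates at 5% CV for 4PL
recovery and CI calibration, under the confirmatory dose design (10 doses,
1:1.4 from 100 µM) with a full-antagonist truth whose IC₅₀ (~22 µM) sits
mid-series — the regime a well-designed dose-response run targets; 200
noiseless plates spanning inactive/partial/full truths for call agreement;
100 synthetic genes (exons 50–2,000 bp, introns 100–3,000 bp) per mutation
condition; and the exhaustive 488,280-sequence cleavage comparison
(lengths ≤ 8 over A/K/R/P/G). With 500 plates the CI-coverage estimate
itself has ~1% binomial standard error, so run-to-run values near 95%
scatter by a point or two. The published-architecture gene check plants a
2,700-bp intron after base 140 of a 1,393-nt cDNA and recovers
exons of 140 and 1,253 bp exactly.

## Known limitations

* Cleavage rules are positional only — no logistic/ML site scoring, and no
  lone-Lys rule (an unusual K site observed in one related species is
  reachable via the configurable pair set, not the default).
* Average masses only; no monoisotopic or MS-matching workflow.
* The aligner assumes colinearity and substitution-only divergence.
* The 4PL CI is asymptotic; profile-likelihood intervals are not yet
  implemented.
* Accession-based checks (the deposited precursor and gene records) need
  live NCBI access; offline runs exercise the same operations on
  generator-truth equivalents.
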