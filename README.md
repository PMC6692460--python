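# kininmine

Tick kinin neuropeptide mining and GPCR antagonist-screen analytics.

Kinins (leucokinins) are invertebrate neuropeptides whose receptors are
attractive, arthropod-specific targets for acaricide discovery. A single
tick precursor protein encodes many kinin *paracopies*, each released by
prohormone-convertase cleavage at basic residues and activated by
C-terminal amidation; the active products share the core
**Phe-X₁-X₂-Trp-Gly-NH₂**. `kininmine` is a library for the computational
side of that biology, aimed at peptide biochemists and receptor
pharmacologists:

* **Precursor mining** — six-frame translation and ORF discovery; cleavage
  prediction (dibasic KR/RR always, KK/RK optional, lone Arg with a basic
  residue at −4/−6/−8, sites followed by Pro suppressed); carboxypeptidase
  trimming of trailing K/R; removal of the C-terminal Gly amide donor;
  detection of the FX₁X₂WG-amide core; average peptide masses
  (Σ residue masses + 18.0153 Da water, −0.9848 Da for the amide).
* **Conservation logos** — kinin sets right-anchored on the amidated Gly;
  per-column information content `R = log₂20 − (H + eₙ)` with the
  small-sample correction `eₙ = 19/(2·n·ln 2)`.
* **Gene structure** — splice-aware cDNA-to-genomic comparison by exact
  k-mer anchor chaining, with intron boundaries refined to canonical
  GT..AG (fallback GC..AG); GFF3 export.
* **Dual-addition calcium assays** — 1:1.4 dilution designs; forward +
  reverse 384-well endpoint reads averaged and expressed as percent of the
  positive control; antagonist calls; four-parameter-logistic fits
  `y = bottom + (top − bottom)/(1 + 10^((log IC₅₀ − log c)·hill))` where
  the IC₅₀ is the fitted midpoint, with t-based 95% CIs; 65-s kinetic
  traces summarised over the [2, 32) s and [35, 65) s windows; one-way
  ANOVA + Tukey HSD with compact letters over independent-assay means.
* **Synthetic data** — seeded generators (precursors, two-exon genes,
  endpoint plates, kinetic traces) that return exact ground truth, so the
  whole pipeline is testable offline.

## Worked example

```python
from kininmine import mine_precursor, peptide_table, PrecursorRecord

prec = PrecursorRecord("demo", "QEEAQFSPWGGKRDADTFGPWGGKREEDA")
print(peptide_table(mine_precursor(prec)).to_string(index=False))
```

```
   name   sequence  amidated  core X1 X2  span_start  span_end  mass_da  mass_rounded
demo_p1 QEEAQFSPWG         1     1  S  P           1        13  1177.24          1177
demo_p2  DADTFGPWG         1     1  G  P          14        25   964.00           964
demo_p3       EEDA         0     0                26        29   462.41           462
```

Both internal fragments end in the amide-donor Gly after trimming their
dibasic KR, so they are amidated (column `amidated`), carry the kinin core
(`X1`/`X2` are the two variable core positions), and report average masses
with the −0.98 Da amide shift. The C-terminal spacer is released unamidated
and has no core.

The scripts in `examples/` walk through each capability (mining,
conservation logos, gene structure, endpoint and kinetic screens) and print
annotated output; run them directly, e.g.
`python examples/endpoint_screen.py`.

There is also a thin CLI:

```sh
kininmine --out-dir out simulate --seed 1
kininmine --out-dir out annotate out/precursor.fasta
kininmine --out-dir out gene out/cdna.fasta out/genomic.fasta
kininmine --out-dir out assay-endpoint out/endpoint.csv
```

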