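# srnamir

Small-RNA sequencing analysis for plant miRNA discovery, at desk scale.

Deep sequencing of a plant small-RNA library (the motivating system is
peanut, *Arachis hypogaea*, where genome sequence is scarce and ESTs serve
as the search space) yields tens of millions of 18–28 nt reads. `srnamir`
implements the complete downstream analysis as a reusable, tested Python
package:

1. **preprocess** — quality filtering, 3′-adapter clipping, length
   filtering (inserts longer than 17 nt kept), and collapsing into unique
   *tags* with abundance counts;
2. **classify** — each tag is assigned to a category (known miRNA, rRNA,
   tRNA, snRNA, snoRNA, siRNA, unannotated) by *perfect* full-sequence
   matching against per-class reference sets, producing the category
   distribution table and per-family miRNA abundances;
3. **discover** — unannotated tags are exactly matched against an EST
   collection; ±150 nt context windows are folded to their single
   minimum-free-energy structure (ViennaRNA by default, with a bundled
   base-pair-maximization fallback) and accepted as novel miRNA candidates
   only when the classical plant-miRNA hairpin criteria hold: mature
   wholly within one stem arm, ≤ 4 unpaired mature bases, no asymmetric
   bulge > 2 nt, no overlap with the terminal loop, negative folding
   energy. The miRNA\* strand implied by the duplex (2-nt 3′ overhangs) is
   searched among the sequenced tags as star support;
4. **target_score** — miRNA targets are called with the point-based
   complementarity statistic: each G:U wobble costs 0.5, each other
   non-canonical pairing 1.0, each indel 2.0; non-wobble mismatches at
   miRNA positions 2–7 (the seed) cost an extra 0.5; for miRNAs longer
   than 20 nt the total is the minimum over all consecutive 20-position
   windows; a site is a target when its total score is **strictly below
   3.0 points**;
5. **synthetic** — a ground-truthed generator that emulates the study
   conditions (24-nt-dominated length distribution, skewed miRNA family
   abundances, ncRNA contaminants, adapter read-through, planted hairpin
   precursors and planted target sites of controlled defect composition)
   so every stage can be tested against known truth;
6. **report / cli** — end-to-end orchestration, manifests, and
   table-style summaries.

## The scoring statistic

For an antiparallel duplex between a miRNA (positions numbered 1…L from
the 5′ end) and a transcript site,

    score = Σ_columns penalty(column) + 0.5 · #{mismatch columns at positions 2–7}

with penalty 0 (Watson–Crick), 0.5 (G:U), 1.0 (other mismatch), 2.0
(indel), and, for L > 20,

    total = min over windows w of score(columns with position in [w, w+19])

Candidate sites are found by evaluating every transcript offset as an
ungapped duplex plus all single-gap variants, reducing overlapping
placements to the best per cluster (exhaustive, auditable search — tested
against an independent brute-force oracle).

## Worked example

```python
from srnamir.report import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(outdir="demo", seed=7, n_reads=20000))
print(manifest["counts"])
```

prints (seed 7):

```
{'simulated_reads': 20000, 'raw_reads': 20000, 'clean_reads': 18276,
 'unique_tags': 13467, 'known_mirna_tags': 30, 'unannotated_tags': 13304,
 'novel_candidates': 20, 'target_hits': 20}
```

91.4 % of raw reads survive cleanup (the rest are low-quality,
adapter-only, or too short); all 20 planted hairpin precursors are
recovered as novel candidates; all 20 planted sub-threshold target sites
are called. `demo/report.txt` holds the rendered tables, e.g. the
category distribution:

```
        category  unique_count  unique_percent  total_count  total_percent
Total small RNAs         13467          100.00        18276         100.00
           miRNA            30            0.22         1790           9.79
            rRNA            40            0.30          727           3.98
            tRNA            30            0.22          598           3.27
           snRNA             3            0.02            4           0.02
          snoRNA             0            0.00            0           0.00
           siRNA            60            0.45         1715           9.38
     unannotated         13304           98.79        13442          73.55
```

Category totals mirror the configured read mixture (miRNA ≈ 9.5 %,
unannotated ≈ 74 %); unique-tag percentages are dominated by the
unannotated background, as in real libraries.

The same stages are available from the shell:

```
srnamir simulate --seed 7 --n-reads 20000 --outdir demo
srnamir preprocess --fastq demo/reads.fastq --outdir demo
srnamir targets --mirnas m.fa --transcripts t.fa --max-score 3.0 --out hits.tsv
srnamir pipeline --seed 7 --outdir demo
```

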