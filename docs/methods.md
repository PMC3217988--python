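# Methods

## Scope and model

`srnamir` re-creates the standard small-RNA-seq analysis chain used for
plant miRNA annotation in species without a reference genome: clean-up
and collapsing of reads, categorisation against reference RNA classes,
hairpin-based discovery of novel miRNAs from EST-mapped tags, and target
prediction by complementarity scoring. All stages operate on collapsed
*tags* (unique sequence + abundance); sequences are stored in the DNA
alphabet internally (U↔T normalised) and rendered as RNA in human-facing
tables.

## Preprocessing

Per read, in order: (1) quality filter — mean Phred ≥ `min_mean_q`
(default 20, inclusive) and no ambiguous base; (2) adapter clip — the
insert is everything before the leftmost 3′-adapter occurrence with at
most `max_mismatch` mismatches over the overlapped region, allowing
suffix overlaps of ≥ 6 nt at the read end; an empty insert marks an
adapter-dimer read; (3) length filter — keep inserts of 18–30 nt
(defaults; "longer than 17 nt" on the short side, while the library gel
cut is 18–28 nt — both bounds are configuration-exposed). Every raw read
lands in exactly one accounting bucket (clean / adapter-only /
low-quality / too-short), an invariant the stats object enforces.
Collapsing orders tags by descending count, ties lexicographic, for
reproducibility.

## Classification

Matching is exact, full-length, and orientation-aware (tag as sequenced
against sense-strand references); one mismatch disqualifies a hit.
Multi-class matches resolve by a priority order, default miRNA > rRNA >
tRNA > snRNA > snoRNA > siRNA; unmatched tags are "unannotated". The
category summary reports unique and total counts with percentages
against the all-tags row. The siRNA category is treated as a reference
set like the others; no operational siRNA definition (e.g. phasing) is
attempted. Family names are parsed as `miR<number>` with species prefixes
and member suffixes stripped (ahy-miR156f → miR156).

## Discovery

Only unannotated tags of 20–24 nt enter discovery (configurable), which
prevents abundant ncRNA fragments from being folded by chance. For each
exact EST occurrence (either strand) a ±150 nt context is extracted
(minus-strand hits are reverse-complemented) and folded to a single
lowest-energy structure. The locus is trimmed to the smallest window
containing the mature–star duplex plus its enclosing stem (extension
through bulges of ≤ 3 nt), refolded, and evaluated against the duplex
criteria:

* mature wholly within one arm — any pairing of mature bases with each
  other, partners on both sides, or a mature tail reaching into the
  terminal loop rejects the locus (`loop_overlap`);
* ≤ 4 unpaired mature bases (`excess_mismatch` otherwise);
* no asymmetric bulge > 2 nt between consecutive paired mature bases
  (`bulge`); crossing partners reject as `nonlinear_duplex`;
* folding energy < 0 (`nonnegative_mfe`);
* trimmed precursor within 50–350 nt (defaults; the delimitation of
  precursors from context windows is not standardised, so the trimming
  rule above is this package's documented choice).

The star strand is inferred from the structure by the 2-nt 3′-overhang
register (star 5′ end = partner of the mature base two positions inside
its 3′ end; star 3′ end = partner of the mature 5′ end plus the star's
own 2-nt overhang); these relations hold on either arm because pairing is
nested. Star support requires an exactly matching sequenced tag,
consistent with the classification rule. Candidates are deduplicated per
EST: identical precursors, identical matures (a hairpin is near-self-
reverse-complementary, so its mature also hits the minus strand), and
loci reached via the star strand merge into one record.

Rejections carry machine-readable reason codes and are written to a log
table.

## Folding engines

The default engine is thermodynamic MFE folding through the ViennaRNA
bindings (kcal/mol, deterministic for a fixed version). A bundled
fallback implements base-pair maximization (Nussinov recursion, minimum
loop 3 nt) with surrogate pair energies −2 (G:C) and −1 (A:U, G:U). Its
energies rank structures but are not free energies and are never compared
numerically to published kcal/mol values. Because the surrogate has no
loop penalties it is highly degenerate: on natural-like stems it may
prefer fragmented structures that tie or marginally beat the clean helix,
so cross-engine agreement is only asserted on unambiguous fixtures (GC-
only stems with unpairable loops) — a documented limitation of the
fallback, not of the discovery criteria.

## Target scoring

Penalties: G:U wobble 0.5; other non-canonical pairing 1.0; indel 2.0;
non-wobble mismatches at miRNA positions 2–7 (1-based from the 5′ end)
carry an extra 0.5. Wobbles in the seed are exempt from the surcharge.
The seed surcharge is applied per mismatch (the per-alignment reading of
the rule is grammatically possible but inconsistent with the scoring
lineage this scheme descends from). For miRNAs longer than 20 nt the
total is the minimum over all consecutive 20-miRNA-position windows, with
seed positions numbered on the full miRNA. Target-deletion columns carry
the bulged miRNA position for window bookkeeping but never trigger the
surcharge; target-insertion columns carry no position and are charged to
windows containing both flanking positions. Acceptance is strict:
score < 3.0.

Candidate generation evaluates every transcript offset as an ungapped
antiparallel duplex plus every single-gap variant (interior gaps only; an
insertion outside the paired span is not an indel of the duplex), up to
`max_indels` ≤ 2 (two-gap placements use a scalar path). Since every
offset overlaps its neighbours, "best per overlap cluster" is implemented
as greedy best-first selection of non-overlapping placements ordered by
(score, start, end) — deterministic, leftmost on ties — and is verified
against an independent brute-force oracle in the tests. The hot path is
vectorised with numpy lookup tables; a 21-nt miRNA against a 1-kb
transcript with one gap allowed evaluates ~42 000 placements in ≈ 0.1 s.

## Synthetic data

The generator's defaults are the study conditions: read-length mixture
peaked at 24 nt (48 %) and 21 nt (20.9 %); class fractions miRNA 9.52 %,
rRNA 4.08 %, siRNA 8.85 %, snRNA 0.02 %, snoRNA 0.01 %, tRNA 3.17 %,
planted-hairpin reads 1 %, remainder unannotated background (≈ 74 %);
5 % low-quality reads and 3 % adapter-dimer reads so that ≈ 91 % of raw
reads survive cleanup; mutation rate 0 by default; star reads emitted
with probability 0.25; reads are 36 nt of insert + 3′-adapter
read-through (classic Solexa adapters as documented default constants). Reference sets are disjoint short
sequences (mature miRNAs 20–24 nt, named `syn-miR<family><member>` over
ten real plant family numbers with a steep power-law family skew);
classification recovery is exact because contaminant reads are verbatim
reference copies. Background reads are rejection-sampled against all
references.

Planted hairpins are seamless perfect stems, `stem5 + loop +
revcomp(stem5)` with `stem5 = ext5 + mature`: the star is the 3′-arm
substring implied by the duplex register with 2-nt 3′ overhangs (the
overhang bases stay paired inside the precursor, exactly as in real
pre-miRNAs), perturbed at up to two interior duplex positions. Loops
(8–40 nt) are A/C-biased so they cannot pair internally. Insert lengths
are drawn so most fall in the 75–188 nt band with a minority up to
~320 nt. This geometry folds unambiguously without consulting the
folding engine during generation, and planted hairpins are recovered at
100 % in the bundled tests (the acceptance bound is ≥ 95 %, leaving room
for folding-engine ambiguity on other engines or versions).

Planted target sites realise controlled defect lists (wobble positions,
mismatch positions, target insertions, all 1-based from the miRNA 5′
end); the declared ground-truth score is computed through the scoring
statistic itself, so recovery tests compare against exactly the quantity
the pipeline computes. Wobbles are only geometrically possible where the
miRNA base is G or U; requesting one elsewhere is an error.

What the generator does **not** model: platform-specific error and
quality profiles, expression noise within a class beyond the family
skew, imperfect natural hairpins (synthetic folding energies are
systematically more negative than natural precursors), genomic repeats,
or degradation fragments of mRNAs. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under clean conditions,
not robustness to the full messiness of real libraries.

## Problem sizes and numerics

Bundled tests run a 6 000-read shared simulation, a 100 000-read
recovery simulation (50 ESTs, 20 planted hairpins), 50 oracle-equivalence
pairs at 1 kb, and sub-second scoring fixtures; the whole suite completes
in about a minute on one CPU. Percentage tables are asserted to sum to
100 within 0.01. Score comparisons are exact (penalties are multiples of
0.5 and float-representable); folding energies are compared only as
signs, bands, or against the bundled reference table at its printed
precision. Determinism: every stochastic component takes a numpy
`Generator` or integer seed; identical configurations produce
byte-identical FASTQ/FASTA/TSV outputs.

## Known limitations

* Exact-match classification understates ncRNA classes relative to
  alignment-based annotation against Rfam; the siRNA class has no
  operational definition here.
* Precursor trimming from context windows is a package choice; published
  precursor-length ranges delimited by other conventions are reproduced
  from the bundled reference table, not from synthetic folding.
* The fallback folder is for dependency-light testing and engine
  cross-checks on unambiguous fixtures only.
* No conservation analysis, no suboptimal-structure or shuffling
  p-values, no target-site accessibility energies, and no downstream GO/
  pathway annotation.
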