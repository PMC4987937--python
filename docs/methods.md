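# Methods

## Scope and model of the problem

`crisprdesign` designs CRISPR guide RNAs against a supplied genome. The
design problem decomposes into five steps, each implemented as a separate
module behind a common pipeline driver:

1. **Enumeration** (`scan`). A target site for an effector with spacer length
   *L* and PAM pattern *P* (IUPAC-degenerate) is any genomic window of length
   *L* adjacent to a match of *P*, on either strand. The PAM is anchored 3'
   of the spacer for Cas9-type effectors and 5' for Cpf1-type; both cases are
   handled by one scanner parameterised on the anchor. The spacer is always
   reported 5'→3' as the sgRNA would read. Both the spacer and the PAM must
   lie fully inside the selected region (the stricter of the two defensible
   conventions; documented here because the choice is invisible in output).
2. **Scoring** (`scoring`). Four per-guide metrics, detailed below.
3. **Off-target counting** (`offtarget`). All genomic windows with a valid
   PAM whose spacer-length sequence is within Hamming distance ≤ 3 of the
   guide, bucketed by distance. Distance 3 is a hard default cap: predicted
   sites at four or more mismatches are overwhelmingly not cleaved, so they
   would only add noise to the report.
4. **Nickase pairing** (`nickase`). Opposite-strand, PAM-out pairs with an
   inter-protospacer gap of 10–31 bp, inclusive.
5. **Reporting** (`report`, `accessory`). Ranking, colors, restriction sites
   and flanking primers.

## Scoring metrics

**GC fraction** is computed over the spacer only (the PAM is excluded — the
rule concerns sgRNA composition, not target context). The "ideal" window is
40–80 % with *inclusive* bounds, tested in exact integer arithmetic
(`40·L ≤ 100·GC ≤ 80·L`) so boundary guides are never misflagged by float
rounding.

**PAM-proximal G.** The classical rule rewards a G at position 20 of a 20-nt
spacer — the PAM-adjacent base. For truncated or extended spacers of a
3'-anchored effector the check generalises to the final (PAM-adjacent) base;
for 5'-anchored effectors the PAM-proximal base is position 1 and the rule's
evidence base does not transfer, so the flag is reported as not applicable
rather than guessed.

**Self-complementarity** counts potential duplexes ("stems") of ≥ 4 bp
within the spacer and between the spacer and the invariant scaffold
(backbone), since such structures impair loading into the effector. A stem
is a maximal antiparallel run of consecutive base pairs; hairpin (intra-
spacer) stems additionally require ≥ 3 unpaired nucleotides between the two
halves. Counting is per *maximal* duplex — a contiguous 5-bp stem is one
stem, not two 4-bp windows; a repeat that can anneal in several shifted
registers contributes one stem per register, which is physically what a
homopolymeric G/C run can do. Pairing is Watson–Crick by default; a flag
adds G·T wobble. Widening the pairing alphabet adds stems on realistic
guides, but in contrived sequences a single wobble pair can bridge two
separate stems into one maximal duplex, reducing the count by one; the
wobble-monotonicity property test is therefore scoped to random guide-scale
inputs and this caveat is the reason. The default backbone is the standard
tracrRNA-derived scaffold, shipped as an editable resource
(`resources/backbone.txt`).

**Efficiency score.** A linear position-feature model: intercept plus the
sum of weights of features (1–2-nt k-mers at fixed offsets) that match the
guide's context window, optionally squashed through a logistic link. The
context window is `upstream + spacer + PAM + downstream` (default 4/20/3/3,
a 30-mer), and every model file carries its own window geometry so published
position-weight layouts with other flank sizes load unchanged. The file
format is TSV with `# key=value` headers (name, window, link, intercept) and
`offset⇥kmer⇥weight` rows. The bundled `models/example_linear.tsv` is a
synthetic demonstration of the format, not a published coefficient table;
published tables can be dropped in as resources. A model is refused when its
window geometry does not match the run (guide or PAM length), and a score is
reported unavailable when the context is truncated at a contig edge and a
feature would read N-padding.

## Off-target search

The searcher is exact, not heuristic. All PAM-adjacent windows on both
strands are collected once per genome; each window's spacer is split into
`max_mm + 1` non-overlapping seed fragments, so by pigeonhole any site
within `max_mm` mismatches agrees exactly with the query on at least one
fragment. Seed lookups produce a candidate set that is then verified by full
Hamming comparison. Guides too short to carry `max_mm + 1` seeds of ≥ 2 bp
fall back to scanning the full site list (still exact). Design decisions:

- Mismatches are counted over the spacer only; the PAM must satisfy the
  degenerate pattern exactly at any mismatch level (PAM recognition is a
  binding prerequisite).
- Sites containing N never match (assembly gaps must not produce hits).
- The guide's own locus is excluded by coordinate identity, not sequence: a
  second exact copy elsewhere is a genuine mm0 off-target.
- Counts are plain Hamming; no position-weighted penalty. A cleavage-
  probability scorer (CFD-style) is a named extension point, not
  implemented.

A fully independent naive scan (`naive_offtargets`) slides the guide over
every position of both strands; the test suite proves the indexed search
identical to it, and to a vectorised window-matrix oracle, on random
genomes.

## Nickase pairing

With a 3'-anchored PAM, a minus-strand guide carries its PAM at genomic left
and a plus-strand guide at genomic right, so `(left='-', right='+')` is the
PAM-out orientation. The pair offset is defined as the gap between the two
PAM-distal protospacer edges:

    offset = right.proto_start − left.proto_end

This measuring convention is stated in the module, in this note and in the
`nickase_pairs.tsv` header, because "binding within X bp" is ambiguous
without it. Accepted window: 10 ≤ offset ≤ 31, both bounds inclusive,
user-overridable. The reported break region is the inter-protospacer gap
`[left.proto_end, right.proto_start)` — the region strictly between the two
spacer spans, whose length equals the offset. (The two modeled nicks fall
3 bp inside each spacer; the break region deliberately reports the
intervening span rather than the nick-to-nick interval so that it never
overlaps either protospacer.)

Paired off-targets pair the two guides' single-guide hit lists exhaustively
(either guide may take either side), keep same-contig, opposite-strand,
PAM-out combinations within a separately configurable offset window
(default: the on-target window), and exclude the on-target pair itself.
Pairs are ranked by paired-off-target count, then summed single-guide
off-target counts, then mean efficiency.

## Ranking and colors

Specificity dominates efficiency: guides sort by (mm0, mm1, mm2, mm3)
ascending, then efficiency descending (unavailable scores sort last within a
tier), then stem count ascending, with genomic position as the final
deterministic tiebreak. Colors: **red** if any additional exact genomic
match exists (mm0 > 0); **green** if mm0 = mm1 = 0, GC is in the ideal
window and there are no stems; **amber** otherwise. The ordering and color
thresholds are this tool's own documented policy (constants in
`RankPolicy`), not a published formula.

## Accessories

Restriction sites are IUPAC-motif matches on both strands of the amplicon;
palindromic motifs are reported once per position, uniqueness is per enzyme
per amplicon, and sites overlapping the modeled cut are flagged for RFLP
validation. The bundled enzyme table is a small editable TSV of ~20 common
enzymes.

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia 2004
unified parameters, SantaLucia 1998 entropy salt correction at 50 mM Na+,
25 nM strands, via Biopython's `MeltingTemp.Tm_NN`); a hand-summed NN oracle
in the test suite pins the parameter set to 0.1 °C. Primer design is a
self-contained exhaustive scan — all left/right primers in the length band
18–25 nt and Tm band 57–63 °C whose product (200–600 bp) brackets the cut
with ≥ 50 bp margin on both sides — ranked by Tm balance, then closeness of
the product to the range midpoint. These defaults are this tool's own; all
are flag-overridable. Primer secondary-structure and dimer screening are
deliberately out of scope; an external Primer3-compatible engine can be
substituted through the same function signature.

Modeled cut positions are documented constants per effector: 3 bp inside
the spacer from the PAM for Cas9-types (blunt), 18 bp from the PAM-proximal
spacer end for Cpf1-types (staggered; the reference coordinate reported is
one strand's nick). They centre primers and flag RFLP sites and are
overridable in the preset table.

## Region modes

Gene models come from BED12. `whole` is the transcript span; `cds` and
`utr5`/`utr3` intersect exons with (or subtract) the thick interval,
strand-aware; `splice` takes ± 20 bp windows around every internal exon
boundary; `exon:K` is the K-th exon in transcript orientation; `promoter`
is 2000 bp upstream to 500 bp downstream of the TSS, strand-adjusted and
clipped at contig ends. The splice-flank and promoter windows are this
tool's defaults (overridable); the mode list follows standard practice for
sub-gene targeting.

## Synthetic data

`fixtures.make_fixture` generates the test substrate: a seeded random
genome (default 20 kb, 50 % GC) with planted features at well-separated
slots — on-target sites (random 20-mer + AGG), off-target copies of the
first guide at exact Hamming distances 0–6 (+ TGG), and PAM-out nickase
half-site pairs at chosen gaps. Every planted feature is recorded in a truth
table; the same seed yields byte-identical FASTA. What it emulates: site
recovery, mismatch bucketing, pairing-window behavior on a neutral
background. What it does not emulate: real genome repeat structure and
segmental duplication (which inflate off-target counts), biased base
composition, assembly gaps beyond simple Ns, and chromatin context. Passing
the planted-truth tests therefore demonstrates correctness of the search and
pairing logic, not genome-scale specificity characteristics of any real
organism. Background sequence can in principle contain spurious near-matches
to a planted guide; at 20-nt guide length and ≤ 50 kb genomes the expected
count is ≪ 1, which the recovery tests rely on.

Problem sizes used by the automated checks — 50 kb genomes and 200 guides
for search-equivalence, ~20 kb fixtures for end-to-end recovery — were
chosen as the smallest sizes at which every code path (seed collisions,
both strands, all mismatch buckets, window boundaries) is exercised with
margin.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; reports print 1-based
  inclusive.
- Non-ACGTN input characters become N with a logged count (warn, never
  guess); lowercase soft-masking is folded and ignored.
- A genomic N matches no PAM code, including N itself.
- IUPAC expansion refuses patterns > 12 nt (4^12 worst case).
- Candidate order, hit order, pair order and all output files are
  deterministic; float columns use fixed formats so repeat runs are
  byte-identical.
- Efficiency ties in ranking are broken by genomic position, never by dict
  order.

## Known limitations

- Off-target search is substitution-only; bulge (indel) off-targets are not
  modeled.
- No aggregate specificity score (MIT/CFD) and no SVM/tree-ensemble
  efficiency models; the linear position-feature interface is the supported
  surface.
- One transcript at a time; no isoform collapsing.
- The preset effector table (SpCas9 NGG/20, StCas9 NNAGAAW/20, SaCas9
  NNGRRT/21, NmCas9 NNNNGATT/24, AsCpf1 TTTN/5'/20) follows each effector's
  primary characterisation literature and is fully user-editable; alternate
  relaxed PAMs (e.g. NAG for SpCas9) are not searched unless the user
  supplies them as the run's PAM.
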