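# crisprdesign

A guide-design engine for CRISPR genome editing. Given a genome (FASTA) and
optionally gene models (BED12), it enumerates every candidate target site for
an effector — preset (SpCas9, StCas9, SaCas9, NmCas9, AsCpf1) or fully custom
(any IUPAC PAM anchored 5' or 3' of a spacer of any length ≥ 10 nt) — scores
each candidate, counts its genomic off-targets, optionally pairs Cas9-nickase
sites, and writes ranked, annotated designs as flat files. It is a library
first and a thin CLI on top.

## Who it is for

Anyone selecting sgRNAs for editing, knockout screens, dCas9
activation/repression (promoter mode) or paired-nickase strategies, who
wants a scriptable, deterministic, fully offline designer with inspectable
rules rather than a web service.

## What it computes

For a spacer *g* of length *L* with PAM pattern *P*:

- **Enumeration** — all windows on both strands where *P* (IUPAC-degenerate)
  matches adjacent to a full-length spacer, within the chosen region
  (whole/CDS/UTR/splice/exon/promoter sub-modes for gene models).
- **GC content** — (#G + #C)/L, flagged "ideal" within 40–80 % inclusive.
- **PAM-proximal G** — whether the PAM-adjacent spacer base (position 20 of
  a 20-mer) is G.
- **Self-complementarity** — the number of potential stems of ≥ 4 bp within
  the spacer and between the spacer and the sgRNA scaffold (hairpins need a
  ≥ 3 nt loop); stems impair effector loading.
- **Efficiency score** — a pluggable linear position-feature model
  (intercept + Σ matching k-mer weights over the ±flank context window,
  identity or logistic link), loaded from a simple TSV so published
  position-weight tables drop in. The bundled model is a synthetic format
  demonstration.
- **Off-targets** — every genomic site with a valid PAM within Hamming
  distance ≤ 3 of the spacer (exact seed-and-verify search, proven
  equivalent to a naive scan), bucketed as MM0–MM3; the guide's own locus is
  excluded by coordinate, so duplicated loci count.
- **Nickase pairs** — opposite-strand PAM-out candidates whose
  inter-protospacer gap (`right.proto_start − left.proto_end`) lies in
  10–31 bp inclusive, plus genome-wide *paired* off-targets: locations where
  off-target hits of the two guides again sit PAM-out within the window and
  could join into an unintended double-strand break.
- **Accessories** — restriction sites in the amplicon (with RFLP
  overlap-with-cut flag) and flanking primer pairs (nearest-neighbor Tm,
  product brackets the cut).

Guides are ranked specificity-first (MM0, MM1, MM2, MM3 ascending, then
efficiency descending, then stems), colored green/amber/red by a documented,
configurable policy.

## Worked example

Generate a small synthetic genome with planted features, then design guides
in its first 2 kb:

```
crisprdesign fixture --seed 7 --length 9000 --offtarget-mms 1,2 \
    --nickase-offsets 20 --out fx
crisprdesign design --fasta fx/fixture.fasta --target chrS:1-2000 \
    --out out --annotate-top 3
```

`out/results.tsv` begins:

```
rank  id           location        strand  protospacer           pam  gc_pct  selfcomp  efficiency  mm0  mm1  mm2  mm3  color  restriction_count  left_primer               right_primer             left_tm  right_tm  product_size
1     chrS_1833_+  chrS:1834-1853  +       GTATACTTGCCTCTTCTCGG  CGG  50.0    7         0.8744      0    0    0    0    amber  1                  CCCCTTAACCTTTGGCCATCACCG  CCGTGTTGTGGCAAAGTCATGCG  59.76    59.76     403
2     chrS_484_-   chrS:485-504    -       GAAGTGGATCGAGGAACGGG  AGG  60.0    2         0.8641      0    0    0    0    amber  5                  TCCCGACAGTCCGAACCATGCA    GCCGCCAGAGCGCAGTACTC     60.18    60.18     409
```

Reading row 1: the top-ranked guide targets the plus strand at
chrS:1834–1853 (1-based inclusive), spacer `GTATAC…TCGG` next to a CGG PAM;
GC is 50 % (ideal window), it forms 7 potential ≥ 4 bp stems with itself or
the scaffold, the bundled demonstration model scores it 0.87, and it has no
additional genomic matches at 0–3 mismatches (MM0–MM3 all zero, hence not
red; the stem count keeps it amber). One restriction site falls in the
annotated amplicon, and the best flanking primer pair (Tm-balanced to
0.01 °C, 403 bp product) is printed alongside. `targets.bed` holds the same
spans with rank as score, `guides.fasta` the spacers. `--mode nickase` adds
`nickase_pairs.tsv` with both guides of each PAM-out pair, their offset, the
break region and the paired-off-target count.

Every run is deterministic: identical inputs give byte-identical outputs.

## Library use

```python
from crisprdesign import (make_fixture, parse_pam, Region,
                          design_pipeline, pair_nicks)

fx = make_fixture(seed=7, length=9000, nickase_offsets=(20,))
pam = parse_pam("NGG", "3")
ranked, hits, index = design_pipeline(
    fx.genome, [Region("chrS", 0, 9000)], pam, guide_len=20)
pairs = pair_nicks([rg.candidate for rg in ranked])  # 10-31 bp window
```

## Layout

- `src/crisprdesign/seqio.py` — FASTA/BED12 I/O, regions, strand-aware extraction
- `src/crisprdesign/effectors.py` — PAM specs, IUPAC matching/expansion, presets
- `src/crisprdesign/scan.py` — region modes and guide enumeration
- `src/crisprdesign/scoring.py` — GC, G-check, stems, efficiency models
- `src/crisprdesign/offtarget.py` — seed-indexed exact search + naive oracle
- `src/crisprdesign/nickase.py` — pair window and paired off-targets
- `src/crisprdesign/accessory.py` — restriction sites, Tm, primer scan
- `src/crisprdesign/report.py` — ranking, colors, output files, pipeline driver
- `src/crisprdesign/fixtures.py` — seeded synthetic genomes with planted truth
- `src/crisprdesign/cli.py` — `crisprdesign design` / `crisprdesign fixture`
- `docs/methods.md` — modeling conventions, defaults and their rationale
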