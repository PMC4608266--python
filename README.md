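# lincmir

Genome-wide discovery and functional annotation of lincRNAs that act as
miRNA cleavage targets or as miRNA decoys (target mimics), in the style of
plant small-RNA target analysis:

- **duplex scan** — antiparallel complementarity alignment of mature miRNAs
  against transcripts (match +1 / G:U +0.5 / mismatch −1 / affine gaps),
  scored with a nearest-neighbor RNA/RNA hybridization energy and the
  site-to-perfect MFE ratio,
- **rule classification** — cleavage-target rule (≤1 mismatch/indel at miRNA
  positions 9–12, ≤4 defects elsewhere, no consecutive mismatches) versus the
  decoy rule (2–5 central defects, perfect pairing at positions 2–8, ≤4
  defects in the outer regions),
- **degradome validation** — PARE read preprocessing, 5′-end mapping,
  t-plots, cleavage categories 0–4 and positional-empirical p-values at the
  position opposite miRNA position 10 (with a 9–12 window fallback),
- **conservation** — 100-bp site windows, seeded ungapped homology search
  under a Karlin–Altschul E-value cutoff, progressive multiple alignment and
  a >80 % site-identity conservation call,
- **network assembly** — role-resolved miRNA–lincRNA–mRNA graph (a molecule
  can be the target of one miRNA and the decoy of another) with summaries,
  connected components and SIF/TSV export,
- **co-expression function transfer** — top-75 % variance filter, Pearson
  correlation with Fisher-z asymptotic p-values, Bonferroni correction,
  top/bottom-5 % correlation tails, one-sided Fisher-exact GO enrichment, and
  ceRNA-rule annotation of decoys,
- **synthetic data** — deterministic generators with recorded ground truth
  for every stage (implanted target/decoy sites, degradome peaks, correlated
  expression modules, GO modules, ortholog windows).

## CLI

```bash
lincmir run-all --out demo --seed 1      # synthetic data + full pipeline
lincmir simulate --out demo --seed 1     # individual stages:
lincmir scan --out demo
lincmir classify --out demo
lincmir validate-degradome --out demo
lincmir network --out demo
lincmir coexpress --out demo
lincmir annotate --out demo
lincmir conserve --out demo --orthologs windows.fa --site-start 40 --site-end 60
```

Stage outputs (TSV tables, SIF edge lists, JSON summaries and manifests with
input digests) are written into the run directory. A YAML config can pre-set
any flag (`lincmir --config cfg.yaml <stage>`); explicit flags win.

## Layout

```
src/lincmir/
  seq_io.py        FASTA/GFF3/TSV I/O, miRNA merging, intergenic filter
  duplex.py        site scan, nearest-neighbor MFE, MFE ratio
  classify.py      target/decoy rule engine
  degradome.py     PARE preprocessing, mapping, categories, p-values
  conservation.py  windows, homology search, alignment, conservation calls
  network.py       regulatory network, summaries, components
  coexpression.py  correlation edges, GO enrichment, function transfer
  synthetic.py     truth-tracked generators
  cli.py           click-based pipeline orchestration
tests/             unit, property and acceptance suites (+ brute-force oracles)
scripts/acceptance.py
```
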