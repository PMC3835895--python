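# tagdge

Tag-based digital gene expression (DGE) analysis, in the style of
NlaIII-anchored (SAGE-like) profiling: every tag is a 21-mer consisting of a
`CATG` anchor plus 17 downstream bases, counted as a proxy for transcript
abundance. The package provides a complete, seed-reproducible pipeline
exercised entirely on synthetic data with known ground truth:

- **`tagdge.simulate`** — synthetic unigene sets with controlled CATG-site
  content, multinomial tag libraries with spiked fold changes, per-base
  sequencing error, adapter/N contaminants, gene→term annotations with one
  deliberately enriched term, and constructed curation fixtures.
- **`tagdge.reference`** — the reference tag library: all `CATG`+17 21-mers
  of a transcriptome, indexed for exact lookup (sense-only by default, both
  strands optional).
- **`tagdge.quant`** — tag cleaning (adapter-only reads, N species,
  singletons), mapping with at most one mismatch (exact-match precedence,
  unambiguous = matches confined to a single gene), and TPM normalization
  (denominator: total clean tags by default, total unambiguous optional).
- **`tagdge.diffexpr`** — exact two-library test conditioning on the count
  in one library (doubled smaller tail, summed exactly in log space),
  Benjamini–Hochberg FDR, DEG calls at FDR ≤ 0.001 and |log2 ratio| ≥ 1,
  and cross-comparison intersection of common up/down genes.
- **`tagdge.enrichment`** — hypergeometric upper-tail term enrichment over
  an annotated background (Bonferroni-corrected P ≤ 0.05 for GO-style runs,
  BH Q ≤ 0.05 for KEGG-style runs).
- **`tagdge.curation`** — gene-family candidate filters: length < 400 bp,
  longest six-frame ATG-initiated ORF < 100 aa, and allelic-variant collapse
  by local-alignment identity (≥ 0.95 identity over ≥ 0.8 of the shorter
  sequence, single linkage, longest member kept).
- **`tagdge.pipeline` / `tagdge.cli`** — orchestration and the `tagdge`
  command-line interface.

## CLI

```bash
tagdge simulate --n-genes 2000 --library-size 1000000 --error-rate 0.01 \
    --n-up-spiked 100 --n-down-spiked 100 --seed 7 --out-dir out/sim
tagdge build-ref --fasta out/sim/unigenes.fasta --out out/ref.tsv
tagdge quant --tags out/sim/tags_control.tsv --ref out/ref.tsv \
    --name control --out-prefix out/control
tagdge quant --tags out/sim/tags_treated.tsv --ref out/ref.tsv \
    --name treated --out-prefix out/treated
tagdge de --control-expr out/control.expression.tsv --control-acct out/control.accounting.json \
    --treated-expr out/treated.expression.tsv --treated-acct out/treated.accounting.json \
    --out out/de.tsv
tagdge enrich --annotations out/sim/annotations.tsv --degs out/degs.txt --out out/enrich.tsv
tagdge curate --fasta family.fasta --out-prefix out/family
```

The full three-library design (control plus two treatments, with
intersection of common DEGs) runs from one YAML config:

```bash
tagdge run --config config.yaml --out-dir out/run
```

Every stochastic stage requires an explicit seed; rerunning with the same
config produces a byte-identical `summary.json`. See
`tests/test_cli.py::small_run_config` for a complete config example.

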