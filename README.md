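# tekit

Transposable-element (TE) copy analysis from pairwise copy-vs-consensus
alignments:

* **Age distributions** (`tekit.te_age`) — per-copy divergence from the
  family consensus, with substitutions shared between copies excluded as
  master-lineage changes, Jukes–Cantor correction, length/identity
  filtering, and percent-of-data histograms binned at 1% divergence.
* **DNA loss rates** (`tekit.dna_loss`) — small (≤30 bp) insertion/deletion
  accounting in decaying non-LTR retrotransposon copies, a chi-square
  codon-position screen against still-active families, homopolymer-indel
  flagging, and the pooled loss rate in bp per (JC-corrected) substitution.
* **Repeat landscapes** (`tekit.landscape`) — overlap-resolved per-label bp,
  percent-of-dataset, Gb-of-genome and sequencing-coverage summaries.
* **Synthetic data** (`tekit.synthetic_data`) — a master-gene TE family
  simulator (burst / exponential / two-burst age models, master-lineage
  substitutions with optional codon-position bias, geometric-size indels,
  read shredding) that emits exact alignments plus full ground truth, so
  every estimator is testable offline.
* **Alignment I/O** (`tekit.alignment_io`) — a canonical text alignment
  format (round-trip exact) and a best-effort RepeatMasker `.align` reader;
  minus-strand hits are stored reverse-complemented in consensus
  orientation.

## Command line

One entry point with subcommands:

```sh
tekit simulate --preset old_burst --seed 42 --out-dir sim/
tekit teage   --alignments sim/alignments.aln --family-map sim/family_map.tsv \
              --consensus sim/master.fasta --out hist.tsv --plot hist.png
tekit dnaloss --alignments sim/alignments.aln --consensus sim/master.fasta \
              --alpha 0.05 --indel-cap 30 --out loss.tsv
tekit landscape --annotations ann.tsv --dataset-bp 732630628 --genome-gb 55 \
              --out landscape.tsv
tekit init-config --out tekit.conf   # every threshold, with defaults
tekit run-all --config tekit.conf    # all stages + manifest.json
```

`run-all` writes a `manifest.json` recording the package version, the full
configuration (and which thresholds were overridden), SHA-256 digests of all
inputs, and per-stage counts; identical config + inputs reproduce outputs
byte-for-byte.

Alignment inputs are either the canonical format (`#aln` header line, gapped
copy row, gapped consensus row, blank-line separated) or RepeatMasker
`.align` files (auto-detected by extension, or forced with
`--format repeatmasker`). Landscape annotations are BED-like TSV
(`read_id  start  end  label  category`, 0-based half-open, category one of
`known_TE`, `unknown_repeat`, `simple_repeat`).

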