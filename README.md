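# delkit

Informatics for DNA-encoded library (DEL) screening: error-correcting
barcode design, combinatorial library enumeration, decoding of sequencing
reads into per-compound counts, and enrichment analysis — with a built-in
selection simulator so the whole pipeline can be exercised and validated
without wet-lab data.

A DEL couples each member of a combinatorial small-molecule library to a
DNA barcode that records its synthesis history (one building-block tag per
split-and-pool cycle). After affinity selection against a target, the
surviving barcodes are PCR-amplified and sequenced; turning those reads
back into compound identities and counts — *decoding* — and ranking
compounds by enrichment is the computational heart of a DEL campaign.
`delkit` is aimed at groups running their own selections who need an
open, scriptable alternative to vendor pipelines.

## What is inside

- **`delkit.barcodes`** — quaternary Hamming codes over GF(4) mapped onto
  the DNA alphabet (A=0, C=1, G=2, T=3). For any length *n* ∈ [7, 16] the
  non-parity code is a shortening of the [21, 18] GF(4) Hamming code
  (minimum distance 3: every single substitution is correctable via
  syndrome lookup, `d ≥ 2t+1`); parity mode draws the parity-check columns
  from an ovoid in PG(3, 4), certifying distance 4 (single-error
  correction **plus** guaranteed detection of any double error). A
  hash-map decoder handles legacy tag sets that follow no single code.
- **`delkit.config`** — library JSON / building-block CSV / selection YAML
  loading with full cross-validation and did-you-mean suggestions
  (Levenshtein distance ≤ 2) for misspelled keys and library ids.
- **`delkit.enumeration`** — batch or on-demand assembly of compound
  structures through a linear SMIRKS reaction scheme (RDKit), plus
  physicochemical descriptors.
- **`delkit.decode`** — the read-to-counts pipeline: semi-global
  (free-read-overhang) affine-gap alignment of the library tag and then of
  the full barcode schema (wildcards at variable positions score
  neutrally, so constant regions anchor the alignment), per-cycle tag
  error correction, UMI extraction, and mergeable count state. Output is
  the "cube" CSV of raw and UMI-corrected counts per compound and
  condition plus a categorical failure report (JSON + HTML).
- **`delkit.analysis`** — sampling depth, counts-per-million, one- and
  two-proportion z-scores, Poisson rate-ratio maximum-likelihood
  enrichment with Clopper–Pearson intervals, mono-/disynthon aggregation,
  replicate-overlap (Venn) counting, and a balanced random-forest-vs-dummy
  baseline for signal quality control.
- **`delkit.simulate`** — synthetic libraries and reads with exact ground
  truth (sampled compound, UMI, injected errors, orientation per read).

## Worked example

Simulate a selection from a synthetic 3-cycle library (24 blocks per
cycle, 8-bp distance-3 Hamming tags, 10-bp UMI) in which 1% of compounds
are true binders sampled at 10× the background weight, then decode and
rank:

```python
from delkit.simulate import (make_synthetic_library, simulate_selection,
                             planted_enrichment_weights)
from delkit.decode import run_decoding
from delkit.config import SelectionSpec, Condition
from delkit import analysis as an

lib = make_synthetic_library(n_cycles=3, blocks_per_cycle=24, seed=7)
sel = SelectionSpec("demo", [lib], [Condition("target", "1", [])])
w, hits = planted_enrichment_weights(lib, hit_fraction=0.01, fold=10.0, seed=7)
reads, truth = simulate_selection(lib, w, 50_000, sub_rate=0.005,
                                  indel_rate=0.001, seed=7)
cube, report, state = run_decoding(sel, reads_by_condition={"target/1": reads})
print(f"decoded {report.status_counts['decoded']}/{report.total_reads} reads "
      f"({100 * report.decoded_fraction:.1f}%)")
table = an.enrichment_table(cube, "target/1", library_size=lib.size)
print(table.nlargest(3, "zscore")[["compound_id", "count", "nsc", "zscore"]]
      .to_string(index=False))
```

prints

```
decoded 48715/50000 reads (97.4%)
          compound_id  count        nsc    zscore
SYN001-A020-B016-C013   47.0 964.795238 23.160683
SYN001-A007-B010-C013   46.0 944.267679 22.627960
SYN001-A024-B011-C023   45.0 923.740121 22.095237
```

97.4% of reads decode end to end at a 0.5% per-base substitution + 0.1%
indel rate (the rest are mostly tags with two substitutions, which a
distance-3 code flags rather than corrects). The z-score ranks each
compound's UMI-corrected count against the uniform null proportion
1/|library|; all three top-ranked compounds here are planted binders.

The same steps are available from the shell:

```sh
delkit design-barcodes --length 8 --count 96 --seed 5 --out barcodes.csv
delkit simulate --library lib.json --n-reads 50000 --sub-rate 0.005 \
    --seed 7 --out reads.fastq.gz
delkit decode --selection sel.yaml --out-dir out/
delkit analyze --cube out/cube.csv --condition target/1 --control NTC/1 \
    --synthon 1,2 --out-dir out/
```

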