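# pairsub

Batch comparison of pairwise protein alignments under many substitution
matrices.

`pairsub` aligns one protein pair — a *pattern* and a *subject* — once per
substitution-matrix/gap-penalty configuration and reports, per configuration:
the alignment score, four percent-identity variants (PID 1–4, differing in
their denominator), per-column substitution annotation (log-odds score,
conservative/non-conservative/neutral call, residue classification), indel
runs, identity regions and subsequence search results.  Configurations are
ranked per metric and min–max normalized so they can be compared directly
(rendered as a blue→red bar in the HTML report).

Ten standard matrices are bundled (PAM30/40/70/120/250 and
BLOSUM45/50/62/80/100, NCBI flat-format text under `src/pairsub/data/`).
Custom matrices are loaded through a *master file*: one matrix filename per
line followed by its space-delimited gap and extension penalties; repeated
filenames with different penalties are allowed, and configs are labelled
`CM0`, `CM1`, … in file order.

## CLI

```bash
pairsub --pattern pattern.fa --subject subject.fa \
        --predefined BLOSUM62:-10:-0.5,PAM70:-10:-0.5 \
        --custom master.txt \
        --mode local \
        --out report.json --tsv report.tsv --html report.html
```

Options of note:

- `--pattern-seq` / `--subject-seq` accept raw residue text instead of files.
- `--predefined NAME:gap_open:gap_extend[,…]` selects bundled matrices with
  per-matrix penalties; `--custom MASTER` adds custom-matrix configs.
- `--mode` is one of `global`, `local`, `overlap`, `global-local` (whole
  pattern vs a substring of the subject), `local-global` (whole subject vs a
  substring of the pattern).
- `--lenient` accepts extended residue codes (B/J/Z/X/U/O) and scores
  residues missing from a matrix as 0 with a warning.
- `--allow-identical` overrides the identical-sequences error.

Exit codes: 0 success, 2 input/validation error, 3 alignment failure.

Gap penalties are non-positive and added to the score; a gap run of length
L costs `gap_open + L * gap_extend` (the first gapped position pays both).

## Library

```python
import pairsub as ps

pattern, subject = ps.read_fasta(">p\nMKVAWEQ\n")[0], ps.read_fasta(">s\nMKVWEH\n")[0]
cfg = ps.MatrixConfig(matrix=ps.load_predefined("BLOSUM62"),
                      gap_open=-10, gap_extend=-0.5, label="B62")
report = ps.run_comparison(pattern, subject, [cfg], "global")
ps.write_report(report, "json", "report.json")
```

Modules: `seqio` (FASTA I/O and residue validation), `matrices`
(bundled/custom matrices, log-odds construction, conservation calls),
`align` (three-state affine-gap DP for the five modes, plus an exhaustive
enumeration oracle used by the tests), `metrics` (PID 1–4, column
annotation, residue classification schemes), `search` (indels, match
regions, subsequence hits, position lookup), `compare` (batch orchestration,
rankings, JSON/TSV/HTML reports), `fixtures` (seeded generators of random
sequences, mutated pairs, matrices and alignments for testing).

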