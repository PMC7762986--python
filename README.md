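# indelprofile

Indel-based fragment-length profiling of aligned non-coding DNA markers
for discriminating closely related species.

Many organellar non-coding regions (introns, intergenic spacers) are
rich in insertions/deletions. Given a multiple sequence alignment per
marker, this package locates the conserved anchor blocks, measures the
ungapped length of every hypervariable span between anchors, and turns
each specimen into a numeric length profile. It then quantifies how well
those profiles separate species:

- species-specific vs. shared profile counts (`Nsp`, `N`) and the
  frequency of species-specific profiles (`f_sp`),
- mismatch distributions (number of regions differing between every pair
  of specimens) and their means,
- the minimum region subset that discriminates all species (exhaustive),
- concatenated multi-marker analysis: statistics of every region
  combination, concatenated mismatch distributions, and a marker-pair
  discriminatory-potential matrix.

A simulator generates alignments with planted anchors, species-level
length effects and intraspecific indel noise, with full ground truth for
end-to-end testing.

## CLI

All subcommands are deterministic given their inputs and `--seed`.

```sh
# 1. synthetic panel: 13 species, 35 accessions, 4 markers
indelprofile simulate --seed 7 --out sim/

# 2. detect conserved anchor blocks in one marker alignment
indelprofile conserved --alignment sim/marker01.fasta --out regions01.tsv

# 3. length profiles for that marker
indelprofile profile --alignment sim/marker01.fasta --regions regions01.tsv \
    --metadata sim/metadata.tsv --out profiles01.tsv

# 4. per-marker statistics (JSON + TSV mirror)
indelprofile stats --profiles profiles01.tsv --conserved-count 4 --out stats01.json

# 5. concatenated multi-marker analysis
indelprofile concat --profiles profiles01.tsv --profiles profiles02.tsv \
    --out concat.json
```

`simulate` accepts a YAML config (`--config`; schema =
`SimulationConfig` fields, see `indelprofile/simulate.py`). `profile`
supports `--include-peripheral` to also measure the spans outside the
first/last anchor (they are flagged and excluded again by `concat`
unless `--include-peripheral` is passed there too).

Exit codes: 0 success, 1 data/validation error, 2 usage error.

## File formats

- Alignments: FASTA, equal-length records, gap character `-` only.
- Metadata: TSV with columns `sequence_id, accession, species,
  subspecies, marker` (subspecies may be empty).
- Regions: TSV with `marker, region_index, start, end, consensus`;
  coordinates are 0-based, half-open alignment columns.
- Profiles: TSV with `accession, species`, then one integer column per
  hypervariable region (missing = `NA`).
- Reports: JSON with a `schema_version` field and echoed parameters.

## Conventions

- Fragment lengths are ungapped residue counts inside a region span;
  `N` counts as a residue.
- `f_sp` is accession-weighted by default (fraction of specimens whose
  profile occurs in only one species); a species-level variant is
  available via `--fsp-definition species`.
- Pairwise comparisons are pairwise-complete: positions missing in
  either profile are skipped, and pairs with no comparable position are
  excluded from the distribution and reported separately.
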