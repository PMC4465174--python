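# semiperm

Multilocus analysis of semi-permeable species boundaries in hybridizing
species complexes. Given per-locus alignments of phased haplotypes and a
sample metadata table, the package computes per-population polymorphism
statistics, population divergence networks, a diagnostic-allele
introgression classifier with an introgression-vs-divergence trend test,
and sympatry-vs-allopatry polymorphism contrasts. A bundled
structured-coalescent simulator of secondary contact with locus-specific
permeability generates validation datasets with known truth.

## Modules

| module | contents |
| --- | --- |
| `semiperm.data_io` | FASTA/TSV readers and writers, haplotype-to-sample binding (`_a`/`_b` copy suffixes, bare IDs for mtDNA), sympatry labelling by basin co-occurrence, allele collapsing into per-population count tables |
| `semiperm.popgen_stats` | S, Hd, K, pi, Watterson's theta per locus and combined; Dxy, Da, Hudson FST matrices (complete deletion of gapped/ambiguous columns) |
| `semiperm.distance_clustering` | Saitou–Nei neighbor joining with deterministic tie-breaking, per-locus site-bootstrap support, newick output |
| `semiperm.introgression` | diagnostic-allele rule (shared only in sympatry, absent from the recipient's allopatric populations, present in the donor), conservative locus exclusion, per-pair introgression proportions, exact one-sided permutation test of the Spearman trend |
| `semiperm.comparative_tests` | Mann–Whitney U with tie-corrected z, Benjamini–Hochberg FDR, sympatric-vs-allopatric contrasts over the five polymorphism measures |
| `semiperm.synthetic_data` | backward-time structured coalescent (isolation with migration, secondary-contact intervals, per-locus permeability scalars, haploid mtDNA), infinite-sites mutations, phased-FASTA/metadata/truth-table output, toy fixtures |
| `semiperm.cli` | `semiperm` subcommand CLI and the full-pipeline runner with a JSON manifest |

## CLI

```sh
semiperm simulate --config sim.toml --out-dir data/        # synthetic dataset
semiperm stats -f data/nuc1.fasta -f data/mt.fasta --haploid mt \
    -m data/metadata.tsv -o stats.tsv
semiperm divergence -f ... -m ... --stat Dxy -o dxy.tsv
semiperm njtree -f ... -m ... --stat Da -B 100 --seed 1 -o tree.nwk
semiperm introgress -f ... -m ... --divergence-tsv data/divergence.tsv \
    --out-dir intro/
semiperm contrast -f ... -m ... -o contrasts.tsv
semiperm run-all --config run.toml --out bundle/ --seed 1
```

Exit codes: 0 success, 2 usage errors, 3 data errors, 4 numeric errors.

`run-all` expects a TOML config with `fasta = [...]`, `metadata = "..."`,
and optionally `divergence_tsv`, `haploid_loci`, `bootstrap`; it writes the
polymorphism table, the three divergence matrices, a bootstrapped NJ tree,
introgression calls/pair summaries/trend test, the sympatry contrasts, and
a `manifest.json` recording inputs (with digests), outputs and warnings.

Simulation configs are TOML with `seed` mandatory; see
`semiperm.synthetic_data.read_simulation_config` for the schema and
`barbel_like_config()` for a ready-made preset (4 species, 2 contact
basins, 4 nuclear loci with heterogeneous permeability, plus mtDNA).

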