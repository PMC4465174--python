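"""Reading/writing of locus alignments and sample metadata, sympatry
labelling, and collapsing of haplotype sequences into allele count tables.

Conventions
-----------
* One FASTA file per locus; sequences are uppercased on read and must be
  over ``{A, C, G, T, N, -}`` with identical lengths.
* Haplotype-ID dialect: nuclear gene copies are named ``<sample_id>_a`` and
  ``<sample_id>_b``; haploid (mtDNA) records use the bare ``sample_id``.
* The population unit is ``(species, basin)``; river and region are carried
  as metadata only.
* Allele identity is exact full-string equality, indels and N included.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    InputError,
    MetadataError,
    PloidyError,
    SchemaError,
)

ALPHABET = frozenset("ACGTN-")

Population = tuple[str, str]  # (species, basin)

SYMPATRIC = "sympatric"
ALLOPATRIC = "allopatric"


@dataclass(frozen=True)
class LocusAlignment:
    """Fixed-length aligned haplotype sequences for one locus."""

    locus_name: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise InputError(f"{self.locus_name}: empty alignment")
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length sequences")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise MetadataError(f"{self.locus_name}: duplicate record ID {dup!r}")
        for hid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"{self.locus_name}: record {hid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            for col, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"{self.locus_name}: illegal character {ch!r} in record "
                        f"{hid!r} at column {col}"
                    )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)

    def sequence(self, hid: str) -> str:
        try:
            return self.seqs[self.ids.index(hid)]
        except ValueError:
            raise MetadataError(f"{self.locus_name}: no record {hid!r}") from None

    def subset(self, ids: Sequence[str]) -> "LocusAlignment":
        keep = {i: s for i, s in zip(self.ids, self.seqs)}
        return LocusAlignment(
            self.locus_name,
            tuple(ids),
            tuple(keep[i] for i in ids),
        )


def read_locus_fasta(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read one per-locus FASTA into a :class:`LocusAlignment`.

    Sequences are uppercased; record IDs are preserved verbatim; the
    alignment length is taken from the first record and enforced.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise InputError(f"{path}: no FASTA records")
    return LocusAlignment(locus_name, tuple(ids), tuple(seqs))


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for hid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{hid}\n{seq}\n")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    basin: str
    river: str
    region: str


@dataclass
class SampleTable:
    """Per-sample species/basin/river metadata plus the haplotype copy map.

    ``copy_map`` maps ``(locus, haplotype_id) -> (sample_id, copy_index)``
    and is filled when alignments are bound via :meth:`bind_alignment`.
    """

    records: list[SampleRecord]
    copy_map: dict[tuple[str, str], tuple[str, int]] = field(default_factory=dict)
    haploid_loci: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise MetadataError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            if not rec.species or not rec.basin:
                raise MetadataError(
                    f"sample {rec.sample_id!r}: species and basin must be non-empty"
                )
        self._by_id = {rec.sample_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def sample(self, sample_id: str) -> SampleRecord:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise MetadataError(f"unknown sample {sample_id!r}") from None

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return out

    @property
    def populations(self) -> list[Population]:
        out: list[Population] = []
        for rec in self.records:
            pop = (rec.species, rec.basin)
            if pop not in out:
                out.append(pop)
        return out

    def samples_in(self, population: Population) -> list[SampleRecord]:
        return [
            r for r in self.records if (r.species, r.basin) == population
        ]

    def parse_haplotype_id(self, hid: str, haploid: bool = False) -> tuple[str, int]:
        """Resolve a FASTA record ID to ``(sample_id, copy_index)``.

        Nuclear copies carry ``_a``/``_b`` suffixes (copy 0/1); haploid
        records use the bare sample ID (copy 0).
        """
        if haploid:
            if hid in self._by_id:
                return hid, 0
            raise MetadataError(f"haploid record {hid!r} matches no sample")
        if "_" in hid:
            stem, suffix = hid.rsplit("_", 1)
            if stem in self._by_id:
                if suffix == "a":
                    return stem, 0
                if suffix == "b":
                    return stem, 1
                raise PloidyError(
                    f"record {hid!r}: copy suffix {suffix!r} exceeds diploid "
                    f"copies 'a'/'b' for sample {stem!r}"
                )
        raise MetadataError(f"record {hid!r} matches no sample")

    def bind_alignment(self, aln: LocusAlignment, haploid: bool = False) -> None:
        """Register every haplotype of ``aln`` in the copy map."""
        if haploid:
            self.haploid_loci.add(aln.locus_name)
        seen: dict[tuple[str, int], str] = {}
        bound_samples: set[str] = set()
        for hid in aln.ids:
            sample_id, copy = self.parse_haplotype_id(hid, haploid=haploid)
            key = (sample_id, copy)
            if key in seen:
                raise PloidyError(
                    f"{aln.locus_name}: records {seen[key]!r} and {hid!r} both "
                    f"claim copy {copy} of sample {sample_id}"
                )
            seen[key] = hid
            bound_samples.add(sample_id)
            self.copy_map[(aln.locus_name, hid)] = (sample_id, copy)
        if not haploid:
            for sid in bound_samples:
                if (sid, 0) in seen and (sid, 1) not in seen or (
                    (sid, 1) in seen and (sid, 0) not in seen
                ):
                    warnings.warn(
                        f"{aln.locus_name}: sample {sid} has only one gene copy",
                        stacklevel=2,
                    )

    def population_of_haplotype(self, locus: str, hid: str) -> Population:
        try:
            sample_id, _ = self.copy_map[(locus, hid)]
        except KeyError:
            raise MetadataError(
                f"haplotype {hid!r} at locus {locus!r} is not bound to a sample"
            ) from None
        rec = self._by_id[sample_id]
        return (rec.species, rec.basin)


METADATA_COLUMNS = ("sample_id", "species", "basin", "river", "region")


def read_metadata_tsv(path: str | Path) -> SampleTable:
    """Read the sample metadata table (TSV with a header row)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        records = [
            SampleRecord(
                row["sample_id"], row["species"], row["basin"],
                row["river"], row["region"],
            )
            for row in reader
        ]
    if not records:
        raise InputError(f"{path}: no sample rows")
    return SampleTable(records)


def write_metadata_tsv(samples: SampleTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for rec in samples.records:
            writer.writerow(
                [rec.sample_id, rec.species, rec.basin, rec.river, rec.region]
            )


@dataclass
class SympatryMap:
    """Sympatric/allopatric labels for every (species, basin) population.

    A population is sympatric iff at least two study species occur in its
    basin, unless an explicit (pair, basin, label) override says otherwise.
    """

    basin_species: dict[str, frozenset[str]]
    labels: dict[Population, str]
    pair_overrides: dict[tuple[frozenset[str], str], str] = field(default_factory=dict)
    override_log: list[tuple[str, str, str, str]] = field(default_factory=list)

    def label(self, species: str, basin: str) -> str:
        try:
            return self.labels[(species, basin)]
        except KeyError:
            raise MetadataError(f"no population ({species!r}, {basin!r})") from None

    def is_sympatric(self, species: str, basin: str) -> bool:
        return self.label(species, basin) == SYMPATRIC

    def pair_sympatric(self, species_a: str, species_b: str, basin: str) -> bool:
        key = (frozenset({species_a, species_b}), basin)
        if key in self.pair_overrides:
            return self.pair_overrides[key] == SYMPATRIC
        present = self.basin_species.get(basin, frozenset())
        return species_a in present and species_b in present

    def populations_of(self, species: str) -> list[Population]:
        return [pop for pop in self.labels if pop[0] == species]

    def allopatric_populations(self, species: str) -> list[Population]:
        return [
            pop for pop, lab in self.labels.items()
            if pop[0] == species and lab == ALLOPATRIC
        ]


def build_sympatry_map(
    samples: SampleTable,
    overrides: Iterable[tuple[str, str, str, str]] = (),
) -> SympatryMap:
    """Label every population sympatric/allopatric by basin co-occurrence.

    ``overrides`` are ``(species_a, species_b, basin, label)`` tuples; both
    species must occur in the named basin. Overrides are applied last and
    logged.
    """
    if not samples.records:
        raise InputError("empty sample table")
    basin_species: dict[str, set[str]] = {}
    for rec in samples.records:
        basin_species.setdefault(rec.basin, set()).add(rec.species)
    labels: dict[Population, str] = {}
    for species, basin in samples.populations:
        labels[(species, basin)] = (
            SYMPATRIC if len(basin_species[basin]) >= 2 else ALLOPATRIC
        )
    smap = SympatryMap(
        {b: frozenset(s) for b, s in basin_species.items()}, labels
    )
    for sp_a, sp_b, basin, label in overrides:
        if label not in (SYMPATRIC, ALLOPATRIC):
            raise MetadataError(f"override label {label!r} not recognised")
        if basin not in basin_species:
            raise MetadataError(f"override names unknown basin {basin!r}")
        for sp in (sp_a, sp_b):
            if sp not in basin_species[basin]:
                raise MetadataError(
                    f"override names species {sp!r} absent from basin {basin!r}"
                )
        smap.pair_overrides[(frozenset({sp_a, sp_b}), basin)] = label
        smap.labels[(sp_a, basin)] = label
        smap.labels[(sp_b, basin)] = label
        smap.override_log.append((sp_a, sp_b, basin, label))
    return smap


def read_sympatry_overrides_tsv(path: str | Path) -> list[tuple[str, str, str, str]]:
    cols = ("species_a", "species_b", "basin", "label")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in cols if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        return [tuple(row[c] for c in cols) for row in reader]  # type: ignore[misc]


@dataclass
class AlleleTable:
    """Distinct-allele registry with per-population copy counts for one locus."""

    locus_name: str
    alleles: dict[str, str]
    counts: dict[tuple[str, Population], int]
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def populations(self) -> list[Population]:
        out: list[Population] = []
        for _, pop in self.counts:
            if pop not in out:
                out.append(pop)
        return out

    def count(self, allele_id: str, population: Population) -> int:
        return self.counts.get((allele_id, population), 0)

    def population_total(self, population: Population) -> int:
        return sum(
            n for (aid, pop), n in self.counts.items() if pop == population
        )

    def alleles_in(self, population: Population) -> dict[str, int]:
        return {
            aid: n for (aid, pop), n in self.counts.items()
            if pop == population and n > 0
        }

    def species_alleles(self, species: str) -> dict[str, int]:
        """Pooled copy counts across all populations of one species."""
        out: dict[str, int] = {}
        for (aid, pop), n in self.counts.items():
            if pop[0] == species and n > 0:
                out[aid] = out.get(aid, 0) + n
        return out


def collapse_alleles(aln: LocusAlignment, samples: SampleTable) -> AlleleTable:
    """Collapse identical sequences into alleles with per-population counts.

    Allele identity is exact full-string equality (gaps and N included);
    allele IDs ``a1, a2, ...`` follow first occurrence in the alignment.
    """
    if not any(key[0] == aln.locus_name for key in samples.copy_map):
        samples.bind_alignment(aln, haploid=aln.locus_name in samples.haploid_loci)
    seq_to_id: dict[str, str] = {}
    alleles: dict[str, str] = {}
    counts: dict[tuple[str, Population], int] = {}
    members: dict[str, list[str]] = {}
    for hid, seq in zip(aln.ids, aln.seqs):
        pop = samples.population_of_haplotype(aln.locus_name, hid)
        aid = seq_to_id.get(seq)
        if aid is None:
            aid = f"a{len(seq_to_id) + 1}"
            seq_to_id[seq] = aid
            alleles[aid] = seq
            members[aid] = []
        members[aid].append(hid)
        counts[(aid, pop)] = counts.get((aid, pop), 0) + 1
    return AlleleTable(aln.locus_name, alleles, counts, members)


def write_allele_table_tsv(tables: Mapping[str, AlleleTable], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["locus", "allele_id", "species", "basin", "count", "sequence"])
        for locus in tables:
            tab = tables[locus]
            for (aid, (species, basin)), n in sorted(tab.counts.items()):
                writer.writerow([locus, aid, species, basin, n, tab.alleles[aid]])


def read_divergence_tsv(path: str | Path) -> dict[frozenset[str], float]:
    """Read the pairwise species-divergence table (p-distances)."""
    cols = ("species_a", "species_b", "p_distance")
    out: dict[frozenset[str], float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in cols if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        for row in reader:
            out[frozenset({row["species_a"], row["species_b"]})] = float(
                row["p_distance"]
            )
    return out


def write_divergence_tsv(
    divergences: Mapping[frozenset[str], float], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["species_a", "species_b", "p_distance"])
        for pair in sorted(divergences, key=sorted):
            a, b = sorted(pair)
            writer.writerow([a, b, f"{divergences[pair]:.6f}"])
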