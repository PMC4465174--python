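"""Structured-coalescent isolation-with-migration simulator with
locus-specific permeability, emitting phased FASTA + metadata with the
statistical structure the analysis pipeline assumes.

Model
-----
Backward in time, in coalescent units of 2N0 generations:

* lineages in deme d (a ``(species, basin)`` population) coalesce at rate
  C(k_d, 2) / size_d;
* during a secondary-contact interval (backward time t < start_time) each
  lineage in one of the two connected demes migrates to the other at rate
  M * s / 2, where M = 4N0 m and s is the locus permeability scalar;
* optionally, lineages migrate between conspecific demes at a total rate
  within_species_m / 2 per lineage (split evenly over target demes);
* at a species' split time all its lineages move to the ancestral species'
  single panmictic deme; haploid (mtDNA) loci scale deme sizes by 0.25.

Mutations follow the infinite-sites model: Poisson(theta/2 x branch length)
per branch, each at a distinct uniformly drawn column, ancestral state A.
Under panmixia this gives E[K] = theta and E[S] = theta * a_{n-1} exactly.

The pairwise species-divergence table is computed from a dedicated
zero-migration reference locus so the divergence axis is independent of
introgression at the analyzed loci.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_io import (
    LocusAlignment,
    SampleRecord,
    SampleTable,
    write_divergence_tsv,
    write_locus_fasta,
    write_metadata_tsv,
)
from .errors import ConfigError, SimulationError

ANCESTRAL_BASIN = "@anc"

DemeKey = tuple[str, str]  # (species, basin)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    length: int
    theta: float
    ploidy: str = "diploid"  # 'diploid' | 'haploid'
    permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.length < 1 or self.theta < 0 or self.permeability < 0:
            raise ConfigError(f"locus {self.name!r}: invalid length/theta/permeability")
        if self.ploidy not in ("diploid", "haploid"):
            raise ConfigError(f"locus {self.name!r}: ploidy {self.ploidy!r}")


@dataclass(frozen=True)
class SpeciesSplit:
    species: str
    parent: str
    time: float


@dataclass(frozen=True)
class DemeSpec:
    species: str
    basin: str
    size: float = 1.0


@dataclass(frozen=True)
class ContactEvent:
    species_a: str
    species_b: str
    basin: str
    start_time: float  # backward time at which secondary contact began
    M: float  # 4 N0 m


@dataclass
class SimulationConfig:
    splits: list[SpeciesSplit]
    demes: list[DemeSpec]
    contacts: list[ContactEvent]
    loci: list[LocusSpec]
    samples_per_deme: int | dict[DemeKey, int]
    seed: int
    within_species_m: float = 0.0
    ref_locus: LocusSpec = field(
        default_factory=lambda: LocusSpec("divergence_ref", 1000, 5.0, "diploid", 0.0)
    )

    def __post_init__(self) -> None:
        self.validate()

    def sample_count(self, deme: DemeKey) -> int:
        if isinstance(self.samples_per_deme, dict):
            return self.samples_per_deme[deme]
        return self.samples_per_deme

    def merge_time(self, species: str) -> float:
        for s in self.splits:
            if s.species == species:
                return s.time
        return math.inf

    def validate(self) -> None:
        leaf_species = {d.species for d in self.demes if d.basin != ANCESTRAL_BASIN}
        if not leaf_species:
            raise ConfigError("no sampled demes configured")
        split_children = [s.species for s in self.splits]
        if len(split_children) != len(set(split_children)):
            raise ConfigError("a species appears in more than one split")
        for s in self.splits:
            if s.time <= 0:
                raise ConfigError(f"split time for {s.species!r} must be positive")
            parent_merge = self.merge_time(s.parent)
            if parent_merge <= s.time:
                raise ConfigError(
                    f"{s.species!r} merges at {s.time} but its parent "
                    f"{s.parent!r} merges earlier ({parent_merge})"
                )
        for c in self.contacts:
            for sp in (c.species_a, c.species_b):
                if sp not in leaf_species:
                    raise ConfigError(f"contact names unknown species {sp!r}")
                if c.start_time >= self.merge_time(sp):
                    raise ConfigError(
                        f"contact in {c.basin!r} starts at {c.start_time}, not "
                        f"before the split time of {sp!r}"
                    )
            keys = {(c.species_a, c.basin), (c.species_b, c.basin)}
            have = {(d.species, d.basin) for d in self.demes}
            if not keys <= have:
                raise ConfigError(
                    f"contact in {c.basin!r} requires demes {sorted(keys)}"
                )
        if self.within_species_m < 0:
            raise ConfigError("within_species_m must be >= 0")

    def deme_size(self, deme: DemeKey) -> float:
        for d in self.demes:
            if (d.species, d.basin) == deme:
                return d.size
        if deme[1] == ANCESTRAL_BASIN:
            return 1.0
        raise ConfigError(f"unknown deme {deme}")


@dataclass
class GenealogyNode:
    time: float
    children: list["GenealogyNode"] = field(default_factory=list)
    tip_id: str | None = None
    n_tips: int = 1

    def tips(self) -> list["GenealogyNode"]:
        if self.tip_id is not None:
            return [self]
        out: list[GenealogyNode] = []
        for c in self.children:
            out.extend(c.tips())
        return out


@dataclass
class LineageRecord:
    tip_id: str
    sampled_deme: DemeKey
    migrant: bool
    origin_deme: DemeKey


@dataclass
class TruthTable:
    """Per-locus migrant flags and per-pair recent cross-coalescence fractions."""

    lineages: dict[str, list[LineageRecord]] = field(default_factory=dict)
    cross_fractions: dict[tuple[str, frozenset[str]], float] = field(
        default_factory=dict
    )

    def write_tsv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["locus", "tip_id", "species", "basin", "migrant",
                 "origin_species", "origin_basin"]
            )
            for locus, recs in self.lineages.items():
                for r in recs:
                    writer.writerow(
                        [locus, r.tip_id, r.sampled_deme[0], r.sampled_deme[1],
                         str(r.migrant).lower(), r.origin_deme[0], r.origin_deme[1]]
                    )
            writer.writerow([])
            writer.writerow(["locus", "species_a", "species_b", "recent_fraction"])
            for (locus, pair), frac in self.cross_fractions.items():
                a, b = sorted(pair)
                writer.writerow([locus, a, b, f"{frac:.6f}"])


class _Lineage:
    __slots__ = ("node", "deme", "migrated")

    def __init__(self, node: GenealogyNode, deme: DemeKey):
        self.node = node
        self.deme = deme
        self.migrated = False


def simulate_genealogy(
    config: SimulationConfig,
    locus: LocusSpec,
    samples: Mapping[DemeKey, Sequence[str]],
    rng: np.random.Generator,
) -> tuple[GenealogyNode, list[LineageRecord]]:
    """Simulate one locus genealogy under the structured coalescent.

    ``samples`` maps each deme to the tip (haplotype) IDs sampled there.
    Returns the root node (ultrametric in backward time) and per-tip
    lineage records for the truth table.
    """
    lineages: list[_Lineage] = []
    for deme, tips in samples.items():
        if config.deme_size(deme) <= 0 and tips:
            raise ConfigError(f"deme {deme} has zero size but sampled lineages")
        for tid in tips:
            lineages.append(_Lineage(GenealogyNode(0.0, tip_id=tid), deme))
    if len(lineages) < 2:
        raise ConfigError("need >= 2 sampled lineages")
    records = {
        lin.node.tip_id: LineageRecord(lin.node.tip_id, lin.deme, False, lin.deme)
        for lin in lineages
    }
    size_scale = 0.25 if locus.ploidy == "haploid" else 1.0
    merges = sorted(config.splits, key=lambda s: s.time)
    breakpoints = sorted(
        {s.time for s in config.splits} | {c.start_time for c in config.contacts}
    )
    species_demes: dict[str, list[DemeKey]] = {}
    for d in config.demes:
        if d.basin != ANCESTRAL_BASIN:
            species_demes.setdefault(d.species, []).append((d.species, d.basin))

    t = 0.0
    merged: set[str] = set()

    def contact_routes(now: float) -> dict[DemeKey, list[tuple[DemeKey, float]]]:
        routes: dict[DemeKey, list[tuple[DemeKey, float]]] = {}
        rate = locus.permeability / 2.0
        for c in config.contacts:
            if now < c.start_time and locus.permeability > 0:
                a = (c.species_a, c.basin)
                b = (c.species_b, c.basin)
                routes.setdefault(a, []).append((b, c.M * rate))
                routes.setdefault(b, []).append((a, c.M * rate))
        if config.within_species_m > 0:
            for sp, demes in species_demes.items():
                if sp in merged or len(demes) < 2:
                    continue
                per_target = config.within_species_m / 2.0 / (len(demes) - 1)
                for src in demes:
                    for dst in demes:
                        if dst != src:
                            routes.setdefault(src, []).append((dst, per_target))
        return routes

    while len(lineages) > 1:
        by_deme: dict[DemeKey, list[int]] = {}
        for idx, lin in enumerate(lineages):
            by_deme.setdefault(lin.deme, []).append(idx)
        coal: list[tuple[DemeKey, float]] = []
        for deme, members in by_deme.items():
            k = len(members)
            if k >= 2:
                size = config.deme_size(deme) * size_scale
                if size <= 0:
                    raise ConfigError(f"deme {deme} has zero size but lineages")
                coal.append((deme, k * (k - 1) / 2.0 / size))
        routes = contact_routes(t)
        migs: list[tuple[int, DemeKey, float, bool]] = []
        for idx, lin in enumerate(lineages):
            for dst, rate in routes.get(lin.deme, ()):  # contact + conspecific
                is_contact = dst[0] != lin.deme[0]
                migs.append((idx, dst, rate, is_contact))
        total = sum(r for _, r in coal) + sum(m[2] for m in migs)
        next_bp = next((b for b in breakpoints if b > t), None)
        if total <= 0.0:
            if next_bp is None:
                raise SimulationError(
                    "no events possible and no structural changes remain"
                )
            t = next_bp
        else:
            dt = rng.exponential(1.0 / total)
            if next_bp is not None and t + dt >= next_bp:
                t = next_bp
            else:
                t = t + dt
                u = rng.uniform(0.0, total)
                acc = 0.0
                chosen = None
                for deme, rate in coal:
                    acc += rate
                    if u < acc:
                        chosen = ("coal", deme)
                        break
                if chosen is None:
                    for idx, dst, rate, is_contact in migs:
                        acc += rate
                        if u < acc:
                            chosen = ("mig", idx, dst, is_contact)
                            break
                if chosen is None:  # numerical edge: attribute to the last event
                    if migs:
                        chosen = ("mig", migs[-1][0], migs[-1][1], migs[-1][3])
                    else:
                        chosen = ("coal", coal[-1][0])
                if chosen[0] == "coal":
                    deme = chosen[1]
                    members = by_deme[deme]
                    i, j = rng.choice(len(members), size=2, replace=False)
                    a, b = lineages[members[i]], lineages[members[j]]
                    parent = GenealogyNode(
                        t, children=[a.node, b.node],
                        n_tips=a.node.n_tips + b.node.n_tips,
                    )
                    parent.tip_id = None
                    for lin in (a, b):
                        if lin.node.tip_id is not None:
                            records[lin.node.tip_id].origin_deme = lin.deme
                    merged_lin = _Lineage(parent, deme)
                    keep = [
                        lin for k, lin in enumerate(lineages)
                        if k not in (members[i], members[j])
                    ]
                    keep.append(merged_lin)
                    lineages = keep
                else:
                    _, idx, dst, is_contact = chosen
                    lin = lineages[idx]
                    lin.deme = dst
                    if is_contact and lin.node.tip_id is not None:
                        records[lin.node.tip_id].migrant = True
                continue
        # structural changes scheduled exactly at t
        for split in merges:
            if split.time == t and split.species not in merged:
                target = (split.parent, ANCESTRAL_BASIN)
                for lin in lineages:
                    if lin.deme[0] == split.species:
                        lin.deme = target
                merged.add(split.species)
    root = lineages[0].node
    return root, [records[tip.tip_id] for tip in root.tips()]


def drop_mutations(
    root: GenealogyNode,
    theta: float,
    length: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Place infinite-sites mutations on the genealogy; return tip sequences."""
    branches: list[tuple[GenealogyNode, GenealogyNode]] = []

    def collect(node: GenealogyNode) -> None:
        for child in node.children:
            branches.append((node, child))
            collect(child)

    collect(root)
    n_mut = [
        int(rng.poisson(theta / 2.0 * (parent.time - child.time)))
        for parent, child in branches
    ]
    if sum(n_mut) > length:
        raise SimulationError(
            f"{sum(n_mut)} mutations exceed {length} columns; increase the "
            "locus length"
        )
    used: set[int] = set()
    bases = "CGT"
    per_branch: list[list[tuple[int, str]]] = []
    for count in n_mut:
        muts: list[tuple[int, str]] = []
        for _ in range(count):
            col = int(rng.integers(0, length))
            while col in used:  # collision -> resample
                col = int(rng.integers(0, length))
            used.add(col)
            muts.append((col, bases[int(rng.integers(0, 3))]))
        per_branch.append(muts)
    branch_muts = {id(child): muts for (_, child), muts in zip(branches, per_branch)}
    seqs: dict[str, str] = {}

    def paint(node: GenealogyNode, acquired: list[tuple[int, str]]) -> None:
        acquired = acquired + branch_muts.get(id(node), [])
        if node.tip_id is not None:
            seq = ["A"] * length
            for col, base in acquired:
                seq[col] = base
            seqs[node.tip_id] = "".join(seq)
        for child in node.children:
            paint(child, acquired)

    paint(root, [])
    return seqs


def _cross_coalescence_fractions(
    root: GenealogyNode, tip_species: Mapping[str, str],
    contacts: Sequence[ContactEvent],
) -> dict[frozenset[str], float]:
    contact_time = {
        frozenset({c.species_a, c.species_b}): c.start_time for c in contacts
    }
    events: dict[frozenset[str], list[float]] = {p: [] for p in contact_time}

    def walk(node: GenealogyNode) -> set[str]:
        if node.tip_id is not None:
            return {tip_species[node.tip_id]}
        sides = [walk(c) for c in node.children]
        for i in range(len(sides)):
            for j in range(i + 1, len(sides)):
                for a in sides[i]:
                    for b in sides[j]:
                        key = frozenset({a, b})
                        if key in events:
                            events[key].append(node.time)
        return set().union(*sides)

    walk(root)
    out: dict[frozenset[str], float] = {}
    for pair, times in events.items():
        if times:
            recent = sum(1 for x in times if x < contact_time[pair])
            out[pair] = recent / len(times)
        else:
            out[pair] = 0.0
    return out


@dataclass
class SimulatedDataset:
    alignments: dict[str, LocusAlignment]
    samples: SampleTable
    divergence: dict[frozenset[str], float]
    truth: TruthTable
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for locus, aln in self.alignments.items():
            p = outdir / f"{locus}.fasta"
            write_locus_fasta(aln, p)
            paths[f"fasta:{locus}"] = p
        paths["metadata"] = outdir / "metadata.tsv"
        write_metadata_tsv(self.samples, paths["metadata"])
        paths["divergence"] = outdir / "divergence.tsv"
        write_divergence_tsv(self.divergence, paths["divergence"])
        paths["truth"] = outdir / "truth.tsv"
        self.truth.write_tsv(paths["truth"])
        return paths


def _sampled_demes(config: SimulationConfig) -> list[DemeKey]:
    return [
        (d.species, d.basin) for d in config.demes if d.basin != ANCESTRAL_BASIN
    ]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate all loci plus the divergence reference locus.

    Deterministic given (config, seed): same inputs give byte-identical
    FASTA output.
    """
    rng = np.random.default_rng(config.seed)
    demes = _sampled_demes(config)
    records: list[SampleRecord] = []
    sample_ids: dict[DemeKey, list[str]] = {}
    for species, basin in demes:
        ids = [
            f"{species}-{basin}-{i + 1:02d}"
            for i in range(config.sample_count((species, basin)))
        ]
        sample_ids[(species, basin)] = ids
        for sid in ids:
            records.append(SampleRecord(sid, species, basin, f"{basin}-river", "sim"))
    samples = SampleTable(records)
    truth = TruthTable()
    alignments: dict[str, LocusAlignment] = {}
    tip_species_cache: dict[str, str] = {}

    def run_locus(locus: LocusSpec) -> LocusAlignment:
        tips: dict[DemeKey, list[str]] = {}
        for deme, sids in sample_ids.items():
            if locus.ploidy == "haploid":
                tips[deme] = list(sids)
            else:
                tips[deme] = [f"{sid}_{c}" for sid in sids for c in ("a", "b")]
            for tid in tips[deme]:
                tip_species_cache[tid] = deme[0]
        root, lineage_records = simulate_genealogy(config, locus, tips, rng)
        seqs = drop_mutations(root, locus.theta, locus.length, rng)
        ordered = [tid for deme in sample_ids for tid in tips[deme]]
        truth.lineages[locus.name] = lineage_records
        for pair, frac in _cross_coalescence_fractions(
            root, tip_species_cache, config.contacts
        ).items():
            truth.cross_fractions[(locus.name, pair)] = frac
        return LocusAlignment(
            locus.name, tuple(ordered), tuple(seqs[t] for t in ordered)
        )

    for locus in config.loci:
        aln = run_locus(locus)
        alignments[locus.name] = aln
        samples.bind_alignment(aln, haploid=locus.ploidy == "haploid")

    ref_aln = run_locus(config.ref_locus)
    divergence: dict[frozenset[str], float] = {}
    by_species: dict[str, list[str]] = {}
    for hid, seq in zip(ref_aln.ids, ref_aln.seqs):
        by_species.setdefault(tip_species_cache[hid], []).append(seq)
    species_list = sorted(by_species)
    for i in range(len(species_list)):
        for j in range(i + 1, len(species_list)):
            sx = by_species[species_list[i]]
            sy = by_species[species_list[j]]
            L = config.ref_locus.length
            diffs = [
                sum(a != b for a, b in zip(x, y)) / L for x in sx for y in sy
            ]
            divergence[frozenset({species_list[i], species_list[j]})] = float(
                np.mean(diffs)
            )
    return SimulatedDataset(alignments, samples, divergence, truth, config)


def barbel_like_config(
    seed: int = 1,
    samples_per_deme: int = 6,
    permeabilities: Sequence[float] = (0.1, 1.0, 1.0, 0.1),
    contact_m: float = 2.0,
    theta: float = 5.0,
) -> SimulationConfig:
    """Preset mirroring the target data shape: 4 species, 2 contact basins,
    4 nuclear loci with heterogeneous permeability, plus an mtDNA locus."""
    species = ["sp1", "sp2", "sp3", "sp4"]
    splits = [
        SpeciesSplit("sp1", "anc12", 3.0),
        SpeciesSplit("sp2", "anc12", 3.0),
        SpeciesSplit("sp3", "anc34", 3.0),
        SpeciesSplit("sp4", "anc34", 3.0),
        SpeciesSplit("anc12", "root", 6.0),
        SpeciesSplit("anc34", "root", 6.0),
    ]
    demes = [
        DemeSpec("sp1", "basinA"), DemeSpec("sp2", "basinA"),
        DemeSpec("sp3", "basinB"), DemeSpec("sp4", "basinB"),
        DemeSpec("sp1", "refugium1"), DemeSpec("sp2", "refugium2"),
        DemeSpec("sp3", "refugium3"), DemeSpec("sp4", "refugium4"),
    ]
    contacts = [
        ContactEvent("sp1", "sp2", "basinA", 0.5, contact_m),
        ContactEvent("sp3", "sp4", "basinB", 0.5, contact_m),
    ]
    loci = [
        LocusSpec(f"nuc{i + 1}", 1000, theta, "diploid", s)
        for i, s in enumerate(permeabilities)
    ]
    loci.append(LocusSpec("mt", 800, theta, "haploid", 1.0))
    return SimulationConfig(
        splits=splits,
        demes=demes,
        contacts=contacts,
        loci=loci,
        samples_per_deme=samples_per_deme,
        seed=seed,
        within_species_m=1.0,
    )


def species_pair_config(
    seed: int,
    split_time: float,
    contact_m: float,
    n_diploids: int = 10,
    n_loci: int = 4,
    locus_length: int = 1000,
    theta: float = 5.0,
    contact_start: float = 0.5,
    species: tuple[str, str] = ("spA", "spB"),
    within_species_m: float = 2.0,
    contact_basins: int = 1,
    contact_deme_size: float = 1.0,
    allo_deme_size: float = 1.0,
) -> SimulationConfig:
    """Two hybridizing species with one allopatric refuge each and one or
    more shared contact basins (named ``contact``, or ``contact1..k``).

    The divergence reference locus is haploid (mtDNA-like), which keeps
    the divergence axis's genealogical variance low.
    """
    a, b = species
    splits = [
        SpeciesSplit(a, "anc", split_time),
        SpeciesSplit(b, "anc", split_time),
    ]
    basins = (
        ["contact"] if contact_basins == 1
        else [f"contact{k + 1}" for k in range(contact_basins)]
    )
    demes = []
    contacts = []
    for basin in basins:
        demes += [
            DemeSpec(a, basin, contact_deme_size),
            DemeSpec(b, basin, contact_deme_size),
        ]
        contacts.append(ContactEvent(a, b, basin, contact_start, contact_m))
    demes += [
        DemeSpec(a, f"allo-{a}", allo_deme_size),
        DemeSpec(b, f"allo-{b}", allo_deme_size),
    ]
    loci = [
        LocusSpec(f"nuc{i + 1}", locus_length, theta, "diploid", 1.0)
        for i in range(n_loci)
    ]
    return SimulationConfig(
        splits=splits,
        demes=demes,
        contacts=contacts,
        loci=loci,
        samples_per_deme=n_diploids,
        seed=seed,
        within_species_m=within_species_m,
        ref_locus=LocusSpec("divergence_ref", locus_length, theta, "haploid", 0.0),
    )


def read_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from TOML; ``seed`` is mandatory."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "seed" not in raw:
        raise ConfigError(f"{path}: 'seed' is mandatory")
    try:
        splits = [SpeciesSplit(**s) for s in raw.get("splits", [])]
        demes = [DemeSpec(**d) for d in raw["demes"]]
        contacts = [ContactEvent(**c) for c in raw.get("contacts", [])]
        loci = [LocusSpec(**l) for l in raw["loci"]]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    kwargs = {}
    if "ref_locus" in raw:
        kwargs["ref_locus"] = LocusSpec(
            raw["ref_locus"].get("name", "divergence_ref"),
            raw["ref_locus"]["length"],
            raw["ref_locus"]["theta"],
            raw["ref_locus"].get("ploidy", "diploid"),
            raw["ref_locus"].get("permeability", 0.0),
        )
    return SimulationConfig(
        splits=splits,
        demes=demes,
        contacts=contacts,
        loci=loci,
        samples_per_deme=raw["samples_per_deme"],
        seed=raw["seed"],
        within_species_m=raw.get("within_species_m", 0.0),
        **kwargs,
    )


ZERO_VARIATION_FASTA = """\
>S1_a
ACGTACGTAC
>S1_b
ACGTACGTAC
>S2_a
ACGTACGTAC
>S2_b
ACGTACGTAC
>S3_a
ACGTACGTAC
>S3_b
ACGTACGTAC
>S4_a
ACGTACGTAC
>S4_b
ACGTACGTAC
"""

ZERO_VARIATION_METADATA = """\
sample_id\tspecies\tbasin\triver\tregion
S1\talpha\tG\tG-river\tsim
S2\talpha\tG\tG-river\tsim
S3\tbeta\tG\tG-river\tsim
S4\tbeta\tG\tG-river\tsim
"""

FIG9_RANKS_TSV = """\
species_a\tspecies_b\tp_distance\tproportion
sp1\tsp2\t0.010\t0.40
sp2\tsp3\t0.020\t0.30
sp3\tsp4\t0.030\t0.20
sp1\tsp4\t0.040\t0.10
"""

FST_THIRD_FASTA = """\
>X1_a
AAAA
>X1_b
AAAT
>Y1_a
TAAA
>Y1_b
TAAT
"""

FST_THIRD_METADATA = """\
sample_id\tspecies\tbasin\triver\tregion
X1\txpop\tG\tG-river\tsim
Y1\typop\tT\tT-river\tsim
"""


def make_toy_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the byte-stable micro-datasets used by the unit tests."""
    outdir = Path(outdir)
    out: dict[str, Path] = {}
    zv = outdir / "zero_variation"
    zv.mkdir(parents=True, exist_ok=True)
    (zv / "locus1.fasta").write_text(ZERO_VARIATION_FASTA)
    (zv / "metadata.tsv").write_text(ZERO_VARIATION_METADATA)
    out["zero_variation"] = zv
    f9 = outdir / "fig9_ranks"
    f9.mkdir(parents=True, exist_ok=True)
    (f9 / "trend.tsv").write_text(FIG9_RANKS_TSV)
    out["fig9_ranks"] = f9
    ft = outdir / "fst_third"
    ft.mkdir(parents=True, exist_ok=True)
    (ft / "locus1.fasta").write_text(FST_THIRD_FASTA)
    (ft / "metadata.tsv").write_text(FST_THIRD_METADATA)
    out["fst_third"] = ft
    return out
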