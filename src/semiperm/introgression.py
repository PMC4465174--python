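"""Diagnostic-allele introgression scoring between sympatric species pairs
and the introgression-vs-divergence trend test.

The classification rule, applied per locus and per direction within one
basin where species A and B co-occur: an allele carried by A's sympatric
population is called introgressed (B -> A) iff it is absent from every
allopatric population of A while present in at least one population of B.
A locus is conservatively excluded for a pair when either species has no
allopatric reference population and is monomorphic at that locus (ancestral
retention and complete replacement cannot be told apart there).

The trend test is a one-sided exact permutation test of the Spearman rank
correlation under the negative-association alternative, computed with
rational arithmetic over all n! rank permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import AlleleTable, Population, SympatryMap
from .errors import InputError, UnresolvedAncestryError, UsageError

Pair = tuple[str, str]


@dataclass(frozen=True)
class IntrogressionCall:
    """One allele judged introgressed from donor into recipient."""

    recipient: str
    donor: str
    basin: str
    locus: str
    allele_id: str
    copies_in_recipient_sympatric: int
    present_in_recipient_allopatric: bool  # always False for emitted calls
    presence_in_donor: str  # 'sympatric' | 'allopatric' | 'both'

    def __post_init__(self) -> None:
        if self.present_in_recipient_allopatric:
            raise InputError("call violates the allopatric-absence clause")
        if self.copies_in_recipient_sympatric < 1:
            raise InputError("call must cover >= 1 gene copy")


@dataclass
class PairIntrogressionSummary:
    pair: Pair
    basin: str
    loci_included: list[str]
    loci_excluded: dict[str, str]
    introgressed_copies: int
    total_copies: int
    proportion: float
    divergence: float | None = None


@dataclass(frozen=True)
class TrendResult:
    n_pairs: int
    rho: float
    p_exact: float
    r2: float
    p_fraction: Fraction | None = None

    def p_truncated(self, places: int = 4) -> float:
        scale = 10 ** places
        return math.floor(self.p_exact * scale) / scale


def _donor_presence(
    table: AlleleTable, allele_id: str, donor: str, smap: SympatryMap
) -> str | None:
    """Where the donor carries the allele: sympatric/allopatric/both/None."""
    in_symp = in_allo = False
    for (aid, pop), n in table.counts.items():
        if aid != allele_id or pop[0] != donor or n <= 0:
            continue
        if smap.is_sympatric(*pop):
            in_symp = True
        else:
            in_allo = True
    if in_symp and in_allo:
        return "both"
    if in_symp:
        return "sympatric"
    if in_allo:
        return "allopatric"
    return None


def classify_diagnostic_alleles(
    pair: Pair,
    basin: str,
    allele_tables: Mapping[str, AlleleTable],
    sympatry_map: SympatryMap,
    exclusions: Mapping[str, str] | None = None,
) -> list[IntrogressionCall]:
    """Apply the diagnostic-allele rule in both directions for one pair.

    Emits a B->A call for every allele with copies in A's sympatric
    population in ``basin`` that has zero copies in every allopatric
    population of A and >= 1 copy in any population of B (and
    symmetrically for A->B). Loci in ``exclusions`` are skipped.
    """
    sp_a, sp_b = pair
    if not sympatry_map.pair_sympatric(sp_a, sp_b, basin):
        raise UsageError(f"{sp_a} and {sp_b} are not sympatric in basin {basin!r}")
    exclusions = exclusions or {}
    calls: list[IntrogressionCall] = []
    for locus, table in allele_tables.items():
        if locus in exclusions:
            continue
        for recipient, donor in ((sp_a, sp_b), (sp_b, sp_a)):
            allo_pops = [
                pop for pop in sympatry_map.allopatric_populations(recipient)
                if pop in table.populations
            ]
            if not allo_pops:
                raise UnresolvedAncestryError(
                    f"{recipient} has no allopatric population at locus "
                    f"{locus!r}; apply the locus-exclusion rule"
                )
            symp_pop: Population = (recipient, basin)
            for aid, copies in table.alleles_in(symp_pop).items():
                in_allo = any(table.count(aid, pop) > 0 for pop in allo_pops)
                if in_allo:
                    continue
                presence = _donor_presence(table, aid, donor, sympatry_map)
                if presence is None:
                    continue
                calls.append(
                    IntrogressionCall(
                        recipient=recipient,
                        donor=donor,
                        basin=basin,
                        locus=locus,
                        allele_id=aid,
                        copies_in_recipient_sympatric=copies,
                        present_in_recipient_allopatric=False,
                        presence_in_donor=presence,
                    )
                )
    return calls


def exclude_loci_for_pair(
    pair: Pair,
    allele_tables: Mapping[str, AlleleTable],
    sympatry_map: SympatryMap,
    manual: Iterable[str] = (),
) -> dict[str, str]:
    """Loci to drop for this pair, with reasons.

    Auto-exclusion: either species has no allopatric population in the data
    AND is monomorphic at the locus (its introgression status cannot be
    resolved there). Manual exclusions are always honored.
    """
    out: dict[str, str] = {locus: "manual" for locus in manual}
    for locus, table in allele_tables.items():
        if locus in out:
            continue
        for species in pair:
            has_allo = any(
                pop in table.populations
                for pop in sympatry_map.allopatric_populations(species)
            )
            if has_allo:
                continue
            pooled = table.species_alleles(species)
            if len(pooled) <= 1:
                out[locus] = (
                    f"auto: {species} has no allopatric population and is "
                    f"monomorphic at {locus}"
                )
                break
    return out


def introgression_proportion(
    pair: Pair,
    basin: str,
    calls: Sequence[IntrogressionCall],
    allele_tables: Mapping[str, AlleleTable],
    exclusions: Mapping[str, str] | None = None,
    divergence: float | None = None,
    denominator: str = "copies",
) -> PairIntrogressionSummary:
    """Pooled-direction introgression proportion for one pair and basin.

    Default denominator: total gene copies sampled in both species'
    sympatric populations across included loci. ``denominator='alleles'``
    instead counts distinct alleles per population per locus.
    """
    exclusions = dict(exclusions or {})
    included = [loc for loc in allele_tables if loc not in exclusions]
    pops = [(pair[0], basin), (pair[1], basin)]
    if denominator == "copies":
        total = sum(
            allele_tables[loc].population_total(pop)
            for loc in included for pop in pops
        )
        numer = sum(
            c.copies_in_recipient_sympatric
            for c in calls if c.locus in included and c.basin == basin
        )
    elif denominator == "alleles":
        total = sum(
            len(allele_tables[loc].alleles_in(pop))
            for loc in included for pop in pops
        )
        numer = sum(
            1 for c in calls if c.locus in included and c.basin == basin
        )
    else:
        raise UsageError(f"unknown denominator mode {denominator!r}")
    if total == 0:
        raise InputError(f"pair {pair} in basin {basin!r}: no gene copies sampled")
    return PairIntrogressionSummary(
        pair=pair,
        basin=basin,
        loci_included=included,
        loci_excluded=exclusions,
        introgressed_copies=numer,
        total_copies=total,
        proportion=numer / total,
        divergence=divergence,
    )


def _midranks(values: Sequence[float]) -> list[Fraction]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks: list[Fraction] = [Fraction(0)] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = Fraction(i + j + 2, 2)  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _rank_rho(rx: Sequence[Fraction], ry: Sequence[Fraction]) -> float:
    """Spearman rho as the Pearson correlation of (mid-)ranks."""
    n = len(rx)
    mx = sum(rx, Fraction(0)) / n
    my = sum(ry, Fraction(0)) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        raise InputError("rank correlation undefined: a variable is constant")
    return float(cov) / math.sqrt(float(vx) * float(vy))


def introgression_divergence_trend(
    summaries: Sequence[PairIntrogressionSummary] | Sequence[tuple[float, float]],
    max_exact_n: int = 10,
) -> TrendResult:
    """Exact one-sided trend test of introgression proportion vs divergence.

    rho is the (mid-rank) Spearman correlation; p_exact is the fraction of
    all n! permutations of the proportion ranks with rho <= the observed
    value (negative-association alternative); r2 is the squared Pearson
    correlation of the raw values.
    """
    pairs: list[tuple[float, float]] = []
    for item in summaries:
        if isinstance(item, PairIntrogressionSummary):
            if item.divergence is None:
                raise InputError(f"pair {item.pair}: divergence value missing")
            pairs.append((item.divergence, item.proportion))
        else:
            pairs.append((float(item[0]), float(item[1])))
    n = len(pairs)
    if n < 3:
        raise InputError(f"trend test needs >= 3 pairs, got {n}")
    if n > max_exact_n:
        raise InputError(
            f"{n} pairs exceeds the exact-permutation limit ({max_exact_n}); "
            "opt into a large-n approximation explicitly"
        )
    div = [d for d, _ in pairs]
    prop = [p for _, p in pairs]
    rx = _midranks(div)
    ry = _midranks(prop)
    rho = _rank_rho(rx, ry)
    # rho is an increasing affine function of S = sum(rx * ry_perm) because
    # rank means/variances are permutation-invariant; compare S exactly.
    s_obs = sum(a * b for a, b in zip(rx, ry))
    count = 0
    total = 0
    for perm in permutations(ry):
        total += 1
        if sum(a * b for a, b in zip(rx, perm)) <= s_obs:
            count += 1
    p_frac = Fraction(count, total)
    dv = np.asarray(div, dtype=float)
    pv = np.asarray(prop, dtype=float)
    if dv.std() == 0 or pv.std() == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(dv, pv)[0, 1] ** 2)
    return TrendResult(
        n_pairs=n, rho=rho, p_exact=float(p_frac), r2=r2, p_fraction=p_frac
    )


def pair_summary_from_alignments(
    alignments,
    samples,
    pair: Pair,
    basin: str,
    divergence: float | None = None,
    manual_exclusions: Iterable[str] = (),
    denominator: str = "copies",
) -> tuple[PairIntrogressionSummary, list[IntrogressionCall]]:
    """End-to-end convenience: collapse alleles, build the sympatry map,
    apply the exclusion rule and the classifier, and summarize one pair.

    Haploid (mtDNA) loci registered on ``samples`` are left out of the
    proportion, which covers nuclear alleles only.
    """
    from .data_io import build_sympatry_map, collapse_alleles

    smap = build_sympatry_map(samples)
    tables = {
        name: collapse_alleles(aln, samples)
        for name, aln in alignments.items()
        if name not in samples.haploid_loci
    }
    exclusions = exclude_loci_for_pair(pair, tables, smap, manual=manual_exclusions)
    calls = classify_diagnostic_alleles(pair, basin, tables, smap, exclusions)
    summary = introgression_proportion(
        pair, basin, calls, tables, exclusions,
        divergence=divergence, denominator=denominator,
    )
    return summary, calls


def write_calls_tsv(calls: Sequence[IntrogressionCall], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "basin", "species_A", "species_B", "direction", "locus",
                "allele_id", "copies", "present_in_A_allopatric",
                "presence_in_B",
            ]
        )
        for c in calls:
            writer.writerow(
                [
                    c.basin, c.recipient, c.donor, f"{c.donor}->{c.recipient}",
                    c.locus, c.allele_id, c.copies_in_recipient_sympatric,
                    str(c.present_in_recipient_allopatric).lower(),
                    c.presence_in_donor,
                ]
            )


def write_pair_summaries_tsv(
    summaries: Sequence[PairIntrogressionSummary], path
) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "pair", "basin", "proportion", "introgressed_copies",
                "total_copies", "divergence", "loci_excluded",
            ]
        )
        for s in summaries:
            writer.writerow(
                [
                    "-".join(s.pair), s.basin, f"{s.proportion:.6f}",
                    s.introgressed_copies, s.total_copies,
                    "" if s.divergence is None else f"{s.divergence:.6f}",
                    ";".join(sorted(s.loci_excluded)),
                ]
            )
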