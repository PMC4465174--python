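"""Within-population polymorphism (S, Hd, K, pi, theta_W) and
between-population divergence (Dxy, Da, Hudson FST).

Site inclusion follows complete deletion: every alignment column containing
``-`` or ``N`` in any sequence in scope is excluded, so within- and
between-population statistics may use different column sets (the effective
length ``L_eff`` is reported with every per-site value).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import LocusAlignment, Population, SampleTable
from .errors import InputError, UndefinedStatisticError

COMBINED = "combined"


def _matrix(seqs: Sequence[str]) -> np.ndarray:
    """Sequences as a (n, L) byte-code matrix."""
    if not seqs:
        raise InputError("empty sequence set")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(seqs), len(seqs[0]))


_EXCLUDED = (ord("-"), ord("N"))


def analyzed_columns(seqs: Sequence[str]) -> list[int]:
    """0-based indices of columns free of gaps and N in every sequence."""
    mat = _matrix(seqs)
    bad = (mat == _EXCLUDED[0]) | (mat == _EXCLUDED[1])
    return np.nonzero(~bad.any(axis=0))[0].tolist()


def _analyzed_matrix(seqs: Sequence[str]) -> np.ndarray:
    mat = _matrix(seqs)
    bad = (mat == _EXCLUDED[0]) | (mat == _EXCLUDED[1])
    return mat[:, ~bad.any(axis=0)]


def segregating_sites(seqs: Sequence[str]) -> int:
    """Number of analyzed columns carrying >= 2 distinct bases."""
    if len(seqs) < 2:
        raise UndefinedStatisticError("segregating sites need >= 2 sequences")
    mat = _analyzed_matrix(seqs)
    if mat.shape[1] == 0:
        return 0
    return int((mat != mat[0]).any(axis=0).sum())


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1..n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Unbiased haplotype (gene) diversity Hd = n/(n-1) (1 - sum p_k^2)."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2 copies")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - sum_p2)


def mean_pairwise_differences(seqs: Sequence[str]) -> float:
    """K: mean number of differences over all sequence pairs (analyzed columns)."""
    n = len(seqs)
    if n < 2:
        raise UndefinedStatisticError("pairwise differences need >= 2 sequences")
    mat = _analyzed_matrix(seqs)
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((mat[i] != mat[j]).sum())
    return total / math.comb(n, 2)


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """pi = K / L_eff (0, with a warning, when no column is analyzable)."""
    cols = analyzed_columns(seqs)
    if not cols:
        warnings.warn("no analyzable columns; pi reported as 0", stacklevel=2)
        return 0.0
    return mean_pairwise_differences(seqs) / len(cols)


def watterson_theta(S: int, n: int, L_eff: int) -> float:
    """Per-site Watterson estimator S / (a_{n-1} * L_eff)."""
    if n < 2:
        raise UndefinedStatisticError("Watterson estimator needs n >= 2")
    if L_eff == 0:
        raise UndefinedStatisticError("Watterson estimator needs L_eff > 0")
    return S / (harmonic_number(n - 1) * L_eff)


@dataclass(frozen=True)
class PolymorphismStats:
    """S, Hd, K, pi, theta_W for one population at one locus (or combined)."""

    population: Population
    locus: str
    n: int
    S: int
    Hd: float
    K: float
    pi: float
    thetaW: float
    L_eff: int
    harmonic_n: float

    def value(self, statistic: str) -> float:
        return float(getattr(self, statistic))


def population_sequences(
    aln: LocusAlignment, samples: SampleTable, population: Population
) -> list[str]:
    """Sequences of one (species, basin) population at one locus."""
    haploid = aln.locus_name in samples.haploid_loci
    if not any(key[0] == aln.locus_name for key in samples.copy_map):
        samples.bind_alignment(aln, haploid=haploid)
    return [
        seq
        for hid, seq in zip(aln.ids, aln.seqs)
        if samples.population_of_haplotype(aln.locus_name, hid) == population
    ]


def locus_stats(
    seqs: Sequence[str], population: Population, locus: str
) -> PolymorphismStats:
    """All five polymorphism statistics for one set of gene copies."""
    n = len(seqs)
    if n < 2:
        raise UndefinedStatisticError(
            f"{population}: {n} gene copies at {locus}; need >= 2"
        )
    cols = analyzed_columns(seqs)
    L_eff = len(cols)
    S = segregating_sites(seqs)
    K = mean_pairwise_differences(seqs)
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    Hd = haplotype_diversity(counts.values())
    pi = K / L_eff if L_eff else 0.0
    theta = S / (harmonic_number(n - 1) * L_eff) if L_eff else 0.0
    return PolymorphismStats(
        population, locus, n, S, Hd, K, pi, theta, L_eff, harmonic_number(n - 1)
    )


def population_stats(
    alignments: Mapping[str, LocusAlignment],
    samples: SampleTable,
    population: Population,
    combine: bool = True,
    combined_hd: str = "mean",
) -> list[PolymorphismStats]:
    """Per-locus statistics for one population, plus a combined record.

    Combined: S summed, K summed, pi and theta_W weighted by per-locus
    L_eff, Hd the unweighted per-locus mean (``combined_hd='concat'``
    instead collapses each sample's concatenated copies into multilocus
    haplotypes), n the maximum per-locus copy count.
    """
    per_locus: list[PolymorphismStats] = []
    locus_seqs: dict[str, list[str]] = {}
    for locus, aln in alignments.items():
        seqs = population_sequences(aln, samples, population)
        if not seqs:
            continue
        locus_seqs[locus] = seqs
        per_locus.append(locus_stats(seqs, population, locus))
    if not per_locus:
        raise InputError(f"population {population} absent from all alignments")
    if not combine:
        return per_locus
    total_L = sum(st.L_eff for st in per_locus)
    if total_L:
        pi_c = sum(st.pi * st.L_eff for st in per_locus) / total_L
        th_c = sum(st.thetaW * st.L_eff for st in per_locus) / total_L
    else:
        pi_c = th_c = 0.0
    if combined_hd == "concat":
        hd_c = _concat_hd(locus_seqs)
    else:
        hd_c = sum(st.Hd for st in per_locus) / len(per_locus)
    n_c = max(st.n for st in per_locus)
    combined = PolymorphismStats(
        population,
        COMBINED,
        n_c,
        sum(st.S for st in per_locus),
        hd_c,
        sum(st.K for st in per_locus),
        pi_c,
        th_c,
        total_L,
        harmonic_number(n_c - 1),
    )
    return per_locus + [combined]


def _concat_hd(locus_seqs: Mapping[str, Sequence[str]]) -> float:
    """Hd of multilocus haplotypes formed by aligning copy indices per locus."""
    n = min(len(s) for s in locus_seqs.values())
    concat = ["".join(locus_seqs[loc][i] for loc in locus_seqs) for i in range(n)]
    counts: dict[str, int] = {}
    for s in concat:
        counts[s] = counts.get(s, 0) + 1
    return haplotype_diversity(counts.values())


def dxy(pop_x: Sequence[str], pop_y: Sequence[str]) -> tuple[float, int]:
    """Mean per-site between-population divergence and the L_eff used.

    Analyzed columns are computed over the union of both populations.
    """
    if not pop_x or not pop_y:
        raise InputError("both populations need >= 1 sequence")
    mat = _matrix(list(pop_x) + list(pop_y))
    bad = (mat == _EXCLUDED[0]) | (mat == _EXCLUDED[1])
    mat = mat[:, ~bad.any(axis=0)]
    L_eff = mat.shape[1]
    if L_eff == 0:
        warnings.warn("no analyzable columns; Dxy reported as 0", stacklevel=2)
        return 0.0, 0
    mx = mat[: len(pop_x)]
    my = mat[len(pop_x):]
    total = sum(int((mx[i] != my[j]).sum()) for i in range(len(pop_x))
                for j in range(len(pop_y)))
    return total / (len(pop_x) * len(pop_y) * L_eff), L_eff


def _pi_on_columns(seqs: Sequence[str], mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return 0.0
    total = sum(int((mat[i] != mat[j]).sum()) for i, j in combinations(range(n), 2))
    L = mat.shape[1]
    return total / (math.comb(n, 2) * L) if L else 0.0


def _within_between(pop_x: Sequence[str], pop_y: Sequence[str]) -> tuple[float, float, int]:
    """(Hw, Hb, L_eff) on the shared column set of the pooled alignment."""
    mat = _matrix(list(pop_x) + list(pop_y))
    bad = (mat == _EXCLUDED[0]) | (mat == _EXCLUDED[1])
    mat = mat[:, ~bad.any(axis=0)]
    L_eff = mat.shape[1]
    mx = mat[: len(pop_x)]
    my = mat[len(pop_x):]
    if L_eff == 0:
        return 0.0, 0.0, 0
    hb = sum(int((mx[i] != my[j]).sum()) for i in range(len(pop_x))
             for j in range(len(pop_y))) / (len(pop_x) * len(pop_y) * L_eff)
    hw = (_pi_on_columns(pop_x, mx) + _pi_on_columns(pop_y, my)) / 2.0
    return hw, hb, L_eff


def da(pop_x: Sequence[str], pop_y: Sequence[str]) -> tuple[float, int]:
    """Net divergence Da = Dxy - (pi_x + pi_y) / 2 on the shared column set."""
    hw, hb, L_eff = _within_between(pop_x, pop_y)
    return hb - hw, L_eff


def hudson_fst(pop_x: Sequence[str], pop_y: Sequence[str]) -> tuple[float, int]:
    """Hudson's FST = 1 - Hw/Hb; NaN when Hb = 0 (undefined)."""
    hw, hb, L_eff = _within_between(pop_x, pop_y)
    if hb == 0.0:
        return float("nan"), L_eff
    return 1.0 - hw / hb, L_eff


@dataclass
class DivergenceMatrix:
    """Symmetric pairwise divergence matrix over populations."""

    statistic: str  # Dxy | Da | FST
    populations: list[Population]
    values: np.ndarray
    L_eff: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.populations),) * 2:
            raise InputError("matrix shape does not match population list")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise InputError("divergence matrix is not symmetric")

    def value(self, pop_a: Population, pop_b: Population) -> float:
        i = self.populations.index(pop_a)
        j = self.populations.index(pop_b)
        return float(self.values[i, j])


_PAIR_FUNCS = {"Dxy": dxy, "Da": da, "FST": hudson_fst}


def divergence_matrix(
    alignments: Mapping[str, LocusAlignment],
    samples: SampleTable,
    statistic: str,
    populations: Sequence[Population] | None = None,
    scope: str = COMBINED,
) -> DivergenceMatrix:
    """Pairwise Dxy/Da/FST over populations for one locus or combined loci.

    Combined scope weights per-locus Hw and Hb by the per-locus L_eff
    (equivalent to recomputing on a virtual concatenation of each locus's
    analyzed columns) before forming the statistic.
    """
    if statistic not in _PAIR_FUNCS:
        raise InputError(f"unknown statistic {statistic!r}")
    if populations is None:
        populations = samples.populations
    populations = list(populations)
    loci = list(alignments) if scope == COMBINED else [scope]
    for locus in loci:
        if locus not in alignments:
            raise InputError(f"locus {locus!r} not among alignments")
    npop = len(populations)
    values = np.zeros((npop, npop))
    l_eff = np.zeros((npop, npop), dtype=int)
    seqs: dict[tuple[str, Population], list[str]] = {}
    for locus in loci:
        for pop in populations:
            seqs[(locus, pop)] = population_sequences(
                alignments[locus], samples, pop
            )
    for i in range(npop):
        for j in range(i + 1, npop):
            hw_sum = hb_sum = 0.0
            L_total = 0
            for locus in loci:
                sx = seqs[(locus, populations[i])]
                sy = seqs[(locus, populations[j])]
                if not sx or not sy:
                    continue
                hw, hb, L = _within_between(sx, sy)
                hw_sum += hw * L
                hb_sum += hb * L
                L_total += L
            if L_total == 0:
                values[i, j] = values[j, i] = float("nan")
                continue
            hw_bar = hw_sum / L_total
            hb_bar = hb_sum / L_total
            if statistic == "Dxy":
                val = hb_bar
            elif statistic == "Da":
                val = hb_bar - hw_bar
            else:
                val = 1.0 - hw_bar / hb_bar if hb_bar else float("nan")
            values[i, j] = values[j, i] = val
            l_eff[i, j] = l_eff[j, i] = L_total
    return DivergenceMatrix(statistic, populations, values, l_eff)


def write_stats_tsv(stats: Sequence[PolymorphismStats], path) -> None:
    """Per-population statistics table (one row per population x locus)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["species", "basin", "locus", "No", "S", "Hd", "K", "pi", "thetaW", "L_eff"]
        )
        for st in stats:
            writer.writerow(
                [
                    st.population[0], st.population[1], st.locus, st.n, st.S,
                    f"{st.Hd:.5f}", f"{st.K:.5f}", f"{st.pi:.5f}",
                    f"{st.thetaW:.5f}", st.L_eff,
                ]
            )


def write_matrix_tsv(matrix: DivergenceMatrix, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        labels = [f"{sp}|{ba}" for sp, ba in matrix.populations]
        writer.writerow([matrix.statistic] + labels)
        for lab, row in zip(labels, matrix.values):
            writer.writerow([lab] + [f"{v:.6f}" for v in row])


def write_matrix_phylip(matrix: DivergenceMatrix, path) -> None:
    """Lower-triangle PHYLIP-style distance file."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.populations)}\n")
        for i, (sp, ba) in enumerate(matrix.populations):
            cells = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(i))
            name = f"{sp}|{ba}"[:30]
            fh.write(f"{name}  {cells}".rstrip() + "\n")
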