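"""Coverage accounting and the Lander-Waterman (Poisson) expectation.

Under random shotgun sequencing, per-base depth over a mappable target of
size N with T total mapped bases is Poisson with mean lambda = T / N.  An
enrichment procedure such as a reduced-representation library concentrates
sequence on a small genome fraction, so the observed depth histogram shows
an excess of bases at zero coverage and again at high coverage relative to
the Poisson expectation.  Unknown (N) bases and annotated repeats are
excluded from both the observed and expected distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import READ_LEN, ReadSet, SyntheticGenome


@dataclass(frozen=True)
class MappabilityAccount:
    """Base-level accounting of the assembled genome."""

    assembled_bases: int
    unknown_bases: int
    repetitive_bases: int

    def __post_init__(self) -> None:
        if min(self.assembled_bases, self.unknown_bases, self.repetitive_bases) < 0:
            raise ValueError("base counts must be non-negative")
        if self.mappable_bases < 0:
            raise ValueError("unknown + repetitive bases exceed assembled bases")

    @property
    def mappable_bases(self) -> int:
        return self.assembled_bases - self.unknown_bases - self.repetitive_bases

    @property
    def unmappable_percent(self) -> float:
        if self.assembled_bases == 0:
            raise ValueError("assembled_bases must be > 0")
        return 100.0 * (self.unknown_bases + self.repetitive_bases) / self.assembled_bases


def mean_coverage(total_mapped_bases: int, mappable_bases: int) -> float:
    """lambda = total mapped bases / mappable bases."""
    if mappable_bases <= 0:
        raise ValueError("mappable_bases must be > 0")
    if total_mapped_bases < 0:
        raise ValueError("total_mapped_bases must be >= 0")
    return total_mapped_bases / mappable_bases


def adjusted_zero_coverage(observed_zero: int, unknown: int, repetitive: int) -> int:
    """Zero-coverage bases after removing positions that cannot be mapped."""
    result = observed_zero - unknown - repetitive
    if result < 0:
        raise ValueError(
            "observed zero-coverage bases fewer than unknown + repetitive "
            "(accounting inconsistency)"
        )
    return result


def unmappable_fraction(account: MappabilityAccount) -> float:
    """Percent of the assembled genome that is unknown or repetitive."""
    return account.unmappable_percent


@dataclass
class CoverageProfile:
    """Observed per-depth base counts over the mappable genome."""

    depth_histogram: np.ndarray  # index = depth, value = base count
    account: MappabilityAccount

    def __post_init__(self) -> None:
        self.depth_histogram = np.asarray(self.depth_histogram, dtype=np.int64)
        if self.depth_histogram.sum() != self.account.mappable_bases:
            raise ValueError("depth histogram must sum to the mappable bases")

    @property
    def total_mapped_bases(self) -> int:
        d = np.arange(len(self.depth_histogram))
        return int((d * self.depth_histogram).sum())

    @property
    def mean_depth(self) -> float:
        return mean_coverage(self.total_mapped_bases, self.account.mappable_bases)


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Minimal BED-3 reader (0-based half-open intervals)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in df.itertuples(index=False):
        out.setdefault(str(chrom), []).append((int(start), int(end)))
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, spans in intervals.items():
            for s, e in spans:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    return path


def depth_histogram(
    readset: ReadSet,
    genome: SyntheticGenome | dict[str, str],
    repeat_intervals: dict[str, list[tuple[int, int]]] | None = None,
    read_length: int = READ_LEN,
) -> CoverageProfile:
    """Observed depth histogram over mappable positions.

    Unknown bases are taken from N runs in the reference; repetitive bases
    from ``repeat_intervals`` (or the genome's own repeat mask).
    """
    if isinstance(genome, SyntheticGenome):
        chrom_seqs = genome.chromosomes
        repeats = repeat_intervals if repeat_intervals is not None else genome.repeat_intervals
    else:
        chrom_seqs = genome
        repeats = repeat_intervals or {}

    assembled = unknown = repetitive = 0
    hist = np.zeros(1, dtype=np.int64)
    chrom_index = {c: i for i, c in enumerate(readset.chroms)}
    for chrom, seq in chrom_seqs.items():
        n = len(seq)
        assembled += n
        mask = np.zeros(n, dtype=bool)  # True = unmappable
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_n = arr == ord("N")
        unknown += int(is_n.sum())
        mask |= is_n
        for s, e in repeats.get(chrom, []):
            span = mask[s:e]
            repetitive += int((~span & ~is_n[s:e]).sum())
            mask[s:e] = True

        diff = np.zeros(n + 1, dtype=np.int64)
        ci = chrom_index.get(chrom)
        if ci is not None:
            sel = readset.chrom_idx == ci
            starts = readset.start[sel]
            np.add.at(diff, starts, 1)
            np.add.at(diff, np.minimum(starts + read_length, n), -1)
        depth = np.cumsum(diff[:-1])
        h = np.bincount(depth[~mask])
        if len(h) > len(hist):
            hist = np.pad(hist, (0, len(h) - len(hist)))
            hist += h
        else:
            hist[: len(h)] += h
    account = MappabilityAccount(assembled, unknown, repetitive)
    return CoverageProfile(depth_histogram=hist, account=account)


def poisson_expected(
    lam: float, mappable_bases: int, max_depth: int
) -> np.ndarray:
    """Expected base counts per depth under Poisson(lambda); the tail mass at
    depths >= max_depth is collapsed into the final bin."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    d = np.arange(max_depth + 1)
    pmf = stats.poisson.pmf(d, lam)
    pmf[-1] = stats.poisson.sf(max_depth - 1, lam)
    return mappable_bases * pmf


def enrichment_report(
    observed: CoverageProfile, expected: np.ndarray
) -> tuple[pd.DataFrame, int | None]:
    """Per-depth observed/expected ratios and the crossover depth.

    The crossover is the smallest depth >= 1 at which the observed base
    count exceeds the expectation; ``None`` when it never does.
    """
    max_depth = len(expected) - 1
    obs = observed.depth_histogram.astype(np.int64)
    if len(obs) > max_depth + 1:
        collapsed = obs[: max_depth + 1].copy()
        collapsed[-1] += obs[max_depth + 1 :].sum()
        obs = collapsed
    else:
        obs = np.pad(obs, (0, max_depth + 1 - len(obs)))
    if abs(obs.sum() - expected.sum()) > 0.01 * max(expected.sum(), 1):
        import logging

        logging.getLogger(__name__).warning(
            "observed and expected totals differ by more than 1%%: %d vs %.0f",
            obs.sum(), expected.sum(),
        )
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(
            expected > 0, obs / expected, np.where(obs == 0, 1.0, np.inf)
        )
    df = pd.DataFrame(
        {"depth": np.arange(max_depth + 1), "observed": obs,
         "expected": expected, "ratio": ratio}
    )
    above = np.flatnonzero(obs[1:] > expected[1:])
    crossover = int(above[0] + 1) if len(above) else None
    return df, crossover
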