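"""Heuristic SNP discovery from per-site, per-sample allele counts.

Two tiers of calls are produced, mirroring the two-stage heuristic used for
RRL short-read data:

* the *candidate* tier applies four preliminary read-count filters — minor
  fraction > 5% of total depth, total depth in [10, 1000], and 3rd+4th
  alleles < 2% of depth — and retains the two most common alleles;
* the *high-quality* tier additionally requires mean base quality >= 20 and
  a genotypic contingency-test p-value <= 0.01.  The contingency test asks
  whether the reference/alternative read counts are heterogeneous across
  samples: genotype-driven variation gives small p, uniform low-level
  sequencing error gives large p.

The module also provides the read-position diagnostic: sequencing error is
concentrated toward read ends, so the candidate tier is enriched for
minor-allele evidence at deep within-read offsets, and the quality and
contingency filters should flatten that bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from .simulate import READ_LEN, ReadSet, SyntheticGenome, _BASE_INDEX, _INDEX_BASE

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# site counts


@dataclass
class SiteCounts:
    """Per-sample allele observations at one genomic site.

    ``counts[sample][allele]`` is the number of covering read bases,
    ``qual_sum`` the summed Phred qualities of those observations and
    ``offsets[sample][allele]`` a length-32 histogram of the within-read
    offsets (1..32) at which the allele was observed.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    counts: dict[str, dict[str, int]]
    qual_sum: dict[str, dict[str, int]]
    offsets: dict[str, dict[str, np.ndarray]]

    def __eq__(self, other) -> bool:  # exact round-trip equality
        if not isinstance(other, SiteCounts):
            return NotImplemented
        if (self.chrom, self.pos, self.ref) != (other.chrom, other.pos, other.ref):
            return False
        if self.counts != other.counts or self.qual_sum != other.qual_sum:
            return False
        if self.offsets.keys() != other.offsets.keys():
            return False
        for s in self.offsets:
            if self.offsets[s].keys() != other.offsets[s].keys():
                return False
            for a in self.offsets[s]:
                if not np.array_equal(self.offsets[s][a], other.offsets[s][a]):
                    return False
        return True

    def allele_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for per in self.counts.values():
            for a, c in per.items():
                totals[a] = totals.get(a, 0) + c
        return totals

    def total_depth(self) -> int:
        return sum(self.allele_totals().values())

    def ordered_alleles(self) -> list[str]:
        """Alleles by descending count; ties broken reference-first, then
        lexicographically (deterministic)."""
        totals = self.allele_totals()
        return sorted(totals, key=lambda a: (-totals[a], a != self.ref, a))

    def mean_quality(self, alleles: Iterable[str] | None = None) -> float:
        qs = n = 0
        for s, per in self.qual_sum.items():
            for a, q in per.items():
                if alleles is None or a in alleles:
                    qs += q
                    n += self.counts[s][a]
        if n == 0:
            raise ValueError("no quality-bearing observations at site")
        return qs / n

    def biallelic_table(self, a1: str, a2: str) -> tuple[list[str], np.ndarray]:
        """2 x k table of (a1, a2) counts over samples with nonzero totals."""
        kept, cols = [], []
        for s, per in self.counts.items():
            c1, c2 = per.get(a1, 0), per.get(a2, 0)
            if c1 + c2 > 0:
                kept.append(s)
                cols.append((c1, c2))
        return kept, np.array(cols, dtype=np.int64).T.reshape(2, -1)

    def sample_counts(self, a1: str, a2: str, sample: str) -> tuple[int, int]:
        per = self.counts.get(sample, {})
        return per.get(a1, 0), per.get(a2, 0)

    def pooled_offsets(self, allele: str) -> np.ndarray:
        out = np.zeros(READ_LEN, dtype=np.int64)
        for per in self.offsets.values():
            if allele in per:
                out += per[allele]
        return out


# ---------------------------------------------------------------------------
# pileup aggregation


def aggregate_pileup(
    source: ReadSet | str | Path, genome: SyntheticGenome | dict[str, str] | None = None
) -> Iterator[SiteCounts]:
    """Aggregate reads (or a pileup file) into a stream of SiteCounts.

    Emits one record per position carrying at least one read base that
    mismatches the reference (the definition of a putative SNP position).
    Sites are yielded sorted by (chromosome, position).
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".sam":
            from .simulate import read_sam

            if genome is None:
                raise ValueError("a reference genome is required with SAM input")
            yield from _aggregate_readset(read_sam(p), genome)
        else:
            yield from read_pileup(p)
    else:
        if genome is None:
            raise ValueError("a reference genome is required with read input")
        yield from _aggregate_readset(source, genome)


def _aggregate_readset(
    readset: ReadSet, genome: SyntheticGenome | dict[str, str]
) -> Iterator[SiteCounts]:
    chrom_seqs = (
        genome.chromosomes if isinstance(genome, SyntheticGenome) else genome
    )
    n_samples = len(readset.samples)
    offs = np.arange(READ_LEN)
    for ci, chrom in enumerate(readset.chroms):
        mask = readset.chrom_idx == ci
        if not mask.any():
            continue
        starts = readset.start[mask]
        strands = readset.strand[mask]
        seqs = readset.seq[mask]
        quals = readset.qual[mask]
        sidx = readset.sample_idx[mask]

        # per-observation arrays (read orientation -> reference orientation)
        pos = starts[:, None] + offs[None, :]
        rev = strands == 1
        if rev.any():
            pos[rev] = starts[rev, None] + (READ_LEN - 1 - offs)[None, :]
        allele = _BASE_INDEX[seqs].astype(np.int64)
        if rev.any():
            allele[rev] = (3 - allele[rev]) % 4  # complement back to + strand
        offset = np.broadcast_to(offs + 1, allele.shape)
        sample = np.broadcast_to(sidx[:, None], allele.shape)
        qual = quals.astype(np.int64)

        pos = pos.ravel()
        allele = allele.ravel()
        offset = np.ascontiguousarray(offset).ravel()
        sample = np.ascontiguousarray(sample).ravel()
        qual = qual.ravel()

        refarr = _BASE_INDEX[
            np.frombuffer(chrom_seqs[chrom].encode(), dtype=np.uint8)
        ].astype(np.int64)
        mismatch_pos = np.zeros(len(refarr), dtype=bool)
        mismatch_pos[pos[allele != refarr[pos]]] = True
        keep = mismatch_pos[pos]
        if not keep.any():
            continue
        pos, allele, offset, sample, qual = (
            pos[keep], allele[keep], offset[keep], sample[keep], qual[keep]
        )

        key = ((pos * n_samples + sample) * 4 + allele) * (READ_LEN + 1) + offset
        order = np.argsort(key, kind="stable")
        key = key[order]
        qual = qual[order]
        ukey, ustart, ucount = np.unique(key, return_index=True, return_counts=True)
        qsum = np.add.reduceat(qual, ustart)

        upos = ukey // (n_samples * 4 * (READ_LEN + 1))
        rem = ukey % (n_samples * 4 * (READ_LEN + 1))
        usample = rem // (4 * (READ_LEN + 1))
        rem = rem % (4 * (READ_LEN + 1))
        uallele = rem // (READ_LEN + 1)
        uoffset = rem % (READ_LEN + 1)

        boundaries = np.flatnonzero(np.diff(upos)) + 1
        groups = np.split(np.arange(len(ukey)), boundaries)
        for g in groups:
            p = int(upos[g[0]])
            counts: dict[str, dict[str, int]] = {}
            qual_sum: dict[str, dict[str, int]] = {}
            offsets: dict[str, dict[str, np.ndarray]] = {}
            for j in g:
                s = readset.samples[int(usample[j])]
                a = chr(_INDEX_BASE[int(uallele[j])])
                counts.setdefault(s, {})
                qual_sum.setdefault(s, {})
                offsets.setdefault(s, {})
                counts[s][a] = counts[s].get(a, 0) + int(ucount[j])
                qual_sum[s][a] = qual_sum[s].get(a, 0) + int(qsum[j])
                h = offsets[s].setdefault(a, np.zeros(READ_LEN, dtype=np.int64))
                h[int(uoffset[j]) - 1] += int(ucount[j])
            yield SiteCounts(
                chrom=chrom,
                pos=p,
                ref=chrom_seqs[chrom][p],
                counts=counts,
                qual_sum=qual_sum,
                offsets=offsets,
            )


# ---------------------------------------------------------------------------
# pileup text format (module dialect)

_PILEUP_HEADER = (
    "#chrom\tpos\tref\tsample\tallele\tcount\tqual_sum\tmean_quality\toffsets\n"
)


def write_pileup(sites: Iterable[SiteCounts], path: str | Path) -> Path:
    """Tab-delimited site pileup; positions 1-based; offsets column holds an
    ``offset:count`` histogram so the file round-trips exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_PILEUP_HEADER)
        for site in sites:
            for s in sorted(site.counts):
                for a in sorted(site.counts[s]):
                    c = site.counts[s][a]
                    q = site.qual_sum[s][a]
                    h = site.offsets[s][a]
                    hist = ",".join(
                        f"{o + 1}:{int(n)}" for o, n in enumerate(h) if n
                    )
                    fh.write(
                        f"{site.chrom}\t{site.pos + 1}\t{site.ref}\t{s}\t{a}\t"
                        f"{c}\t{q}\t{q / c:.2f}\t{hist}\n"
                    )
    return path


def read_pileup(path: str | Path) -> Iterator[SiteCounts]:
    path = Path(path)
    current: SiteCounts | None = None
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, pos1, ref, s, a = f[0], int(f[1]), f[2], f[3], f[4]
                count, qsum = int(f[5]), int(f[6])
                hist = np.zeros(READ_LEN, dtype=np.int64)
                if len(f) > 8 and f[8]:
                    for tok in f[8].split(","):
                        o, n = tok.split(":")
                        hist[int(o) - 1] = int(n)
            except (IndexError, ValueError):
                n_bad += 1
                continue
            pos = pos1 - 1
            if current is None or (current.chrom, current.pos) != (chrom, pos):
                if current is not None:
                    yield current
                current = SiteCounts(chrom, pos, ref, {}, {}, {})
            current.counts.setdefault(s, {})[a] = count
            current.qual_sum.setdefault(s, {})[a] = qsum
            current.offsets.setdefault(s, {})[a] = hist
    if current is not None:
        yield current
    if n_bad:
        logger.warning("skipped %d malformed pileup records", n_bad)


# ---------------------------------------------------------------------------
# filters


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the two-tier SNP-calling heuristic (defaults are the
    published rule set)."""

    min_depth: int = 10
    max_depth: int = 1000
    min_minor_frac: float = 0.05  # reject if minor fraction <= this
    max_third_fourth_frac: float = 0.02  # reject if 3rd+4th fraction >= this
    min_mean_q: float = 20.0
    max_contingency_p: float = 0.01
    mean_q_minor_only: bool = False
    mc_draws: int = 10_000


@dataclass
class CandidateSNP:
    """A site passing the preliminary filters, with its two retained alleles."""

    site: SiteCounts
    allele_major: str
    allele_minor: str
    total_depth: int
    minor_fraction: float
    mean_quality: float | None = None
    contingency_p: float | None = None
    filter_flags: list[str] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def ref_allele(self) -> str:
        """Reference-orientation allele pair; falls back to the major allele
        when the genome reference base was not retained."""
        return (
            self.site.ref
            if self.site.ref in (self.allele_major, self.allele_minor)
            else self.allele_major
        )

    @property
    def alt_allele(self) -> str:
        ref = self.ref_allele
        return self.allele_minor if ref == self.allele_major else self.allele_major


@dataclass
class SNPSet:
    snps: list[CandidateSNP]
    tier: str  # "candidate" or "high_quality"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[CandidateSNP]:
        return iter(self.snps)


def preliminary_filter(
    site: SiteCounts, config: FilterConfig = FilterConfig()
) -> tuple[bool, list[str]]:
    """Apply the four preliminary read-count rules; returns (accepted,
    reason codes for every failed rule)."""
    reasons: list[str] = []
    totals = site.allele_totals()
    ordered = site.ordered_alleles()
    depth = sum(totals.values())
    if len(ordered) < 2:
        return False, ["single_allele"]
    minor = totals[ordered[1]]
    if minor / depth <= config.min_minor_frac:
        reasons.append("minor_fraction")
    if depth > config.max_depth:
        reasons.append("high_depth")
    if depth < config.min_depth:
        reasons.append("low_depth")
    if len(ordered) > 2:
        extra = sum(totals[a] for a in ordered[2:4])
        if extra / depth >= config.max_third_fourth_frac:
            reasons.append("third_fourth_alleles")
    return (not reasons), reasons


def mean_site_quality(
    site: SiteCounts, minor_allele: str | None = None, minor_only: bool = False
) -> float:
    """Mean Phred quality over base observations at the site.

    By default all observations are averaged; ``minor_only`` restricts the
    mean to the minor-allele observations.
    """
    if minor_only:
        if minor_allele is None:
            raise ValueError("minor_only requires the minor allele")
        return site.mean_quality([minor_allele])
    return site.mean_quality()


def _pearson_chi2(table: np.ndarray) -> float:
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def genotypic_contingency_test(
    table: np.ndarray,
    method: str = "auto",
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Test of independence between sample identity and allele identity.

    ``table`` is a 2 x k array of (reference, alternative) read counts per
    sample; zero-coverage samples are dropped.  A Pearson chi-square p-value
    is used when every expected cell is >= 5; otherwise (or when
    ``method="mc"``) a Monte-Carlo permutation p-value with the margins held
    fixed is computed.  Degenerate tables (a single informative row or
    column) return p = 1 by convention.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    table = table[:, table.sum(axis=0) > 0]
    k = table.shape[1]
    if k < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    stat = _pearson_chi2(table)
    if method not in ("auto", "chi2", "mc"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        method = "chi2" if (expected >= 5).all() else "mc"
    if method == "chi2":
        return float(stats.chi2.sf(stat, k - 1))
    rng = rng or np.random.default_rng(0)
    col_totals = table.sum(axis=0)
    row0 = int(table[0].sum())
    draws = rng.multivariate_hypergeometric(col_totals, row0, size=n_draws)
    n = table.sum()
    expected0 = np.outer(table.sum(axis=1), col_totals)[0] / n
    expected1 = col_totals - expected0
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (draws - expected0) ** 2 / expected0
        t1 = ((col_totals - draws) - expected1) ** 2 / expected1
    stats_null = np.nansum(t0, axis=1) + np.nansum(t1, axis=1)
    return float((1 + np.sum(stats_null >= stat - 1e-12)) / (n_draws + 1))


def make_candidate(
    site: SiteCounts,
    config: FilterConfig = FilterConfig(),
    rng: np.random.Generator | None = None,
) -> CandidateSNP:
    """Build a CandidateSNP (two most common alleles retained) and compute
    its quality and contingency statistics."""
    ordered = site.ordered_alleles()
    major, minor = ordered[0], ordered[1]
    totals = site.allele_totals()
    depth = sum(totals.values())
    try:
        mq = mean_site_quality(site, minor, config.mean_q_minor_only)
    except ValueError:
        mq = None
    _, table = site.biallelic_table(major, minor)
    p = genotypic_contingency_test(table, n_draws=config.mc_draws, rng=rng)
    return CandidateSNP(
        site=site,
        allele_major=major,
        allele_minor=minor,
        total_depth=depth,
        minor_fraction=totals[minor] / depth,
        mean_quality=mq,
        contingency_p=p,
    )


def high_quality_filter(
    candidates: SNPSet, config: FilterConfig = FilterConfig()
) -> SNPSet:
    """Select candidates with mean Q >= threshold and contingency p <= cutoff."""
    if candidates.tier != "candidate":
        raise ValueError("high_quality_filter expects the candidate tier")
    kept = []
    for snp in candidates:
        flags = []
        if snp.mean_quality is None or snp.mean_quality < config.min_mean_q:
            flags.append("low_quality")
        if snp.contingency_p is None or snp.contingency_p > config.max_contingency_p:
            flags.append("contingency_p")
        snp.filter_flags = flags
        if not flags:
            kept.append(snp)
    return SNPSet(
        snps=kept, tier="high_quality", provenance=dict(candidates.provenance)
    )


@dataclass
class DiscoveryResult:
    candidates: SNPSet
    high_quality: SNPSet
    audit: list[tuple[str, int, str]]  # (chrom, pos0, reason) per rejected site
    n_sites_seen: int

    def rejection_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, reason in self.audit:
            out[reason] = out.get(reason, 0) + 1
        return out


def discover(
    sites: Iterable[SiteCounts],
    config: FilterConfig = FilterConfig(),
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full two-tier discovery over a stream of sites."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x434F4E]))
    cands: list[CandidateSNP] = []
    audit: list[tuple[str, int, str]] = []
    n_seen = 0
    for site in sites:
        n_seen += 1
        ok, reasons = preliminary_filter(site, config)
        if not ok:
            audit.extend((site.chrom, site.pos, r) for r in reasons)
            continue
        cands.append(make_candidate(site, config, rng))
    candidates = SNPSet(cands, tier="candidate", provenance={"n_sites": n_seen})
    hq = high_quality_filter(candidates, config)
    return DiscoveryResult(candidates, hq, audit, n_seen)


# ---------------------------------------------------------------------------
# read-position diagnostics


@dataclass
class PositionBias:
    histogram: np.ndarray  # length 32, minor-allele evidence by offset
    slope: float  # least-squares slope over offsets 4..32

    @property
    def total(self) -> float:
        return float(self.histogram.sum())


def read_position_distribution(
    snpset: SNPSet, mode: str = "site", slope_offsets: tuple[int, int] = (4, 32)
) -> PositionBias:
    """Distribution of minor-allele evidence across within-read offsets.

    ``mode="site"`` (default) gives each SNP unit weight spread over the
    offsets at which its minor allele was observed — the per-SNP read
    position distribution.  ``mode="observations"`` counts raw minor-allele
    observations instead.  The summary slope is the least-squares slope of
    the histogram over offsets 4..32 (the first three positions are the
    invariant CGG tag).
    """
    hist = np.zeros(READ_LEN, dtype=float)
    for snp in snpset:
        h = snp.site.pooled_offsets(snp.allele_minor).astype(float)
        if mode == "site":
            tot = h.sum()
            if tot > 0:
                hist += h / tot
        elif mode == "observations":
            hist += h
        else:
            raise ValueError(f"unknown mode {mode!r}")
    lo, hi = slope_offsets
    x = np.arange(lo, hi + 1)
    y = hist[lo - 1 : hi]
    slope = float(np.polyfit(x, y, 1)[0]) if len(x) > 1 else 0.0
    return PositionBias(histogram=hist, slope=slope)


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    snpset: SNPSet,
    genome: SyntheticGenome | dict[str, str],
    path: str | Path,
) -> Path:
    """Write the SNP set as uncompressed VCF 4.2 (1-based positions)."""
    import pysam

    chrom_seqs = genome.chromosomes if isinstance(genome, SyntheticGenome) else genome
    header = pysam.VariantHeader()
    for name, seq in chrom_seqs.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("DP", 1, "Integer", "Total read depth across samples")
    header.info.add("MAF", 1, "Float", "Minor-allele read fraction")
    header.info.add("MQS", 1, "Float", "Mean Phred quality at site")
    header.info.add("CTP", 1, "Float", "Genotypic contingency test p-value")
    header.info.add("TIER", 1, "String", "SNP set tier")
    header.filters.add("low_quality", None, None, "Mean base quality below threshold")
    header.filters.add("contingency_p", None, None, "Contingency p above threshold")

    path = Path(path)
    n_skipped = 0
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for snp in snpset:
            seq = chrom_seqs.get(snp.chrom)
            if seq is None or snp.pos >= len(seq):
                n_skipped += 1
                continue
            rec = vcf.new_record(
                contig=snp.chrom,
                start=snp.pos,  # pysam writes the 1-based POS
                alleles=(snp.ref_allele, snp.alt_allele),
            )
            rec.info["DP"] = snp.total_depth
            rec.info["MAF"] = round(snp.minor_fraction, 6)
            if snp.mean_quality is not None:
                rec.info["MQS"] = round(snp.mean_quality, 4)
            if snp.contingency_p is not None:
                rec.info["CTP"] = snp.contingency_p
            rec.info["TIER"] = snpset.tier
            if snp.filter_flags:
                for f in snp.filter_flags:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)
    if n_skipped:
        logger.warning("skipped %d records beyond contig ends", n_skipped)
    return path
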