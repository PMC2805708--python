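"""Rule-based genotype calling from read counts, and cross-platform
genotype concordance.

Two rule sets are implemented:

* *lenient* (used for LD analysis): a genotype is called only with >= 4
  reads; homozygous with >= 4 reads of one allele and 0 of the other,
  heterozygous with >= 4 reads of each;
* *strict* (used for array concordance): homozygous with >= 5 reads all of
  the same allele; heterozygous with >= 8 reads passing the heterozygosity
  test — an exact binomial test that the minor read count exceeds what
  sequencing error alone would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING, HOM_REF, HET, HOM_ALT = -1, 0, 1, 2
CALL_NAMES = {MISSING: "missing", HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}


def call_lenient(ref_count: int, alt_count: int) -> int:
    """Lenient genotype call: >=4/0 homozygous, >=4/>=4 heterozygous."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if ref_count >= 4 and alt_count == 0:
        return HOM_REF
    if alt_count >= 4 and ref_count == 0:
        return HOM_ALT
    if ref_count >= 4 and alt_count >= 4:
        return HET
    return MISSING


def heterozygosity_test(
    total_reads: int, minor_count: int, error_rate: float = 0.01,
    alpha: float = 0.01,
) -> tuple[bool, float]:
    """Is the minor read count inconsistent with pure sequencing error?

    Returns (passed, p) with p = P(Binomial(n, error_rate) >= k); the test
    passes when p < ``alpha``.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    p = float(stats.binom.sf(minor_count - 1, total_reads, error_rate))
    return p < alpha, p


def call_strict(
    ref_count: int, alt_count: int, error_rate: float = 0.01, alpha: float = 0.01
) -> int:
    """Strict genotype call: >=5 reads all of one allele for a homozygote;
    >=8 reads plus a passing heterozygosity test for a heterozygote."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total >= 5 and alt_count == 0:
        return HOM_REF
    if total >= 5 and ref_count == 0:
        return HOM_ALT
    if total >= 8:
        passed, _ = heterozygosity_test(total, min(ref_count, alt_count), error_rate, alpha)
        if passed:
            return HET
    return MISSING


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype calls with group labels.

    ``calls`` uses the codes -1 (missing), 0 (hom ref), 1 (het), 2 (hom alt).
    """

    samples: list[str]
    groups: list[str]
    sites: list[tuple[str, int]]  # (chrom, 0-based pos), sorted within chrom
    ref_alleles: list[str]
    alt_alleles: list[str]
    calls: np.ndarray  # (n_samples, n_sites) int8
    source: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls matrix shape does not match samples x sites")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample is required")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def n_called(self) -> int:
        return int((self.calls != MISSING).sum())

    def subset_samples(self, keep: Sequence[str] | str) -> "GenotypeMatrix":
        """Subset to named samples, or to a group when given a group label."""
        if isinstance(keep, str):
            idx = [i for i, g in enumerate(self.groups) if g == keep]
        else:
            wanted = set(keep)
            idx = [i for i, s in enumerate(self.samples) if s in wanted]
        if not idx:
            raise ValueError("no samples retained")
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            sites=list(self.sites),
            ref_alleles=list(self.ref_alleles),
            alt_alleles=list(self.alt_alleles),
            calls=self.calls[idx],
            source=self.source,
        )

    def subset_sites(self, site_idx: Sequence[int]) -> "GenotypeMatrix":
        site_idx = list(site_idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            groups=list(self.groups),
            sites=[self.sites[j] for j in site_idx],
            ref_alleles=[self.ref_alleles[j] for j in site_idx],
            alt_alleles=[self.alt_alleles[j] for j in site_idx],
            calls=self.calls[:, site_idx],
            source=self.source,
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            cols = [f"{c}:{p + 1}" for c, p in self.sites]
            fh.write("sample\tgroup\t" + "\t".join(cols) + "\n")
            fh.write(
                "#alleles\t.\t"
                + "\t".join(
                    f"{r}/{a}" for r, a in zip(self.ref_alleles, self.alt_alleles)
                )
                + "\n"
            )
            for i, (s, g) in enumerate(zip(self.samples, self.groups)):
                row = [
                    "NA" if v == MISSING else str(int(v)) for v in self.calls[i]
                ]
                fh.write(f"{s}\t{g}\t" + "\t".join(row) + "\n")
        return path

    @classmethod
    def read_tsv(cls, path: str | Path, source: str = "") -> "GenotypeMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            sites = []
            for col in header[2:]:
                chrom, pos1 = col.rsplit(":", 1)
                sites.append((chrom, int(pos1) - 1))
            refs = ["N"] * len(sites)
            alts = ["N"] * len(sites)
            samples, groups, rows = [], [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[0] == "#alleles":
                    for j, tok in enumerate(f[2:]):
                        if "/" in tok:
                            refs[j], alts[j] = tok.split("/", 1)
                    continue
                samples.append(f[0])
                groups.append(f[1])
                rows.append(
                    [MISSING if v == "NA" else int(v) for v in f[2:]]
                )
        return cls(
            samples=samples,
            groups=groups,
            sites=sites,
            ref_alleles=refs,
            alt_alleles=alts,
            calls=np.array(rows, dtype=np.int8),
            source=source,
        )


def genotype_matrix(
    snps,
    samples: Sequence[str],
    groups: Sequence[str],
    rule: str = "lenient",
    error_rate: float = 0.01,
    alpha: float = 0.01,
) -> GenotypeMatrix:
    """Call genotypes for every (sample, SNP) pair from the site read counts.

    ``snps`` is an iterable of CandidateSNP; the reference-orientation
    allele pair of each SNP defines the 0/2 coding.
    """
    snps = list(snps)
    calls = np.full((len(samples), len(snps)), MISSING, dtype=np.int8)
    for j, snp in enumerate(snps):
        ref, alt = snp.ref_allele, snp.alt_allele
        for i, s in enumerate(samples):
            rc, ac = snp.site.sample_counts(ref, alt, s)
            if rule == "lenient":
                calls[i, j] = call_lenient(rc, ac)
            elif rule == "strict":
                calls[i, j] = call_strict(rc, ac, error_rate, alpha)
            else:
                raise ValueError(f"unknown rule {rule!r}")
    return GenotypeMatrix(
        samples=list(samples),
        groups=list(groups),
        sites=[(s.chrom, s.pos) for s in snps],
        ref_alleles=[s.ref_allele for s in snps],
        alt_alleles=[s.alt_allele for s in snps],
        calls=calls,
        source=f"sequence_{rule}",
    )


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordanceTable:
    """3 x 3 genotype concordance over calls made by both platforms.

    Rows index platform A (hom ref, het, hom alt); columns platform B.
    Percentages are computed against the grand total, and the overall
    concordance is the diagonal share in percent.
    """

    counts: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    n_dropped_sites: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("concordance table must be 3 x 3")
        if (self.counts < 0).any():
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_counts(cls, counts, **kw) -> "ConcordanceTable":
        return cls(counts=np.asarray(counts), **kw)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def overall_percent(self) -> float:
        if self.grand_total == 0:
            raise ValueError("no co-called genotypes; concordance undefined")
        return 100.0 * float(np.trace(self.counts)) / self.grand_total

    def cell_percent(self) -> np.ndarray:
        if self.grand_total == 0:
            raise ValueError("no co-called genotypes; concordance undefined")
        return 100.0 * self.counts / self.grand_total

    def dominant_discordance(self) -> tuple[tuple[int, int], int]:
        """(cell, count) of the largest off-diagonal cell."""
        off = self.counts.copy()
        np.fill_diagonal(off, -1)
        idx = np.unravel_index(np.argmax(off), off.shape)
        return (int(idx[0]), int(idx[1])), int(off[idx])

    def to_dataframe(self) -> pd.DataFrame:
        names = ["hom_ref", "het", "hom_alt"]
        return pd.DataFrame(self.counts, index=names, columns=names)


def concordance(a: GenotypeMatrix, b: GenotypeMatrix) -> ConcordanceTable:
    """Cross-tabulate genotype calls over shared samples and sites.

    Genotypes missing on either side are excluded; sites whose allele pair
    disagrees between platforms are dropped (counted in
    ``n_dropped_sites``).
    """
    shared_samples = [s for s in a.samples if s in set(b.samples)]
    if not shared_samples:
        raise ValueError("matrices share no samples")
    a_site = {site: j for j, site in enumerate(a.sites)}
    b_site = {site: j for j, site in enumerate(b.sites)}
    shared_sites = [s for s in a.sites if s in b_site]
    ai = [a.samples.index(s) for s in shared_samples]
    bi = [b.samples.index(s) for s in shared_samples]
    counts = np.zeros((3, 3), dtype=np.int64)
    dropped = 0
    for site in shared_sites:
        ja, jb = a_site[site], b_site[site]
        pair_a = (a.ref_alleles[ja], a.alt_alleles[ja])
        pair_b = (b.ref_alleles[jb], b.alt_alleles[jb])
        if "N" not in pair_a and "N" not in pair_b and set(pair_a) != set(pair_b):
            dropped += 1
            continue
        flip = "N" not in pair_b and pair_a[0] == pair_b[1] and pair_a != pair_b
        ca = a.calls[ai, ja]
        cb = b.calls[bi, jb]
        if flip:
            cb = np.where(cb == MISSING, MISSING, 2 - cb)
        ok = (ca != MISSING) & (cb != MISSING)
        for x, y in zip(ca[ok], cb[ok]):
            counts[int(x), int(y)] += 1
    return ConcordanceTable(
        counts=counts,
        label_a=a.source or "A",
        label_b=b.source or "B",
        n_dropped_sites=dropped,
    )


def truth_matrix(panel, source: str = "array") -> GenotypeMatrix:
    """The planted genotypes as a GenotypeMatrix (the error-free analogue of
    an array-platform genotype matrix)."""
    calls = np.stack([v.genotypes for v in panel.variants], axis=1).astype(np.int8)
    return GenotypeMatrix(
        samples=panel.sample_ids,
        groups=panel.groups,
        sites=[(v.chrom, v.pos) for v in panel.variants],
        ref_alleles=[v.ref for v in panel.variants],
        alt_alleles=[v.alt for v in panel.variants],
        calls=calls,
        source=source,
    )
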