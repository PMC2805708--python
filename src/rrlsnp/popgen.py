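"""Population-genetic summaries: segregation classes, EM-based two-locus
linkage disequilibrium, the binned LD-decay profile with an unlinked
background, and principal components analysis of genotype matrices.

The LD statistic is r^2 = D^2 / (p_A p_a p_B p_b), where D is the
haplotype-frequency covariance f(AB) - p_A p_B.  Phase of double
heterozygotes is unobserved in unphased diploids, so haplotype frequencies
are obtained by maximum likelihood via EM: the double-heterozygote count is
split between the cis and trans phases at their current expected
proportions, and the four frequencies re-estimated until stationary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotyping import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# segregation classes

SEGREGATION_VALUES = (
    "vinifera_polymorphic",
    "wild_polymorphic",
    "shared_polymorphic",
    "fixed_difference",
    "unclassified",
)


@dataclass(frozen=True)
class Segregation:
    """Disjoint segregation class plus the overlapping per-group flags."""

    value: str
    poly_a: bool  # polymorphic within the cultivated group
    poly_b: bool  # polymorphic within the wild group


def classify_segregation(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    groups: np.ndarray,
    group_a: str = "cultivated",
    group_b: str = "wild",
) -> Segregation:
    """Classify a SNP from per-sample read counts of its two alleles.

    A group is polymorphic when it contains >= 1 read of each allele; a
    fixed difference has one allele exclusively in one group and the other
    allele exclusively in the other group.  (Relabelling of the wild
    progenitor into the cultivated group is the caller's choice, applied to
    the ``groups`` vector.)
    """
    ref_counts = np.asarray(ref_counts)
    alt_counts = np.asarray(alt_counts)
    groups = np.asarray(groups)
    in_a = groups == group_a
    in_b = groups == group_b
    ra, aa = int(ref_counts[in_a].sum()), int(alt_counts[in_a].sum())
    rb, ab = int(ref_counts[in_b].sum()), int(alt_counts[in_b].sum())
    poly_a = ra >= 1 and aa >= 1
    poly_b = rb >= 1 and ab >= 1
    fixed = (ra >= 1 and aa == 0 and rb == 0 and ab >= 1) or (
        ra == 0 and aa >= 1 and rb >= 1 and ab == 0
    )
    if poly_a and poly_b:
        value = "shared_polymorphic"
    elif poly_a:
        value = "vinifera_polymorphic"
    elif poly_b:
        value = "wild_polymorphic"
    elif fixed:
        value = "fixed_difference"
    else:
        value = "unclassified"
    return Segregation(value=value, poly_a=poly_a, poly_b=poly_b)


def segregation_summary(classes: list[Segregation]) -> dict[str, float]:
    """Shares of the disjoint partition plus the overlapping per-group
    shares.  The identity poly_a + poly_b - shared + fixed + unclassified = 1
    holds on the returned shares."""
    n = len(classes)
    if n == 0:
        raise ValueError("no classified SNPs")
    out = {v: sum(c.value == v for c in classes) / n for v in SEGREGATION_VALUES}
    out["share_polymorphic_a"] = sum(c.poly_a for c in classes) / n
    out["share_polymorphic_b"] = sum(c.poly_b for c in classes) / n
    return out


# ---------------------------------------------------------------------------
# EM haplotype frequencies and r^2


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab); A/B are the
    reference alleles."""

    f: np.ndarray  # length 4, sums to 1
    loglik: float
    n: int  # individuals used
    converged: bool

    @property
    def p_a(self) -> float:  # frequency of reference allele at locus 1
        return float(self.f[0] + self.f[1])

    @property
    def p_b(self) -> float:
        return float(self.f[0] + self.f[2])

    @property
    def d(self) -> float:
        return float(self.f[0] * self.f[3] - self.f[1] * self.f[2])

    @property
    def r2(self) -> float:
        pa, pb = self.p_a, self.p_b
        denom = pa * (1 - pa) * pb * (1 - pb)
        if denom <= 0:
            raise ValueError("r2 undefined at a monomorphic locus")
        return float(self.d**2 / denom)


def _pair_loglik(f: np.ndarray, n: np.ndarray) -> float:
    fAB, fAb, faB, fab = f
    probs = np.array(
        [
            fAB**2, 2 * fAB * fAb, fAb**2,
            2 * fAB * faB, 2 * fAB * fab + 2 * fAb * faB, 2 * fAb * fab,
            faB**2, 2 * faB * fab, fab**2,
        ]
    )
    mask = n.ravel() > 0
    p = probs[mask]
    if (p <= 0).any():
        return -np.inf
    return float(np.sum(n.ravel()[mask] * np.log(p)))


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """ML haplotype frequencies for two bi-allelic loci from unphased
    diploid genotypes (0/1/2 copies of the alternative allele).

    Individuals missing at either locus are excluded pairwise.  Raises
    ``ValueError`` when a locus is monomorphic after exclusions.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok].astype(np.int64), g2[ok].astype(np.int64)
    n_ind = len(g1)
    if n_ind < 2:
        raise ValueError("need >= 2 individuals with calls at both loci")
    counts = np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3).astype(float)
    pa = 1 - g1.sum() / (2 * n_ind)  # reference-allele frequency, locus 1
    pb = 1 - g2.sum() / (2 * n_ind)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus after pairwise exclusions")

    n = counts
    n_dh = n[1, 1]

    def em_from(f0: np.ndarray) -> tuple[np.ndarray, bool]:
        f = f0.copy()
        for _ in range(max_iter):
            cis, trans = f[0] * f[3], f[1] * f[2]
            w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
            hAB = 2 * n[0, 0] + n[0, 1] + n[1, 0] + w * n_dh
            hAb = 2 * n[0, 2] + n[0, 1] + n[1, 2] + (1 - w) * n_dh
            haB = 2 * n[2, 0] + n[1, 0] + n[2, 1] + (1 - w) * n_dh
            hab = 2 * n[2, 2] + n[2, 1] + n[1, 2] + w * n_dh
            f_new = np.array([hAB, hAb, haB, hab]) / (2 * n_ind)
            delta = np.max(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                return f, True
        return f, False

    # The linkage-equilibrium start (D = 0) is a stationary point of the EM
    # map, so also start from D displaced toward both coupling phases and
    # keep the highest-likelihood solution.
    d_hi = min(pa, pb) - pa * pb
    d_lo = max(0.0, pa + pb - 1) - pa * pb
    starts = []
    for d in (0.0, 0.5 * d_hi, 0.5 * d_lo):
        f0 = np.array(
            [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d,
             (1 - pa) * (1 - pb) + d]
        )
        starts.append(np.clip(f0, 1e-12, 1.0))
    best = None
    for f0 in starts:
        f, conv = em_from(f0 / f0.sum())
        ll = _pair_loglik(f, counts)
        if best is None or ll > best[1]:
            best = (f, ll, conv)
    f, ll, converged = best
    return HaplotypeFreqs(f=f, loglik=ll, n=n_ind, converged=converged)


def r2_pair(g1: np.ndarray, g2: np.ndarray) -> float | None:
    """EM-based r^2 for one pair of sites; None when not estimable."""
    try:
        hf = em_haplotype_freqs(g1, g2)
        return hf.r2
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# LD site filter, decay profile and background


def ld_site_filter(
    matrix: GenotypeMatrix,
    group: str | None = "cultivated",
    max_missing: int = 1,
    min_minor_copies: int = 2,
) -> GenotypeMatrix:
    """Restrict to one group and drop sites with too many missing calls or a
    singleton/monomorphic minor allele (< ``min_minor_copies`` copies among
    called genotypes)."""
    m = matrix.subset_samples(group) if group is not None else matrix
    keep = []
    for j in range(m.n_sites):
        col = m.calls[:, j]
        called = col != MISSING
        if (~called).sum() > max_missing:
            continue
        alt = int(col[called].sum())
        total = 2 * int(called.sum())
        if min(alt, total - alt) < min_minor_copies:
            continue
        keep.append(j)
    return m.subset_sites(keep)


@dataclass
class LDBin:
    """One bin of same-chromosome SNP-pair comparisons."""

    mean_distance: float
    median_r2: float
    n: int
    r2_values: np.ndarray
    p_vs_background: float | None = None


def _pair_r2_table(
    matrix: GenotypeMatrix, max_distance: int
) -> tuple[np.ndarray, np.ndarray]:
    """(distance, r2) for every scoreable same-chromosome pair."""
    dists, r2s = [], []
    n_skipped = 0
    by_chrom: dict[str, list[int]] = {}
    for j, (chrom, _) in enumerate(matrix.sites):
        by_chrom.setdefault(chrom, []).append(j)
    for chrom, idx in by_chrom.items():
        pos = np.array([matrix.sites[j][1] for j in idx])
        for x in range(len(idx)):
            for y in range(x + 1, len(idx)):
                d = abs(int(pos[y]) - int(pos[x]))
                if d == 0 or d > max_distance:
                    continue
                r2 = r2_pair(matrix.calls[:, idx[x]], matrix.calls[:, idx[y]])
                if r2 is None:
                    n_skipped += 1
                    continue
                dists.append(d)
                r2s.append(r2)
    if n_skipped:
        logger.info("skipped %d unscoreable pairs", n_skipped)
    return np.array(dists), np.array(r2s)


def ld_decay_profile(
    matrix: GenotypeMatrix,
    bin_size: int = 1000,
    max_distance: int = 40_000,
    keep_partial_bin: bool = False,
) -> list[LDBin]:
    """Median r^2 in sequential bins of ``bin_size`` pair comparisons,
    sorted by inter-SNP distance.  The trailing partial bin is dropped
    unless ``keep_partial_bin``."""
    dists, r2s = _pair_r2_table(matrix, max_distance)
    if len(dists) == 0:
        logger.warning("no scoreable SNP pairs; empty LD profile")
        return []
    order = np.argsort(dists, kind="stable")
    dists, r2s = dists[order], r2s[order]
    bins = []
    for start in range(0, len(dists), bin_size):
        chunk_d = dists[start : start + bin_size]
        chunk_r = r2s[start : start + bin_size]
        if len(chunk_d) < bin_size and not keep_partial_bin:
            break
        bins.append(
            LDBin(
                mean_distance=float(chunk_d.mean()),
                median_r2=float(np.median(chunk_r)),
                n=len(chunk_d),
                r2_values=chunk_r,
            )
        )
    return bins


def background_ld(
    matrix: GenotypeMatrix, n_pairs: int = 20_000, seed: int = 0
) -> np.ndarray:
    """r^2 for random SNP pairs on *different* chromosomes — the null
    distribution for LD-decay significance.  Pairs are drawn without
    replacement; when fewer than ``n_pairs`` exist all are used."""
    chroms = np.array([c for c, _ in matrix.sites])
    uniq = np.unique(chroms)
    if len(uniq) < 2:
        raise ValueError("background LD requires sites on >= 2 chromosomes")
    i_idx, j_idx = np.triu_indices(matrix.n_sites, k=1)
    cross = chroms[i_idx] != chroms[j_idx]
    i_idx, j_idx = i_idx[cross], j_idx[cross]
    total = len(i_idx)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x42474C]))
    if total <= n_pairs:
        logger.info("only %d inter-chromosomal pairs available; using all", total)
        chosen = np.arange(total)
    else:
        chosen = rng.choice(total, size=n_pairs, replace=False)
    out = []
    for t in chosen:
        r2 = r2_pair(matrix.calls[:, i_idx[t]], matrix.calls[:, j_idx[t]])
        if r2 is not None:
            out.append(r2)
    return np.array(out)


def mann_whitney_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney U p-value for x stochastically greater than y
    (exact on small tie-free inputs, else normal approximation with tie
    correction)."""
    res = stats.mannwhitneyu(x, y, alternative="greater", method="auto")
    return float(min(max(res.pvalue, np.nextafter(0.0, 1.0)), 1.0))


def mwu_bins(bins: list[LDBin], background: np.ndarray) -> list[float]:
    """Attach one-sided Mann-Whitney p-values (bin r^2 greater than the
    unlinked background) to each bin; returns the p-values."""
    if len(background) == 0:
        raise ValueError("background sample is empty")
    ps = []
    for b in bins:
        p = mann_whitney_greater(b.r2_values, background)
        b.p_vs_background = p
        ps.append(p)
    return ps


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n_samples, k)
    variance_fraction: np.ndarray  # (k,), non-increasing, sums to <= 1
    n_sites_used: int
    samples: list[str] = field(default_factory=list)


def pca(
    matrix: GenotypeMatrix,
    min_called_samples: int = 14,
    n_components: int = 10,
) -> PCAResult:
    """PCA of a genotype matrix coded 0/1/2 copies of the alternative allele.

    Sites called in fewer than ``min_called_samples`` samples or monomorphic
    among called genotypes are excluded; missing genotypes are imputed with
    the per-site mean; sites are centred and the sample coordinates taken
    from the singular value decomposition.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires >= 2 samples")
    X = matrix.calls.astype(float)
    X[matrix.calls == MISSING] = np.nan
    called = ~np.isnan(X)
    enough = called.sum(axis=0) >= min_called_samples
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(np.where(called, X, np.nan), axis=0)
        site_var = np.nanvar(np.where(called, X, np.nan), axis=0)
    poly = np.nan_to_num(site_var) > 0
    keep = enough & poly
    if not keep.any():
        raise ValueError("all sites excluded by the call-rate/monomorphism filters")
    Xk = X[:, keep]
    mu = site_mean[keep]
    inds = np.where(np.isnan(Xk))
    Xk[inds] = mu[inds[1]]
    Xc = Xk - mu
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    total = float((s**2).sum())
    return PCAResult(
        coordinates=u[:, :k] * s[:k],
        variance_fraction=(s[:k] ** 2) / total if total > 0 else np.zeros(k),
        n_sites_used=int(keep.sum()),
        samples=list(matrix.samples),
    )
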