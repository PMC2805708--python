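"""Synthetic reduced-representation library (RRL) sequencing data.

This module generates the inputs that an RRL SNP-discovery pipeline consumes,
with a known ground truth attached:

* a small diploid reference genome with a controlled density of *HpaII*
  recognition sites (CCGG),
* a panel of planted bi-allelic SNPs with a two-group (cultivated vs wild)
  structure, including variants that abolish a restriction site on one
  haplotype (the cause of allele dropout in real RRL data),
* an in-silico *HpaII* digestion of every haplotype (the enzyme cleaves
  C^CGG, so internal fragments begin with the CGG tag),
* 32 bp reads sampled from fragment ends, with amplification strongly biased
  toward fragments inside a preferred size window and a substitution-error
  rate that rises toward the end of the read.

Coordinates are 0-based half-open internally; text outputs (pileup, truth
table, VCF) are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

READ_LEN = 32
RECOGNITION_SITE = b"CCGG"
CUT_OFFSET = 1  # HpaII cleaves C^CGG
TAG = "CGG"

_BASES = b"ACGT"
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")
# ASCII byte -> 0..3 index (A,C,G,T); N and others map to 4
_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i
_INDEX_BASE = np.frombuffer(_BASES, dtype=np.uint8)


def revcomp(seq: str | bytes) -> str | bytes:
    if isinstance(seq, str):
        return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# error / quality profile


@dataclass(frozen=True)
class ErrorProfile:
    """Per-offset substitution probabilities and reported base qualities.

    ``rates[i]`` is the substitution probability at within-read offset i+1.
    ``quality_means[i]`` is the mean *reported* Phred quality at that offset.
    The two are deliberately decoupled: base callers are systematically
    overconfident near read ends, so reported qualities decline more gently
    than the true error rate rises.
    """

    rates: np.ndarray
    quality_means: np.ndarray
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        quals = np.asarray(self.quality_means, dtype=float)
        if rates.shape != (READ_LEN,) or quals.shape != (READ_LEN,):
            raise ValueError(f"profiles must have length {READ_LEN}")
        if np.any(rates < 0) or np.any(rates > 0.25):
            raise ValueError("substitution rates must lie in [0, 0.25]")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "quality_means", quals)

    @classmethod
    def default(cls) -> "ErrorProfile":
        """Error rate linear 0.002 -> 0.02, reported quality 34 -> 22."""
        return cls(
            rates=np.linspace(0.002, 0.02, READ_LEN),
            quality_means=np.linspace(34.0, 22.0, READ_LEN),
        )

    @classmethod
    def flat(cls, rate: float, quality: float = 30.0) -> "ErrorProfile":
        return cls(
            rates=np.full(READ_LEN, rate),
            quality_means=np.full(READ_LEN, quality),
        )


# ---------------------------------------------------------------------------
# genome


@dataclass
class SyntheticGenome:
    """A toy multi-chromosome reference with known CCGG site placement."""

    chromosomes: dict[str, str]
    seed: int
    site_density: float
    repeat_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chromosomes) < 2:
            raise ValueError(
                "at least 2 chromosomes are required (background LD needs "
                "physically unlinked loci)"
            )
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"chromosome {name} contains non-ACGTN characters")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def sequence_bytes(self, chrom: str) -> bytes:
        return self.chromosomes[chrom].encode()


def _scrub_sites(seq: bytearray, keep: set[int]) -> None:
    """Destroy every CCGG occurrence whose start is not in ``keep``.

    Replacement base is 'A', which can never complete a new CCGG, so the
    loop terminates.
    """
    while True:
        dirty = False
        pos = bytes(seq).find(RECOGNITION_SITE)
        while pos != -1:
            if pos not in keep:
                seq[pos + 1] = ord("A")
                dirty = True
            pos = bytes(seq).find(RECOGNITION_SITE, pos + 1)
        if not dirty:
            return


def generate_genome(
    n_chroms: int = 2,
    chrom_length: int = 100_000,
    gc_fraction: float = 0.45,
    site_density: float = 5.0,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a random genome with ~``site_density`` CCGG sites per kb.

    Sites are planted explicitly at random, well-separated positions;
    incidental occurrences arising from the random background are removed
    so the realised density tracks the request.
    """
    if n_chroms < 2:
        raise ValueError("n_chroms must be >= 2")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in (0, 1)")
    if site_density < 0:
        raise ValueError("site_density must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x47454E]))
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    chroms: dict[str, str] = {}
    for c in range(n_chroms):
        idx = rng.choice(4, size=chrom_length, p=p)
        seq = bytearray(_INDEX_BASE[idx].tobytes())
        n_sites = int(round(site_density * chrom_length / 1000))
        planted: set[int] = set()
        if n_sites > 0:
            # uniform site positions across the chromosome, >= 8 bp apart
            cand = rng.choice(
                np.arange(20, chrom_length - 40), size=min(3 * n_sites, chrom_length // 10),
                replace=False,
            )
            cand.sort()
            spaced = []
            last = -100
            for q in cand:
                if q - last >= 8:
                    spaced.append(int(q))
                    last = q
            if len(spaced) < n_sites:
                raise ValueError("site_density too high for the chromosome length")
            keep = rng.choice(len(spaced), size=n_sites, replace=False)
            planted = {spaced[i] for i in keep}
        _scrub_sites(seq, planted)
        for q in planted:
            seq[q : q + 4] = RECOGNITION_SITE
        _scrub_sites(seq, planted)
        chroms[f"chr{c + 1}"] = seq.decode()
    return SyntheticGenome(chromosomes=chroms, seed=seed, site_density=site_density)


# ---------------------------------------------------------------------------
# digestion


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _cut_positions(seq: bytes) -> list[int]:
    cuts = []
    pos = seq.find(RECOGNITION_SITE)
    while pos != -1:
        cuts.append(pos + CUT_OFFSET)
        pos = seq.find(RECOGNITION_SITE, pos + 1)
    return cuts


def digest(sequence: str | bytes, chrom: str = "chr") -> list[Fragment]:
    """In-silico *HpaII* digestion: cut at C^CGG.

    The returned fragments tile the sequence exactly; every fragment except
    the first begins with CGG and every fragment except the last ends with C.
    """
    if len(sequence) == 0:
        raise ValueError("cannot digest an empty sequence")
    seq = sequence.encode() if isinstance(sequence, str) else sequence
    bounds = [0] + _cut_positions(seq) + [len(seq)]
    return [
        Fragment(chrom, bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]


# ---------------------------------------------------------------------------
# truth panel


@dataclass
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: np.ndarray  # (n_samples,) copies of alt in {0,1,2}
    alt_hap: np.ndarray  # (n_samples,) haplotype carrying alt when het, else -1
    disrupts_site: bool
    klass: str  # planted segregation class


@dataclass
class TruthPanel:
    """Planted variants plus the diploid genotypes of every sample."""

    samples: list[tuple[str, str]]  # (sample_id, group)
    variants: list[Variant]

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    @property
    def groups(self) -> list[str]:
        return [g for _, g in self.samples]

    def variants_by_chrom(self) -> dict[str, list[Variant]]:
        out: dict[str, list[Variant]] = {}
        for v in self.variants:
            out.setdefault(v.chrom, []).append(v)
        return out


DEFAULT_CLASS_MIX = {
    # disjoint shares emulating the observed segregation structure:
    # 68.5% cultivated-polymorphic and 53.1% wild-polymorphic with 24.3%
    # shared and 2.7% fixed gives these exclusive shares.
    "vinifera_only": 0.442,
    "wild_only": 0.288,
    "shared": 0.243,
    "fixed": 0.027,
}


def default_samples(n_cultivated: int = 11, n_wild: int = 6) -> list[tuple[str, str]]:
    """17-sample panel: 11 cultivated (incl. the reference line) + 6 wild."""
    cult = [(f"vinifera_{i:02d}", "cultivated") for i in range(1, n_cultivated + 1)]
    wild = [(f"wild_{i:02d}", "wild") for i in range(1, n_wild + 1)]
    return cult + wild


def _class_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    total = sum(mix.values())
    if total > 1 + 1e-9:
        raise ValueError("class mixture proportions must sum to <= 1")
    probs = {k: v / total for k, v in mix.items()}
    counts = {k: int(math.floor(p * n)) for k, p in probs.items()}
    # largest-remainder rounding
    rem = n - sum(counts.values())
    order = sorted(probs, key=lambda k: probs[k] * n - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def _draw_group_genotypes(
    rng: np.random.Generator, n: int, freq: float, polymorphic: bool
) -> np.ndarray:
    """HWE genotypes, optionally conditioned on both alleles being present."""
    for _ in range(1000):
        g = rng.binomial(2, freq, size=n)
        if not polymorphic:
            return g
        alt = int(g.sum())
        if 0 < alt < 2 * n:
            return g
    raise RuntimeError("failed to draw polymorphic genotypes")


def _creates_site(seq: bytes, pos: int, alt: str) -> bool:
    lo = max(0, pos - 3)
    window = bytearray(seq[lo : pos + 4])
    window[pos - lo] = ord(alt)
    return bytes(window).find(RECOGNITION_SITE) != -1


def plant_variants(
    genome: SyntheticGenome,
    n_snps: int = 600,
    maf_range: tuple[float, float] = (0.1, 0.5),
    class_mix: dict[str, float] | None = None,
    restriction_disruption_rate: float = 0.05,
    samples: list[tuple[str, str]] | None = None,
    size_window: tuple[int, int] = (40, 250),
    seed: int = 0,
) -> TruthPanel:
    """Plant bi-allelic SNPs with a cultivated/wild group structure.

    Variants are placed inside the read-accessible terminal windows of
    digestion fragments (offsets 4..32 from a cut, sparing the CGG tag).
    A fraction ``restriction_disruption_rate`` of variants is placed inside
    a CCGG site instead, with the alternative allele abolishing the cut on
    the carrying haplotype (allele dropout).
    """
    if samples is None:
        samples = default_samples()
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x504C54]))
    n_disrupt = int(round(restriction_disruption_rate * n_snps))
    n_plain = n_snps - n_disrupt

    groups = np.array([g for _, g in samples])
    n_cult = int((groups == "cultivated").sum())
    n_wild = int((groups == "wild").sum())
    if n_cult == 0 or n_wild == 0:
        raise ValueError("both cultivated and wild samples are required")

    # -- candidate positions in sequenced fragment-end zones ---------------
    # Variants are planted in the terminal read windows of fragments inside
    # the amplified size range: that is the genome fraction the assay
    # interrogates at genotypable depth.  (Fragments outside the window are
    # still sequenced at low depth and contribute error-driven candidate
    # sites, but a variant there is below the detection design point.)
    lo_w, hi_w = size_window
    zone_positions: list[tuple[str, int]] = []
    cut_sites: list[tuple[str, int]] = []  # start of usable CCGG occurrences
    site_spans: dict[str, set[int]] = {}
    for chrom, seq in genome.chromosomes.items():
        sb = seq.encode()
        cuts = _cut_positions(sb)
        spans: set[int] = set()
        for c in cuts:
            spans.update(range(c - 1, c + 3))
        site_spans[chrom] = spans
        frags = digest(sb, chrom)
        cutset = set(cuts)
        for fr in frags:
            if fr.length < READ_LEN or not lo_w <= fr.length <= hi_w:
                continue
            if fr.start in cutset:  # forward-sequenced end, spare the tag
                for p in range(fr.start + 3, min(fr.start + READ_LEN, fr.end)):
                    if p not in spans and sb[p] != ord("N"):
                        zone_positions.append((chrom, p))
            if fr.end in cutset:  # reverse-sequenced end
                for p in range(max(fr.start, fr.end - 30), fr.end - 1):
                    if p not in spans and sb[p] != ord("N"):
                        zone_positions.append((chrom, p))
                # the cut closing an in-window fragment is covered by its
                # reverse reads; usable for a site-disrupting variant
                cut_sites.append((chrom, fr.end - 1))
    zone_positions = sorted(set(zone_positions))
    if n_plain > len(zone_positions):
        raise ValueError(
            f"requested {n_plain} placeable variants but only "
            f"{len(zone_positions)} accessible positions exist"
        )
    if n_disrupt > len(cut_sites):
        raise ValueError("not enough restriction sites for the disruption rate")

    pick = rng.choice(len(zone_positions), size=n_plain, replace=False)
    plain_pos = [zone_positions[i] for i in pick]
    pick = rng.choice(len(cut_sites), size=n_disrupt, replace=False)
    disrupt_sites = [cut_sites[i] for i in pick]

    # -- classes and genotypes --------------------------------------------
    counts = _class_counts(n_snps, mix)
    klasses = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(klasses)

    variants: list[Variant] = []
    lo, hi = maf_range

    def genotypes_for(klass: str) -> np.ndarray:
        g = np.zeros(len(samples), dtype=np.int8)
        if klass == "vinifera_only":
            f = rng.uniform(lo, hi)
            g[groups == "cultivated"] = _draw_group_genotypes(rng, n_cult, f, True)
        elif klass == "wild_only":
            f = rng.uniform(lo, hi)
            g[groups == "wild"] = _draw_group_genotypes(rng, n_wild, f, True)
        elif klass == "shared":
            g[groups == "cultivated"] = _draw_group_genotypes(
                rng, n_cult, rng.uniform(lo, hi), True
            )
            g[groups == "wild"] = _draw_group_genotypes(
                rng, n_wild, rng.uniform(lo, hi), True
            )
        elif klass == "fixed":
            if rng.random() < 0.5:
                g[groups == "wild"] = 2
            else:
                g[groups == "cultivated"] = 2
        else:
            raise ValueError(f"unknown variant class {klass!r}")
        return g

    idx = 0
    for chrom, pos in plain_pos:
        seq = genome.sequence_bytes(chrom)
        ref = chr(seq[pos])
        alts = [b for b in "ACGT" if b != ref and not _creates_site(seq, pos, b)]
        if not alts:
            continue
        alt = alts[int(rng.integers(len(alts)))]
        g = genotypes_for(klasses[idx])
        hap = np.where(g == 1, rng.integers(0, 2, size=len(samples)), -1).astype(np.int8)
        variants.append(Variant(chrom, pos, ref, alt, g, hap, False, klasses[idx]))
        idx += 1

    for chrom, site_start in disrupt_sites:
        seq = genome.sequence_bytes(chrom)
        pos = site_start + int(rng.integers(4))
        ref = chr(seq[pos])
        alts = [b for b in "ACGT" if b != ref and not _creates_site(seq, pos, b)]
        if not alts:
            continue
        alt = alts[int(rng.integers(len(alts)))]
        g = genotypes_for(klasses[idx])
        hap = np.where(g == 1, rng.integers(0, 2, size=len(samples)), -1).astype(np.int8)
        variants.append(Variant(chrom, pos, ref, alt, g, hap, True, klasses[idx]))
        idx += 1

    variants.sort(key=lambda v: (v.chrom, v.pos))
    # positions unique per chromosome by construction (sampling w/o replacement)
    return TruthPanel(samples=list(samples), variants=variants)


# ---------------------------------------------------------------------------
# reads


class Read(NamedTuple):
    sample_id: str
    chrom: str
    start: int  # leftmost reference position of the 32 bp alignment
    strand: str  # '+' or '-'
    sequence: str  # in read orientation (5'->3' of the read)
    qualities: np.ndarray


@dataclass
class ReadSet:
    """Columnar container of simulated, pre-placed 32 bp reads.

    ``seq`` holds bases in read orientation; a '-' strand read aligns to
    ``[start, start + 32)`` with its reverse complement.
    """

    samples: list[str]
    chroms: list[str]
    sample_idx: np.ndarray
    chrom_idx: np.ndarray
    start: np.ndarray
    strand: np.ndarray  # 0 forward, 1 reverse
    seq: np.ndarray  # (n, 32) uint8 ASCII
    qual: np.ndarray  # (n, 32) uint8

    def __len__(self) -> int:
        return len(self.start)

    def iter_reads(self) -> Iterator[Read]:
        for i in range(len(self)):
            yield Read(
                self.samples[self.sample_idx[i]],
                self.chroms[self.chrom_idx[i]],
                int(self.start[i]),
                "-" if self.strand[i] else "+",
                self.seq[i].tobytes().decode(),
                self.qual[i],
            )

    def tag_fraction(self) -> float:
        """Fraction of reads beginning with the CGG tag."""
        tag = np.frombuffer(b"CGG", dtype=np.uint8)
        return float(np.mean(np.all(self.seq[:, :3] == tag, axis=1)))


def _haplotype_sequence(
    ref: bytes, variants: Sequence[Variant], sample: int, hap: int
) -> bytearray:
    seq = bytearray(ref)
    for v in variants:
        g = v.genotypes[sample]
        if g == 2 or (g == 1 and v.alt_hap[sample] == hap):
            seq[v.pos] = ord(v.alt)
    return seq


def _sequenced_ends(
    seq: bytes, chrom_len: int, size_window: tuple[int, int],
    weight_in: float, weight_out: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start, strand, weight) for every sequenceable fragment end.

    Only ends at genuine cuts are sequenced (terminal fragment outer ends
    have no ligatable overhang) and only fragments >= 32 bp are usable.
    """
    cuts = _cut_positions(seq)
    cutset = set(cuts)
    bounds = [0] + cuts + [len(seq)]
    starts, strands, weights = [], [], []
    lo, hi = size_window
    for i in range(len(bounds) - 1):
        fs, fe = bounds[i], bounds[i + 1]
        length = fe - fs
        if length < READ_LEN:
            continue
        w = weight_in if lo <= length <= hi else weight_out
        if fs in cutset:
            starts.append(fs)
            strands.append(0)
            weights.append(w)
        if fe in cutset:
            # reverse read covers [fe-30, fe+2): its first three bases are
            # the CGG tag of the bottom-strand cut (CCGG is palindromic)
            starts.append(fe - 30)
            strands.append(1)
            weights.append(w)
    return (
        np.array(starts, dtype=np.int64),
        np.array(strands, dtype=np.int8),
        np.array(weights, dtype=float),
    )


def simulate_reads(
    genome: SyntheticGenome,
    panel: TruthPanel,
    mean_depth: float = 20.0,
    size_window: tuple[int, int] = (40, 250),
    weight_in: float = 10.0,
    weight_out: float = 1.0,
    error_profile: ErrorProfile | None = None,
    seed: int = 0,
) -> ReadSet:
    """Simulate per-sample RRL reads from both haplotypes.

    ``mean_depth`` is the expected per-sample read depth at the terminal
    window of a fragment inside ``size_window``; ends outside the window
    receive depth scaled by ``weight_out / weight_in``. A haplotype whose
    planted variant abolishes a CCGG site is never sequenced from that cut.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    profile = error_profile or ErrorProfile.default()
    ss = np.random.SeedSequence([seed, 0x52454144])
    by_chrom = panel.variants_by_chrom()
    chrom_names = genome.names
    sample_ids = panel.sample_ids

    out_sample, out_chrom, out_start, out_strand = [], [], [], []
    out_seq, out_qual = [], []

    children = ss.spawn(len(sample_ids))
    for s, sid in enumerate(sample_ids):
        rng = np.random.default_rng(children[s])
        for hap in (0, 1):
            for ci, chrom in enumerate(chrom_names):
                ref = genome.sequence_bytes(chrom)
                hapseq = _haplotype_sequence(ref, by_chrom.get(chrom, []), s, hap)
                hb = bytes(hapseq)
                starts, strands, weights = _sequenced_ends(
                    hb, len(hb), size_window, weight_in, weight_out
                )
                if len(starts) == 0:
                    raise ValueError(
                        f"no sequenceable fragments on {chrom}; "
                        "increase site density or chromosome length"
                    )
                w_total = weights.sum()
                n_reads = int(round(mean_depth / 2 * w_total / weight_in))
                if n_reads == 0:
                    continue
                chosen = rng.choice(len(starts), size=n_reads, p=weights / w_total)
                rstart = starts[chosen]
                rstrand = strands[chosen]

                arr = np.frombuffer(hb, dtype=np.uint8)
                mat = arr[rstart[:, None] + np.arange(READ_LEN)[None, :]].copy()
                rev = rstrand == 1
                if rev.any():
                    # read orientation: reverse-complement the ref window
                    sub = mat[rev][:, ::-1]
                    mat[rev] = _INDEX_BASE[(3 - _BASE_INDEX[sub]) % 4]
                # substitution errors, rate rising along the read
                err = rng.random(mat.shape) < profile.rates[None, :]
                if err.any():
                    idx = _BASE_INDEX[mat[err]]
                    shift = rng.integers(1, 4, size=idx.shape)
                    mat[err] = _INDEX_BASE[(idx + shift) % 4]
                qual = np.clip(
                    np.rint(
                        rng.normal(
                            profile.quality_means[None, :],
                            profile.quality_sd,
                            size=mat.shape,
                        )
                    ),
                    2,
                    40,
                ).astype(np.uint8)

                out_sample.append(np.full(n_reads, s, dtype=np.int32))
                out_chrom.append(np.full(n_reads, ci, dtype=np.int32))
                out_start.append(rstart)
                out_strand.append(rstrand)
                out_seq.append(mat)
                out_qual.append(qual)

    return ReadSet(
        samples=sample_ids,
        chroms=chrom_names,
        sample_idx=np.concatenate(out_sample),
        chrom_idx=np.concatenate(out_chrom),
        start=np.concatenate(out_start),
        strand=np.concatenate(out_strand),
        seq=np.vstack(out_seq),
        qual=np.vstack(out_qual),
    )


def uniform_readset(
    genome: SyntheticGenome, mean_depth: float, seed: int = 0
) -> ReadSet:
    """Un-enriched control: reads placed uniformly at random (one pooled
    sample, no errors). Used to check the Lander-Waterman expectation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x554E49]))
    lengths = genome.lengths()
    total = sum(lengths.values())
    n_reads = int(round(mean_depth * total / READ_LEN))
    names = genome.names
    probs = np.array([lengths[c] - READ_LEN + 1 for c in names], dtype=float)
    probs /= probs.sum()
    chrom_idx = rng.choice(len(names), size=n_reads, p=probs)
    starts = np.empty(n_reads, dtype=np.int64)
    seqs = np.empty((n_reads, READ_LEN), dtype=np.uint8)
    for ci, chrom in enumerate(names):
        mask = chrom_idx == ci
        n = int(mask.sum())
        st = rng.integers(0, lengths[chrom] - READ_LEN + 1, size=n)
        starts[mask] = st
        arr = np.frombuffer(genome.sequence_bytes(chrom), dtype=np.uint8)
        seqs[mask] = arr[st[:, None] + np.arange(READ_LEN)[None, :]]
    return ReadSet(
        samples=["pool"],
        chroms=names,
        sample_idx=np.zeros(n_reads, dtype=np.int32),
        chrom_idx=chrom_idx.astype(np.int32),
        start=starts,
        strand=np.zeros(n_reads, dtype=np.int8),
        seq=seqs,
        qual=np.full((n_reads, READ_LEN), 30, dtype=np.uint8),
    )


# ---------------------------------------------------------------------------
# block-structured genotypes (for LD-decay validation)


def simulate_block_genotypes(
    n_samples: int = 10,
    n_chroms: int = 2,
    chrom_length: int = 100_000,
    n_sites_per_chrom: int = 300,
    block_length: int = 5_000,
    freq_range: tuple[float, float] = (0.25, 0.75),
    site_noise: float = 0.02,
    group: str = "cultivated",
    seed: int = 0,
):
    """Genotypes from block-structured haplotypes.

    Within a block of ``block_length`` bp sites ride on one of two founder
    haplotypes (near-complete LD); across blocks the founder choice is
    independent, so r2 between blocks matches the unlinked background.
    ``site_noise`` is a small per-site, per-haplotype flip probability
    (mutation/gene conversion) that keeps sites within a block from being
    exact copies of each other.
    """
    from .genotyping import GenotypeMatrix

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x424C4B]))
    samples = [f"s{i:02d}" for i in range(n_samples)]
    sites: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    n_hap = 2 * n_samples
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = np.sort(rng.choice(chrom_length, size=n_sites_per_chrom, replace=False))
        blocks = pos // block_length
        for b in np.unique(blocks):
            # founder assignment for each haplotype, kept clear of fixation
            while True:
                q = rng.uniform(*freq_range)
                hap_assign = rng.random(n_hap) < q
                k = int(hap_assign.sum())
                if 2 <= k <= n_hap - 2:
                    break
            for p in pos[blocks == b]:
                hap = hap_assign.copy()
                if site_noise > 0:
                    flip = rng.random(n_hap) < site_noise
                    hap = hap ^ flip
                sites.append((chrom, int(p)))
                cols.append(
                    hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
                )
    calls = np.stack(cols, axis=1)
    return GenotypeMatrix(
        samples=samples,
        groups=[group] * n_samples,
        sites=sites,
        ref_alleles=["A"] * len(sites),
        alt_alleles=["G"] * len(sites),
        calls=calls,
        source="truth_block",
    )


# ---------------------------------------------------------------------------
# file emission

def write_fasta(genome: SyntheticGenome, path: str | Path) -> Path:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_sam(readset: ReadSet, genome_lengths: dict[str, int], path: str | Path) -> Path:
    """Write read placements as plain-text SAM (reverse reads stored on the
    forward genome strand per SAM convention)."""
    import pysam

    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome_lengths[c]} for c in readset.chroms],
        "RG": [{"ID": s, "SM": s} for s in readset.samples],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i in range(len(readset)):
            a = pysam.AlignedSegment(fh.header)
            sid = readset.samples[readset.sample_idx[i]]
            a.query_name = f"{sid}.{i}"
            a.flag = 16 if readset.strand[i] else 0
            a.reference_id = int(readset.chrom_idx[i])
            a.reference_start = int(readset.start[i])
            a.mapping_quality = 60
            a.cigartuples = [(0, READ_LEN)]
            seq = readset.seq[i].tobytes()
            qual = readset.qual[i]
            if readset.strand[i]:
                seq = revcomp(seq)
                qual = qual[::-1]
            a.query_sequence = seq.decode()
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            a.set_tag("RG", sid)
            fh.write(a)
    return path


def read_sam(path: str | Path) -> ReadSet:
    import pysam

    samples: list[str] = []
    sample_pos: dict[str, int] = {}
    rows: list[tuple[int, int, int, int, bytes, np.ndarray]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        chroms = list(fh.references)
        for a in fh:
            sid = a.get_tag("RG") if a.has_tag("RG") else a.query_name.rsplit(".", 1)[0]
            if sid not in sample_pos:
                sample_pos[sid] = len(samples)
                samples.append(sid)
            seq = a.query_sequence.encode()
            qual = np.array(a.query_qualities, dtype=np.uint8)
            if a.is_reverse:
                seq = revcomp(seq)
                qual = qual[::-1]
            rows.append(
                (sample_pos[sid], a.reference_id, a.reference_start,
                 int(a.is_reverse), seq, qual)
            )
    n = len(rows)
    return ReadSet(
        samples=samples,
        chroms=chroms,
        sample_idx=np.array([r[0] for r in rows], dtype=np.int32),
        chrom_idx=np.array([r[1] for r in rows], dtype=np.int32),
        start=np.array([r[2] for r in rows], dtype=np.int64),
        strand=np.array([r[3] for r in rows], dtype=np.int8),
        seq=np.vstack([np.frombuffer(r[4], dtype=np.uint8) for r in rows])
        if n
        else np.empty((0, READ_LEN), dtype=np.uint8),
        qual=np.vstack([r[5] for r in rows])
        if n
        else np.empty((0, READ_LEN), dtype=np.uint8),
    )


def write_truth(panel: TruthPanel, path: str | Path) -> Path:
    path = Path(path)
    ids = panel.sample_ids
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tclass\tdisrupts_site\t")
        fh.write("\t".join(ids) + "\t" + "\t".join(f"hap_{s}" for s in ids) + "\n")
        fh.write("#groups\t" + "\t".join(panel.groups) + "\n")
        for v in panel.variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.klass}\t"
                f"{int(v.disrupts_site)}\t"
                + "\t".join(str(int(g)) for g in v.genotypes)
                + "\t"
                + "\t".join(str(int(h)) for h in v.alt_hap)
                + "\n"
            )
    return path


def read_truth(path: str | Path) -> TruthPanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        n_fixed = 6
        n_samples = (len(header) - n_fixed) // 2
        ids = header[n_fixed : n_fixed + n_samples]
        groups_line = fh.readline().rstrip("\n").split("\t")
        groups = groups_line[1 : 1 + n_samples]
        variants = []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            g = np.array([int(x) for x in f[6 : 6 + n_samples]], dtype=np.int8)
            h = np.array(
                [int(x) for x in f[6 + n_samples : 6 + 2 * n_samples]], dtype=np.int8
            )
            variants.append(
                Variant(f[0], int(f[1]) - 1, f[2], f[3], g, h, bool(int(f[5])), f[4])
            )
    return TruthPanel(samples=list(zip(ids, groups)), variants=variants)


def emit_outputs(
    readset: ReadSet,
    panel: TruthPanel,
    genome: SyntheticGenome,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write reference FASTA, SAM placements, site pileup and truth table."""
    from .discovery import aggregate_pileup, write_pileup

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": write_fasta(genome, outdir / "reference.fasta"),
        "sam": write_sam(readset, genome.lengths(), outdir / "reads.sam"),
        "truth": write_truth(panel, outdir / "truth.tsv"),
    }
    sites = aggregate_pileup(readset, genome)
    paths["pileup"] = write_pileup(sites, outdir / "pileup.tsv")
    return paths
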