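"""Shared fixtures: one full synthetic run at the default study conditions
(2 x 100 kb genome, 17 samples, 20x fragment-end depth), reused by the
module tests and the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

import rrlsnp as r

RUN_SEED = 101


@pytest.fixture(scope="session")
def default_run():
    genome = r.generate_genome(
        n_chroms=2, chrom_length=100_000, gc_fraction=0.45, site_density=5.0,
        seed=RUN_SEED,
    )
    panel = r.plant_variants(genome, n_snps=600, seed=RUN_SEED)
    readset = r.simulate_reads(genome, panel, mean_depth=20.0, seed=RUN_SEED)
    sites = list(r.aggregate_pileup(readset, genome))
    result = r.discover(iter(sites), seed=RUN_SEED)
    return {
        "genome": genome,
        "panel": panel,
        "readset": readset,
        "sites": sites,
        "result": result,
        "site_by_pos": {(s.chrom, s.pos): s for s in sites},
        "truth_by_pos": {(v.chrom, v.pos): v for v in panel.variants},
    }


@pytest.fixture(scope="session")
def eligible_truth(default_run):
    """Planted variants whose site passes the depth and minor-fraction
    conditions the discovery rules are designed for."""
    out = []
    for key, v in default_run["truth_by_pos"].items():
        s = default_run["site_by_pos"].get(key)
        if s is None:
            continue
        totals = s.allele_totals()
        depth = sum(totals.values())
        ordered = s.ordered_alleles()
        if len(ordered) < 2:
            continue
        if 10 <= depth <= 1000 and totals[ordered[1]] / depth > 0.05:
            out.append((key, v))
    return out


def make_site(per_sample, ref="A", chrom="chr1", pos=0, qual=30):
    """Build a SiteCounts from {sample: {allele: count}} with uniform
    qualities and offsets at position 10."""
    counts = {s: dict(a) for s, a in per_sample.items()}
    qual_sum = {
        s: {a: qual * c for a, c in per.items()} for s, per in counts.items()
    }
    offsets = {}
    for s, per in counts.items():
        offsets[s] = {}
        for a, c in per.items():
            h = np.zeros(32, dtype=np.int64)
            h[9] = c
            offsets[s][a] = h
    return r.SiteCounts(
        chrom=chrom, pos=pos, ref=ref, counts=counts, qual_sum=qual_sum,
        offsets=offsets,
    )
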