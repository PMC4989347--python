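"""Shared fixtures: hand-built variant sets and session-scoped synthetic cohorts."""

from __future__ import annotations

import pytest

from somaphyl.partition import partition_cohort
from somaphyl.synthetic_data import SimConfig, scaled_config, simulate_cohort
from somaphyl.variant_io import Variant, VariantSet


def make_variant(chrom="1", pos=100, ref="C", alt="T", **kw) -> Variant:
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def make_set(keys, sample_id="S", tissue="PTC", **kw) -> VariantSet:
    """VariantSet from (chrom, pos, ref, alt) tuples."""
    return VariantSet(
        sample_id, tissue, [Variant(chrom=c, pos=p, ref=r, alt=a, **kw) for c, p, r, a in keys]
    )


def keyset(*positions, chrom="1", ref="C", alt="T"):
    """Distinct keys at the given positions with a fixed substitution."""
    return [(chrom, p, ref, alt) for p in positions]


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions: 20 patients, all defaults."""
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def default_partitions(default_sim):
    return partition_cohort(default_sim.as_cohort())


@pytest.fixture(scope="session")
def small_sim():
    """A down-scaled cohort for cheap structural tests."""
    cfg = scaled_config(SimConfig(n_patients=5, seed=7), 0.1)
    return simulate_cohort(cfg)
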