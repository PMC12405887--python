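"""Shared fixtures: small synthetic panels and hand-built variant tables."""

import numpy as np
import pytest

from cyberphenom import synthgen
from cyberphenom.variant_io import PAD, VariantTable


def build_table(contigs, sites, strains):
    """Hand-build a VariantTable.

    ``sites`` is a list of (chrom, pos, ref, alts, per-strain calls) where
    each call is (allele_tuple, ad_ref, ad_alt, dp); allele None means a
    missing slot.
    """
    n = len(sites)
    s = len(strains)
    max_pl = max(len(call[0]) for _, _, _, _, calls in sites for call in calls)
    max_alt = max(len(alts) for _, _, _, alts, _ in sites)
    gt = np.full((n, s, max_pl), PAD, dtype=np.int8)
    ad_ref = np.full((n, s), -1, dtype=np.int32)
    ad_alt = np.full((n, s, max_alt), -1, dtype=np.int32)
    dp = np.full((n, s), -1, dtype=np.int32)
    chrom, pos, ref, alts_all = [], [], [], []
    for i, (c, p, r, alts, calls) in enumerate(sites):
        chrom.append(c)
        pos.append(p)
        ref.append(r)
        alts_all.append(tuple(alts))
        for j, (alleles, adr, ada, d) in enumerate(calls):
            gt[i, j, : len(alleles)] = [(-1 if a is None else a) for a in alleles]
            ad_ref[i, j] = adr
            if np.isscalar(ada):
                ad_alt[i, j, 0] = ada
            else:
                ad_alt[i, j, : len(ada)] = ada
            dp[i, j] = d
    return VariantTable(
        contigs=dict(contigs),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=alts_all,
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
        strains=list(strains),
    )


def het(ad=30, ploidy=2, alt_copies=1):
    """Convenience call tuple for build_table."""
    alleles = tuple([0] * (ploidy - alt_copies) + [1] * alt_copies)
    return (alleles, ad, ad, 2 * ad)


def hom_ref(ad=30, ploidy=2):
    return (tuple([0] * ploidy), ad, 0, ad)


def hom_alt(ad=30, ploidy=2):
    return (tuple([1] * ploidy), 0, ad, ad)


@pytest.fixture(scope="session")
def default_config():
    return synthgen.SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale panel (1/1000 genome) for fast genotype tests."""
    return synthgen.SimulationConfig(seed=101, genome_scale=0.001)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthgen.simulate_genotypes(small_config)
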