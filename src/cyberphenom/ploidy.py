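"""Ploidy and aneuploidy inference from allele balance and read depth.

Genome ploidy (2n vs 3n) is decided by comparing two per-site likelihood
models of the B-allele frequency at heterozygous-candidate sites: a
diploid model with a single allele-balance mode at 1/2, and a triploid
model that is an equal-weight mixture of modes at 1/3 and 2/3.  Both use
the same beta-binomial overdispersion, so the comparison carries no
parameter-count penalty.  Chromosome copy numbers are then called from
normalized per-window read depth, and a strain is aneuploid when any
chromosome's copy number deviates from the genome ploidy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .variant_io import GenomeWindows, VariantTable

logger = logging.getLogger(__name__)

#: heterozygous-candidate band: excludes homozygous calls and sequencing-error
#: tails without truncating the 1/3 and 2/3 modes
BAF_BAND = (0.10, 0.90)
MIN_BAND_DEPTH = 10

_HET_MODES = np.array([1 / 3, 1 / 2, 2 / 3])


class UnclassifiableStrainError(ValueError):
    """Too few usable sites to classify a strain."""


@dataclass
class BafProfile:
    """Per-site B-allele frequencies of one strain at heterozygous-candidate
    biallelic sites, sorted by (chrom, pos)."""

    strain: str
    chrom: np.ndarray
    pos: np.ndarray
    baf: np.ndarray
    depth: np.ndarray  # ref + alt reads at the site

    @property
    def n_sites(self) -> int:
        return len(self.baf)


@dataclass
class PloidyCall:
    """Genome ploidy call plus per-chromosome copy numbers for one strain."""

    strain: str
    ploidy: int
    loglik_diploid: float
    loglik_triploid: float
    n_sites: int
    rho: float
    low_confidence: bool = False
    chrom_copies: dict[str, int] = field(default_factory=dict)
    depth_ratio: dict[str, float] = field(default_factory=dict)

    @property
    def aneuploid(self) -> bool:
        return any(c != self.ploidy for c in self.chrom_copies.values())

    @property
    def euploid(self) -> bool:
        return not self.aneuploid


def compute_baf(table: VariantTable, strain: str, min_depth: int = MIN_BAND_DEPTH) -> BafProfile:
    """B-allele frequency profile of ``strain`` at biallelic sites.

    Sites are retained when AD-based depth >= max(min_depth, 10) and the
    BAF lies inside the heterozygous-candidate band [0.10, 0.90].
    """
    s = table.strain_index(strain)
    if np.all(table.ad_ref[:, s] < 0):
        raise ValueError(f"strain {strain}: AD field absent")
    min_depth = max(int(min_depth), MIN_BAND_DEPTH)
    biallelic = np.array([len(a) == 1 for a in table.alts])
    ref_d = table.ad_ref[:, s].astype(float)
    alt_d = table.ad_alt[:, s, 0].astype(float)
    ok = biallelic & (ref_d >= 0) & (alt_d >= 0)
    depth = np.where(ok, ref_d + alt_d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, alt_d / np.maximum(depth, 1), np.nan)
    keep = ok & (depth >= min_depth) & (baf >= BAF_BAND[0]) & (baf <= BAF_BAND[1])
    if not keep.any():
        raise UnclassifiableStrainError(f"strain {strain}: no heterozygous-candidate sites survive filtering")
    # table sites are already sorted by (chrom, pos); boolean selection keeps order
    return BafProfile(
        strain=strain,
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        baf=baf[keep],
        depth=depth[keep].astype(np.int64),
    )


def estimate_overdispersion(profile: BafProfile) -> float:
    """Method-of-moments beta-binomial overdispersion rho.

    Pools the squared BAF deviation from the nearer heterozygous mode
    (1/3, 1/2 or 2/3) and inverts Var(BAF) = m(1-m)(1+(n-1)rho)/n.
    """
    m = _HET_MODES[np.argmin(np.abs(profile.baf[:, None] - _HET_MODES[None, :]), axis=1)]
    n = profile.depth.astype(float)
    resid2 = (profile.baf - m) ** 2
    num = resid2.sum() - (m * (1 - m) / n).sum()
    den = (m * (1 - m) * (n - 1) / n).sum()
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 0.45))


def _log_pmf(k: np.ndarray, n: np.ndarray, mu: float, rho: float) -> np.ndarray:
    if rho <= 0:
        return stats.binom.logpmf(k, n, mu)
    conc = 1.0 / rho - 1.0
    return stats.betabinom.logpmf(k, n, mu * conc, (1 - mu) * conc)


def model_loglikelihoods(profile: BafProfile, rho: float) -> tuple[float, float]:
    """(diploid, triploid) summed log-likelihoods of the alt read counts."""
    k = np.round(profile.baf * profile.depth).astype(np.int64)
    n = profile.depth
    ll_d = _log_pmf(k, n, 0.5, rho).sum()
    l13 = _log_pmf(k, n, 1 / 3, rho)
    l23 = _log_pmf(k, n, 2 / 3, rho)
    ll_t = (np.logaddexp(l13, l23) - np.log(2.0)).sum()
    return float(ll_d), float(ll_t)


def classify_ploidy(
    profile: BafProfile,
    rho: float | None = None,
    min_sites: int = 200,
    loglik_gap_floor: float = 2.0,
) -> PloidyCall:
    """Classify a strain as diploid or triploid from its BAF profile.

    ``rho`` is the shared beta-binomial overdispersion; when omitted it is
    estimated by method of moments from the profile itself.  Strains whose
    two model log-likelihoods differ by less than ``loglik_gap_floor`` are
    flagged low-confidence.
    """
    if profile.n_sites < min_sites:
        raise UnclassifiableStrainError(
            f"strain {profile.strain}: {profile.n_sites} sites < floor {min_sites}"
        )
    if rho is None:
        rho = estimate_overdispersion(profile)
    if not (0 <= rho < 0.5):
        raise ValueError(f"overdispersion rho must lie in [0, 0.5), got {rho}")
    ll_d, ll_t = model_loglikelihoods(profile, rho)
    if not (np.isfinite(ll_d) and np.isfinite(ll_t)):
        raise FloatingPointError(f"strain {profile.strain}: non-finite model likelihood")
    ploidy = 2 if ll_d >= ll_t else 3
    return PloidyCall(
        strain=profile.strain,
        ploidy=ploidy,
        loglik_diploid=ll_d,
        loglik_triploid=ll_t,
        n_sites=profile.n_sites,
        rho=float(rho),
        low_confidence=bool(abs(ll_d - ll_t) < loglik_gap_floor),
    )


def call_chromosome_copies(
    table: VariantTable,
    strain: str,
    call: PloidyCall,
    windows: GenomeWindows,
    deviation_threshold: float = 0.2,
    direction_consensus: float = 0.8,
    min_windows: int = 3,
) -> PloidyCall:
    """Fill per-chromosome copy numbers of an existing genome-ploidy call.

    Per chromosome, the depth ratio is the median of per-window mean DP on
    that chromosome over the genome-wide median of per-window means.  The
    copy number is round(ratio x ploidy), but a chromosome is only allowed
    to deviate from the genome ploidy when |ratio x ploidy - ploidy|
    exceeds ``deviation_threshold`` AND more than ``direction_consensus``
    of its windows deviate in the same direction; otherwise it inherits
    the genome ploidy.  Chromosomes with fewer than ``min_windows`` data
    windows inherit the genome ploidy with a warning.
    """
    s = table.strain_index(strain)
    dp = table.dp[:, s].astype(float)
    valid = dp >= 0
    if not valid.any():
        raise ValueError(f"strain {strain}: DP field absent")
    widx = windows.assign(table.chrom[valid], table.pos[valid])
    sums = np.bincount(widx, weights=dp[valid], minlength=windows.n_windows)
    counts = np.bincount(widx, minlength=windows.n_windows)
    has_data = counts > 0
    wmean = np.full(windows.n_windows, np.nan)
    wmean[has_data] = sums[has_data] / counts[has_data]
    genome_median = float(np.median(wmean[has_data]))
    if genome_median <= 0:
        raise ValueError(f"strain {strain}: nonpositive genome-wide median depth")

    wchrom = windows.windows["chrom"].to_numpy()
    ploidy = call.ploidy
    copies: dict[str, int] = {}
    ratios: dict[str, float] = {}
    for chrom in table.contigs:
        mask = (wchrom == chrom) & has_data
        n_w = int(mask.sum())
        if n_w < min_windows:
            logger.warning("strain %s chromosome %s: %d windows of data, inheriting genome ploidy", strain, chrom, n_w)
            copies[chrom] = ploidy
            ratios[chrom] = np.nan
            continue
        ratio = float(np.median(wmean[mask]) / genome_median)
        ratios[chrom] = ratio
        dev = ratio * ploidy - ploidy
        if abs(dev) > deviation_threshold:
            signs = np.sign(wmean[mask] / genome_median * ploidy - ploidy)
            consensus = np.mean(signs == np.sign(dev))
            if consensus > direction_consensus:
                copies[chrom] = max(1, int(round(ratio * ploidy)))
                continue
        copies[chrom] = ploidy
    call.chrom_copies = copies
    call.depth_ratio = ratios
    return call


def call_strain(
    table: VariantTable,
    strain: str,
    windows: GenomeWindows,
    min_depth: int = MIN_BAND_DEPTH,
    rho: float | None = None,
    min_sites: int = 200,
) -> PloidyCall:
    """Convenience wrapper: BAF profile -> genome ploidy -> chromosome copies."""
    profile = compute_baf(table, strain, min_depth=min_depth)
    call = classify_ploidy(profile, rho=rho, min_sites=min_sites)
    return call_chromosome_copies(table, strain, call, windows)
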