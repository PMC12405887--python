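"""Multi-sample VCF input/output and the shared site/window data model.

The in-memory :class:`VariantTable` keeps, for every retained site and
strain, the genotype as allele-copy counts (supporting mixed diploid and
triploid calls), the per-allele read depths (AD) and the total depth (DP).
All coordinates are VCF-style: 1-based, inclusive.  Multiallelic records
are read intact and removed downstream by the biallelic filter, never
split.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: slot value for a missing allele ('.') inside a genotype call
MISSING_ALLELE = -1
#: slot value used to pad genotypes shorter than the widest call in the table
PAD = -9


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantTable:
    """Per-site, per-strain genotypes and allele depths.

    Attributes
    ----------
    contigs:
        Ordered mapping contig name -> length in bp.
    chrom, pos, ref:
        Arrays of length ``n_sites``; ``pos`` is 1-based and strictly
        increasing within each contig.
    alts:
        Per-site tuple of alternate alleles (one entry for biallelic sites).
    gt:
        ``(n_sites, n_strains, max_ploidy)`` int8 array of allele indices;
        ``MISSING_ALLELE`` marks a '.' allele, ``PAD`` pads calls whose
        ploidy is below ``max_ploidy``.
    ad_ref, dp:
        ``(n_sites, n_strains)`` int32 arrays; ``-1`` where absent.
    ad_alt:
        ``(n_sites, n_strains, max_alts)`` int32 array; ``-1`` where absent.
    strains:
        Sample identifiers, column order of all per-strain arrays.
    """

    contigs: dict[str, int]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: list[tuple[str, ...]]
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    strains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {name}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_alleles(self) -> np.ndarray:
        """Number of declared alleles (ref + alts) per site."""
        return np.array([1 + len(a) for a in self.alts])

    def call_ploidy(self) -> np.ndarray:
        """(n_sites, n_strains) number of allele slots in each call (0 if fully missing)."""
        called = self.gt != PAD
        return called.sum(axis=2)

    def alt_copy_counts(self) -> np.ndarray:
        """(n_sites, n_strains) copies of the first alternate allele; -1 if the call has any missing allele."""
        out = (self.gt == 1).sum(axis=2).astype(np.int16)
        missing = (self.gt == MISSING_ALLELE).any(axis=2) | (self.gt != PAD).sum(axis=2).astype(bool).__invert__()
        out[missing] = -1
        return out

    def dosage_matrix(self) -> np.ndarray:
        """Diploidized dosage in {0,1,2}, -1 for missing calls.

        Allele-copy genotypes are projected onto hom-ref / het / hom-alt:
        a call is 0 when all copies are reference, 2 when all copies are
        the first alternate, and 1 otherwise.  Intended for biallelic
        tables (SNPRelate-style dosage); a lossy projection for triploids.
        """
        ploidy = self.call_ploidy()
        alt = self.alt_copy_counts()
        out = np.full(alt.shape, -1, dtype=np.int8)
        ok = (alt >= 0) & (ploidy > 0)
        out[ok & (alt == 0)] = 0
        out[ok & (alt == ploidy)] = 2
        out[ok & (alt > 0) & (alt < ploidy)] = 1
        return out

    def take_sites(self, idx: np.ndarray) -> "VariantTable":
        """New table restricted to site indices ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return VariantTable(
            contigs=dict(self.contigs),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alts=[self.alts[i] for i in idx],
            gt=self.gt[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            dp=self.dp[idx],
            strains=list(self.strains),
        )

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.contigs == other.contigs
            and self.strains == other.strains
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and self.alts == other.alts
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
            and np.array_equal(self.dp, other.dp)
        )


@dataclass
class GenomeWindows:
    """Non-overlapping tiling of each contig into fixed-size windows.

    ``windows`` has columns ``chrom``, ``start``, ``end`` (1-based,
    inclusive) and ``index`` (0-based within the chromosome).  The last
    window of a contig may be short.
    """

    size: int
    windows: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Global window row index for each (chrom, pos); position p maps to
        within-chromosome index floor((p-1)/W)."""
        offsets = {}
        off = 0
        for name, grp in self.windows.groupby("chrom", sort=False):
            offsets[name] = off
            off += len(grp)
        local = (np.asarray(pos) - 1) // self.size
        return np.array([offsets[c] for c in chrom]) + local


def make_windows(contigs: dict[str, int], size: int = 50_000) -> GenomeWindows:
    """Tile every contig with windows of ``size`` bp (default 50 kb)."""
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    rows = []
    for name, length in contigs.items():
        if length <= 0:
            raise ValueError(f"contig {name} has nonpositive length {length}")
        n = int(np.ceil(length / size))
        for i in range(n):
            rows.append((name, i * size + 1, min((i + 1) * size, length), i))
    return GenomeWindows(size=size, windows=pd.DataFrame(rows, columns=["chrom", "start", "end", "index"]))


def _format_gt(alleles: np.ndarray) -> str:
    slots = [a for a in alleles if a != PAD]
    return "/".join("." if a == MISSING_ALLELE else str(int(a)) for a in slots)


def write_vcf(table: VariantTable, path: str) -> None:
    """Write the table as a plain-text multi-sample VCF 4.2 (GT:AD:DP)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in table.contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.strains) + "\n")
        for i in range(table.n_sites):
            alt_field = ",".join(table.alts[i]) if table.alts[i] else "."
            n_alt = len(table.alts[i])
            cols = [
                str(table.chrom[i]),
                str(int(table.pos[i])),
                ".",
                str(table.ref[i]),
                alt_field,
                ".",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            for s in range(table.n_strains):
                gt = _format_gt(table.gt[i, s])
                ads = [table.ad_ref[i, s]] + [table.ad_alt[i, s, k] for k in range(n_alt)]
                ad = ",".join("." if a < 0 else str(int(a)) for a in ads)
                dp = "." if table.dp[i, s] < 0 else str(int(table.dp[i, s]))
                cols.append(f"{gt}:{ad}:{dp}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str, min_quality: float = 0.0, min_depth: int = 0) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Records are dropped when they fail FILTER (anything other than PASS or
    '.'), have QUAL below ``min_quality`` (records without QUAL pass), or
    have DP below ``min_depth`` in every strain.  GT is required; AD/DP are
    optional at read time but required by the ploidy stage.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (FileNotFoundError, OSError) as exc:
        raise FileNotFoundError(f"cannot open VCF {path}: {exc}") from exc

    if "GT" not in vcf.header.formats:
        raise VcfFormatError(f"{path}: no GT FORMAT declared in header")

    strains = list(vcf.header.samples)
    contigs = {c: vcf.header.contigs[c].length or 0 for c in vcf.header.contigs}

    chroms, poss, refs, alts_all = [], [], [], []
    gts, adrs, adas, dps = [], [], [], []
    n_read = n_kept = 0
    max_pl = 1
    max_alt = 1
    for rec in vcf:
        n_read += 1
        if rec.filter.keys() and "PASS" not in rec.filter.keys():
            continue
        if rec.qual is not None and rec.qual < min_quality:
            continue
        site_alts = tuple(rec.alts) if rec.alts else ()
        row_gt, row_adr, row_ada, row_dp = [], [], [], []
        for s in strains:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                gt = ()
            alleles = [MISSING_ALLELE if a is None else int(a) for a in gt]
            for a in alleles:
                if a > len(site_alts):
                    raise VcfFormatError(
                        f"{rec.chrom}:{rec.pos}: allele index {a} out of range for {1 + len(site_alts)} alleles"
                    )
            max_pl = max(max_pl, len(alleles))
            ad = call.get("AD")
            if ad is None or all(a is None for a in np.atleast_1d(ad)):
                adr, ada = -1, [-1] * max(1, len(site_alts))
            else:
                ad = [(-1 if a is None else int(a)) for a in np.atleast_1d(ad)]
                adr = ad[0]
                ada = ad[1 : 1 + max(1, len(site_alts))]
                ada += [-1] * (max(1, len(site_alts)) - len(ada))
            dp = call.get("DP")
            dp = -1 if dp is None else int(dp)
            if dp >= 0 and adr >= 0 and adr + sum(a for a in ada if a > 0) > dp:
                raise VcfFormatError(f"{rec.chrom}:{rec.pos} sample {s}: sum(AD) exceeds DP")
            row_gt.append(alleles)
            row_adr.append(adr)
            row_ada.append(ada)
            row_dp.append(dp)
        max_alt = max(max_alt, max(1, len(site_alts)))
        if min_depth > 0:
            if not any(d >= min_depth for d in row_dp):
                continue
        n_kept += 1
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts_all.append(site_alts)
        gts.append(row_gt)
        adrs.append(row_adr)
        adas.append(row_ada)
        dps.append(row_dp)
    vcf.close()
    logger.info("read_vcf: %d records read, %d kept", n_read, n_kept)

    n = len(poss)
    gt_arr = np.full((n, len(strains), max_pl), PAD, dtype=np.int8)
    ada_arr = np.full((n, len(strains), max_alt), -1, dtype=np.int32)
    for i in range(n):
        for s in range(len(strains)):
            al = gts[i][s]
            gt_arr[i, s, : len(al)] = al
            aa = adas[i][s]
            ada_arr[i, s, : len(aa)] = aa
    return VariantTable(
        contigs=contigs,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alts=alts_all,
        gt=gt_arr,
        ad_ref=np.array(adrs, dtype=np.int32),
        ad_alt=ada_arr,
        dp=np.array(dps, dtype=np.int32),
        strains=strains,
    )
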