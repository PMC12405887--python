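"""Synthetic strain panels with known ground truth.

Three generators emulate the data a small wild-yeast resequencing and
phenomics study produces: multi-sample genotypes with binomial allele
depths (diploid and triploid strains over six chromosomes, optional
aneuploid chromosomes), logistic OD610 growth curves under a panel of
conditions with lineage-specific effects, and replicated morphology
tables with a ploidy effect on cell-size traits.

The genotype model is a stylized shared-ancestor allele model.  Every
site belongs to one category: ancestral heterozygous (all strains het,
the background heterozygosity that drives allele-balance ploidy
inference), ancestral homozygous-alt, lineage-differentiating (one
lineage carries a derived het or hom-alt state; site count proportional
to that lineage's divergence scaler), or strain-private het.  Site
density is calibrated analytically so that the nucleotide diversity of
the generated panel matches ``target_pi`` in expectation under the same
estimator the analysis stage uses.

All randomness flows from a single integer seed through named
substreams, so each generator can be re-run independently and
reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import PAD, VariantTable

# substream tags (kept stable; changing them changes every simulated panel)
_STREAM_EFFECTS = 0
_STREAM_GENO = 1
_STREAM_GROWTH = 2
_STREAM_MORPH = 3

#: full-scale chromosome lengths (bp) for a six-chromosome, 13.12 Mb genome
DEFAULT_CHROM_LENGTHS = (3_950_000, 2_600_000, 2_250_000, 1_850_000, 1_270_000, 1_200_000)
CHROM_NAMES = ("chrI", "chrII", "chrIII", "chrIV", "chrV", "chrVI")

DEFAULT_CONDITIONS: dict[str, str] = {
    "YPD": "reference",
    "Glycerol": "carbon", "Acetate": "carbon", "Xylose": "carbon", "EtOH_carbon": "carbon",
    "Galactose": "carbon", "Maltose": "carbon", "Sucrose": "carbon", "Raffinose": "carbon",
    "pH3": "environment", "pH8": "environment", "NaCl_1M": "environment", "KCl_1M": "environment",
    "Sorbitol_1M": "environment", "37C": "environment", "15C": "environment", "Ethanol_6pct": "environment",
    "CuSO4": "toxin", "CdCl2": "toxin", "6-azauracil": "toxin", "Methyl-Viologen": "toxin",
    "Caffeine": "toxin", "SDS": "toxin", "H2O2": "toxin",
}

#: 31 morphology traits; the leading size-class traits carry the ploidy effect
SIZE_TRAITS = (
    "WholeCellSize", "MotherCellSize", "BudSize", "CellOutlineLength", "NucleusSize", "ActinRegionSize",
)
SHAPE_TRAITS = tuple(
    f"{name}" for name in (
        "CellAxisRatio", "MotherAxisRatio", "BudAxisRatio", "CellRoundness", "MotherRoundness",
        "BudRoundness", "NeckWidth", "BudNeckPositionAngle", "BudTipMotherAxisDistance",
        "NoBudRatio", "SmallBudRatio", "LargeBudRatio", "NucleusPositionRatio", "NucleusAxisRatio",
        "NucleusMotherDistance", "ActinPatchNumber", "ActinPolarityIndex", "CellWallThicknessProxy",
        "VacuoleAreaRatio", "MitoRegionRatio", "SeptinRingIntensity", "CellElongationIndex",
        "MotherBudAngle", "BudGrowthDirection", "NeckPositionRatio",
    )
)
DEFAULT_TRAITS = SIZE_TRAITS + SHAPE_TRAITS
assert len(DEFAULT_TRAITS) == 31


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class LineageSpec:
    """One lineage: a label, how many strains it contains and how far it
    has diverged from the panel ancestor (dimensionless scaler; 0 means
    no lineage-specific or strain-private variation)."""

    label: str
    n_strains: int
    divergence: float = 1.0


@dataclass
class GrowthSpec:
    """Logistic growth-curve parameters.

    ``base_rate`` is the specific growth rate (1/h) in the reference
    condition; per-condition multipliers scale it.  ``lineage_effect_sd``
    is the SD of the per-(lineage, condition) log-effect, multiplied by
    the lineage divergence scaler, so diverged lineages have more
    distinctive fitness profiles.
    """

    base_rate: float = 0.40
    condition_multipliers: dict[str, float] | None = None
    lineage_effect_sd: float = 0.25
    strain_effect_sd: float = 0.05
    interaction_sd: float = 0.08
    noise_sd: float = 0.005
    od0: float = 0.05
    carrying_capacity: float = 1.8
    n_replicates: int = 3
    t_max_h: float = 48.0
    dt_h: float = 1.0 / 3.0
    conditions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))


@dataclass
class MorphSpec:
    """Morphology-replicate parameters (arbitrary trait units).

    ``ploidy_effect`` is added to every size-class trait of triploid
    strains; ``strain_sd`` is the between-strain SD of trait means and
    ``replicate_sd`` the within-strain replicate SD.
    """

    traits: tuple[str, ...] = DEFAULT_TRAITS
    size_traits: tuple[str, ...] = SIZE_TRAITS
    ploidy_effect: float = 0.8
    strain_sd: float = 0.12
    replicate_sd: float = 0.10
    n_replicates: int = 5


def _default_lineages() -> list[LineageSpec]:
    # three clades; the small third clade is the most diverged (mimicking a
    # panel whose minority clade shows distinct fitness and homozygosity)
    return [LineageSpec("I", 8, 1.0), LineageSpec("II", 9, 1.0), LineageSpec("III", 3, 2.0)]


def _default_ploidy(lineages: list[LineageSpec]) -> list[int]:
    # 9 diploids / 11 triploids over 20 strains; the minority clade is all diploid
    if [lg.n_strains for lg in lineages] == [8, 9, 3]:
        return [2, 2, 2, 3, 3, 3, 3, 3] + [2, 2, 2, 3, 3, 3, 3, 3, 3] + [2, 2, 2]
    out = []
    for i, lg in enumerate(lineages):
        for j in range(lg.n_strains):
            out.append(2 if (i + j) % 2 == 0 else 3)
    return out


@dataclass
class SimulationConfig:
    """Complete description of one synthetic panel.

    Defaults mimic the study scale this package targets: 20 strains in
    three lineages, six chromosomes totalling 13.12 Mb scaled down by
    ``genome_scale`` (default 1/100) for fast in-memory work, a diploid/
    triploid mix with four aneuploid triploids, target per-site diversity
    0.018, and 60x mean coverage.
    """

    n_strains: int = 20
    lineages: list[LineageSpec] = field(default_factory=_default_lineages)
    ploidy_assignment: list[int] | None = None
    aneuploid_events: list[tuple[str, str, int]] | None = None
    chrom_lengths: tuple[int, ...] = DEFAULT_CHROM_LENGTHS
    chrom_names: tuple[str, ...] = CHROM_NAMES
    genome_scale: float = 0.01
    target_pi: float = 0.018
    depth_mean: float = 60.0
    depth_dispersion: float = 0.15
    seq_error: float = 0.002
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    morph: MorphSpec = field(default_factory=MorphSpec)
    seed: int = 0
    # genotype-category weights (unnormalized); lineage and private weights
    # are additionally multiplied by the divergence scalers
    w_ancestral_het: float = 0.45
    w_ancestral_hom: float = 0.10
    w_lineage: float = 0.15
    w_private: float = 0.01
    p_lineage_hom: float = 0.40

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must be non-empty")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigurationError("chrom_lengths must all be positive")
        if not (0 < self.target_pi < 0.1):
            raise ConfigurationError(f"target_pi must lie in (0, 0.1), got {self.target_pi}")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        if self.depth_dispersion < 0:
            raise ConfigurationError("depth_dispersion must be nonnegative")
        if not (0 <= self.seq_error < 0.5):
            raise ConfigurationError("seq_error must lie in [0, 0.5)")
        if sum(lg.n_strains for lg in self.lineages) != self.n_strains:
            raise ConfigurationError("lineage strain counts must sum to n_strains")
        if any(lg.divergence < 0 for lg in self.lineages):
            raise ConfigurationError("divergence scalers must be nonnegative")
        if self.ploidy_assignment is None:
            self.ploidy_assignment = _default_ploidy(self.lineages)
        if len(self.ploidy_assignment) != self.n_strains:
            raise ConfigurationError("ploidy_assignment length must equal n_strains")
        if any(p not in (2, 3) for p in self.ploidy_assignment):
            raise ConfigurationError("ploidy values must be 2 or 3")
        if self.growth.noise_sd < 0:
            raise ConfigurationError("growth noise sd must be nonnegative")
        if self.morph.replicate_sd <= 0:
            raise ConfigurationError("morphology replicate sd must be positive")
        if self.aneuploid_events is None:
            self.aneuploid_events = self._default_aneuploidies()
        ids = set(self.strain_ids)
        for strain, chrom, copy in self.aneuploid_events:
            if strain not in ids:
                raise ConfigurationError(f"aneuploid event names unknown strain {strain!r}")
            if chrom not in self.chrom_names:
                raise ConfigurationError(f"aneuploid event names unknown chromosome {chrom!r}")
            if not (1 <= copy <= 4):
                raise ConfigurationError(f"chromosome copy number {copy} outside supported range 1..4")

    # -- derived layout -------------------------------------------------
    @property
    def strain_ids(self) -> list[str]:
        return [f"CJ{i + 1:03d}" for i in range(self.n_strains)]

    @property
    def lineage_of(self) -> list[str]:
        out = []
        for lg in self.lineages:
            out.extend([lg.label] * lg.n_strains)
        return out

    @property
    def scaled_chrom_lengths(self) -> dict[str, int]:
        return {
            name: max(1, int(round(length * self.genome_scale)))
            for name, length in zip(self.chrom_names, self.chrom_lengths)
        }

    def _default_aneuploidies(self) -> list[tuple[str, str, int]]:
        """Four aneuploid triploids (three chromosome gains, one loss);
        diploids stay euploid, mirroring panels where aneuploidy
        concentrates in triploid strains."""
        ids = self.strain_ids
        tri = [s for s, p in zip(ids, self.ploidy_assignment) if p == 3]
        events: list[tuple[str, str, int]] = []
        chroms = self.chrom_names
        for k, strain in enumerate(tri[:4]):
            copy = 2 if k == 3 else 4
            events.append((strain, chroms[(2 * k + 1) % len(chroms)], copy))
        return events

    def copy_numbers(self) -> pd.DataFrame:
        """strains x chromosomes integer copy numbers implied by ploidy +
        aneuploid events."""
        df = pd.DataFrame(
            {c: self.ploidy_assignment for c in self.chrom_names},
            index=pd.Index(self.strain_ids, name="strain"),
        )
        for strain, chrom, copy in self.aneuploid_events:
            df.loc[strain, chrom] = copy
        return df

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PopulationTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    strain_ids: list[str]
    lineage: dict[str, str]
    ploidy: dict[str, int]
    chrom_copies: pd.DataFrame  # strains x chromosomes
    growth_rates: pd.DataFrame  # strains x conditions true mu (1/h)
    morph_means: pd.DataFrame  # strains x traits true means

    @property
    def aneuploid(self) -> dict[str, bool]:
        return {
            s: bool((self.chrom_copies.loc[s] != self.ploidy[s]).any())
            for s in self.strain_ids
        }

    def to_json(self, path: str) -> None:
        payload = {
            "strains": self.strain_ids,
            "lineage": self.lineage,
            "ploidy": self.ploidy,
            "aneuploid": self.aneuploid,
            "chrom_copies": {s: self.chrom_copies.loc[s].to_dict() for s in self.strain_ids},
            "growth_rates": {s: self.growth_rates.loc[s].to_dict() for s in self.strain_ids},
            "morph_means": {s: self.morph_means.loc[s].to_dict() for s in self.strain_ids},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _lineage_sizes(config: SimulationConfig) -> dict[str, int]:
    return {lg.label: lg.n_strains for lg in config.lineages}


def _true_growth_rates(config: SimulationConfig) -> pd.DataFrame:
    g = config.growth
    rng = config.rng(_STREAM_EFFECTS)
    conds = list(g.conditions)
    # default per-category multipliers: rich reference medium fastest,
    # alternative carbon sources and toxins progressively slower
    cat_mult = {"reference": 1.0, "carbon": 0.75, "environment": 0.85, "toxin": 0.65}
    mult = g.condition_multipliers or {}
    base = np.array(
        [g.base_rate * mult.get(c, cat_mult.get(g.conditions[c], 0.85)) for c in conds]
    )
    # lineage log-effects are clipped at +/-0.45 (x0.64..x1.57): the realistic
    # span of condition-specific fitness ratios between yeast lineages
    lin_eff = {
        lg.label: np.exp(
            np.clip(lg.divergence * rng.normal(0.0, g.lineage_effect_sd, size=len(conds)), -0.45, 0.45)
        )
        for lg in config.lineages
    }
    # YPD is the normalization reference; lineage effects there stay neutral
    ypd = conds.index("YPD") if "YPD" in conds else None
    rows = []
    for strain, lab in zip(config.strain_ids, config.lineage_of):
        strain_eff = np.exp(rng.normal(0.0, g.strain_effect_sd))
        # strain x condition interactions: condition-specific deviations of
        # each strain from its lineage profile, as real panels show; the
        # reference condition stays interaction-free (a YPD-specific
        # deviation would inject a rank-one common mode into every
        # normalized ratio)
        interaction = np.exp(rng.normal(0.0, g.interaction_sd, size=len(conds)))
        mu = base * lin_eff[lab] * strain_eff * interaction
        if ypd is not None:
            mu[ypd] = base[ypd] * strain_eff
        rows.append(mu)
    return pd.DataFrame(rows, index=pd.Index(config.strain_ids, name="strain"), columns=conds)


def _true_morph_means(config: SimulationConfig) -> pd.DataFrame:
    m = config.morph
    rng = config.rng(_STREAM_EFFECTS)
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from growth draws
    baselines = 1.0 + 0.2 * np.arange(len(m.traits)) % 5  # heterogeneous but fixed scales
    rows = []
    for strain, ploidy in zip(config.strain_ids, config.ploidy_assignment):
        dev = rng.normal(0.0, m.strain_sd, size=len(m.traits))
        means = baselines + dev
        if ploidy == 3 and m.ploidy_effect:
            for k, t in enumerate(m.traits):
                if t in m.size_traits:
                    means[k] += m.ploidy_effect
        rows.append(means)
    return pd.DataFrame(rows, index=pd.Index(config.strain_ids, name="strain"), columns=list(m.traits))


def population_truth(config: SimulationConfig) -> PopulationTruth:
    """Ground truth implied by a configuration (pure function of the config,
    including its seed)."""
    return PopulationTruth(
        strain_ids=config.strain_ids,
        lineage=dict(zip(config.strain_ids, config.lineage_of)),
        ploidy=dict(zip(config.strain_ids, config.ploidy_assignment)),
        chrom_copies=config.copy_numbers(),
        growth_rates=_true_growth_rates(config),
        morph_means=_true_morph_means(config),
    )


# ---------------------------------------------------------------------------
# genotypes


def _site_category_weights(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Categories: 'anc_het', 'anc_hom', 'lin:<label>', 'priv:<strain>'."""
    cats = ["anc_het", "anc_hom"]
    w = [config.w_ancestral_het, config.w_ancestral_hom]
    for lg in config.lineages:
        cats.append(f"lin:{lg.label}")
        w.append(config.w_lineage * lg.divergence)
    for strain, lab in zip(config.strain_ids, config.lineage_of):
        div = next(lg.divergence for lg in config.lineages if lg.label == lab)
        cats.append(f"priv:{strain}")
        w.append(config.w_private * div)
    return cats, np.asarray(w, dtype=float)


def _expected_pi_per_site(config: SimulationConfig) -> float:
    """Expected per-site diversity contribution of one generated site under
    the diploidized-projection estimator, restricted to biallelic
    segregating configurations (the same convention the analysis uses)."""
    n = config.n_strains
    sizes = _lineage_sizes(config)
    cats, w = _site_category_weights(config)
    probs = w / w.sum() if w.sum() > 0 else w

    def contrib(p_hat: float) -> float:
        nj = 2 * n
        return nj / (nj - 1) * 2.0 * p_hat * (1.0 - p_hat)

    total = 0.0
    for cat, p in zip(cats, probs):
        if p == 0 or cat in ("anc_het", "anc_hom"):
            continue  # single genotype state across the panel: filtered out
        if cat.startswith("lin:"):
            k = sizes[cat.split(":", 1)[1]]
            c_het = contrib(k / (2 * n))
            c_hom = contrib(k / n) if k < n else 0.0
            total += p * ((1 - config.p_lineage_hom) * c_het + config.p_lineage_hom * c_hom)
        else:  # strain-private het
            total += p * contrib(1 / (2 * n))
    return total


def simulate_genotypes(config: SimulationConfig) -> tuple[VariantTable, PopulationTruth]:
    """Generate the genotype/allele-depth table and its ground truth.

    Sites are placed uniformly per chromosome with counts proportional to
    chromosome length; the total count is calibrated analytically so the
    expected nucleotide diversity of the panel equals ``target_pi``.
    Total depth at each call follows a gamma-mixed Poisson with mean
    ``depth_mean`` scaled by (chromosome copy number / genome ploidy);
    alternate read counts are binomial around the allelic fraction of the
    genotype, perturbed by the per-read error rate.
    """
    rng = config.rng(_STREAM_GENO)
    lengths = config.scaled_chrom_lengths
    L = sum(lengths.values())
    e_site = _expected_pi_per_site(config)
    if e_site > 0:
        m = max(1, int(round(config.target_pi * L / e_site)))
    else:
        m = max(1, int(round(0.01 * L)))  # degenerate (no divergence): density fallback
    m = min(m, L)  # cannot place more sites than bases

    cats, w = _site_category_weights(config)
    probs = w / w.sum()
    n = config.n_strains
    copies = config.copy_numbers()
    copy_mat = copies.to_numpy()  # strains x chroms
    ploidy = np.asarray(config.ploidy_assignment)
    lineage_of = np.asarray(config.lineage_of, dtype=object)
    chrom_index = {c: k for k, c in enumerate(config.chrom_names)}

    # site placement
    chroms_arr, pos_arr = [], []
    counts = np.maximum(1, np.round(m * np.array([lengths[c] for c in config.chrom_names]) / L).astype(int))
    for cname, cnt in zip(config.chrom_names, counts):
        cnt = min(cnt, lengths[cname])
        pos = np.sort(rng.choice(lengths[cname], size=cnt, replace=False) + 1)
        chroms_arr.append(np.full(cnt, cname, dtype=object))
        pos_arr.append(pos)
    chrom = np.concatenate(chroms_arr)
    pos = np.concatenate(pos_arr)
    m = len(pos)

    cat_idx = rng.choice(len(cats), size=m, p=probs)
    lin_hom = rng.random(m) < config.p_lineage_hom
    het_pick = rng.random((m, n))  # picks among het dosage options

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=m)]
    alts = []
    for i in range(m):
        choices = [b for b in bases if b != ref[i]]
        alts.append((choices[int(rng.integers(0, 3))],))

    site_copy = copy_mat[:, np.array([chrom_index[c] for c in chrom])].T  # m x n

    # allelic fraction class per site/strain: 0 = hom-ref, 1 = het, 2 = hom-alt
    state = np.zeros((m, n), dtype=np.int8)
    for i, ci in enumerate(cat_idx):
        cat = cats[ci]
        if cat == "anc_het":
            state[i, :] = 1
        elif cat == "anc_hom":
            state[i, :] = 2
        elif cat.startswith("lin:"):
            members = lineage_of == cat.split(":", 1)[1]
            state[i, members] = 2 if lin_hom[i] else 1
        else:
            s_idx = config.strain_ids.index(cat.split(":", 1)[1])
            state[i, s_idx] = 1

    # dosage (alt allele copies out of the local copy number)
    dosage = np.zeros((m, n), dtype=np.int16)
    dosage[state == 2] = site_copy[state == 2]
    het = state == 1
    c_het = site_copy[het]
    # het dosage drawn uniformly among 1..copy-1 (1/2 for disomic calls,
    # 1/3 vs 2/3 for trisomic, and so on)
    opts = np.maximum(c_het - 1, 1)
    dosage[het] = 1 + np.floor(het_pick[het] * opts).astype(np.int16)
    dosage[het] = np.minimum(dosage[het], np.maximum(c_het - 1, 1))

    # depths
    mean_dp = config.depth_mean * site_copy / ploidy[None, :]
    if config.depth_dispersion > 0:
        shape = 1.0 / config.depth_dispersion
        lam = rng.gamma(shape, mean_dp / shape)
    else:
        lam = mean_dp
    dp = rng.poisson(lam).astype(np.int32)
    frac = dosage / site_copy
    p_alt = frac * (1 - config.seq_error) + (1 - frac) * config.seq_error
    alt_reads = rng.binomial(dp, p_alt).astype(np.int32)
    ref_reads = dp - alt_reads

    # genotype slots
    max_pl = int(site_copy.max())
    gt = np.full((m, n, max_pl), PAD, dtype=np.int8)
    for i in range(m):
        for s in range(n):
            c = int(site_copy[i, s])
            a = int(dosage[i, s])
            gt[i, s, :c] = [0] * (c - a) + [1] * a

    table = VariantTable(
        contigs=dict(lengths),
        chrom=chrom,
        pos=pos.astype(np.int64),
        ref=ref,
        alts=alts,
        gt=gt,
        ad_ref=ref_reads,
        ad_alt=alt_reads[:, :, None],
        dp=dp,
        strains=config.strain_ids,
    )
    return table, population_truth(config)


# ---------------------------------------------------------------------------
# growth curves


def logistic_od(t: np.ndarray, mu: float, od0: float, K: float) -> np.ndarray:
    """Logistic growth curve OD(t) = K / (1 + ((K-OD0)/OD0) exp(-mu t))."""
    return K / (1.0 + (K - od0) / od0 * np.exp(-mu * np.asarray(t)))


def simulate_growth(config: SimulationConfig) -> tuple[pd.DataFrame, PopulationTruth]:
    """Generate OD610 trajectories for every strain x condition x replicate.

    Returns a long-format frame (strain, condition, replicate, time_h, od)
    sampled every 20 min from 0 to 48 h inclusive, plus the ground truth
    with the true specific growth rates.
    """
    g = config.growth
    if g.base_rate <= 0 or g.od0 <= 0 or g.carrying_capacity <= g.od0:
        raise ConfigurationError("growth parameters must satisfy 0 < od0 < K and base_rate > 0")
    if g.noise_sd < 0:
        raise ConfigurationError("growth noise sd must be nonnegative")
    rng = config.rng(_STREAM_GROWTH)
    truth = population_truth(config)
    t = np.arange(0.0, g.t_max_h + g.dt_h / 2, g.dt_h)
    frames = []
    for strain in config.strain_ids:
        for cond in g.conditions:
            mu = truth.growth_rates.loc[strain, cond]
            clean = logistic_od(t, mu, g.od0, g.carrying_capacity)
            for rep in range(1, g.n_replicates + 1):
                od = clean + rng.normal(0.0, g.noise_sd, size=t.size) if g.noise_sd > 0 else clean.copy()
                od = np.maximum(od, 0.0)
                frames.append(
                    pd.DataFrame(
                        {
                            "strain": strain,
                            "condition": cond,
                            "replicate": rep,
                            "time_h": t,
                            "od": od,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# morphology


def simulate_morphology(config: SimulationConfig) -> tuple[pd.DataFrame, PopulationTruth]:
    """Generate the replicated morphology table (strain, trait, replicate,
    value) around the true strain means, with the ploidy effect on
    size-class traits baked into the truth."""
    m = config.morph
    if config.n_strains < 2 or m.n_replicates < 2:
        raise ConfigurationError("need at least 2 strains and 2 replicates")
    if m.replicate_sd <= 0:
        raise ConfigurationError("morphology replicate sd must be positive")
    rng = config.rng(_STREAM_MORPH)
    truth = population_truth(config)
    means = truth.morph_means
    noise = rng.normal(0.0, m.replicate_sd, size=(config.n_strains, len(m.traits), m.n_replicates))
    records = []
    for si, strain in enumerate(config.strain_ids):
        for ti, trait in enumerate(m.traits):
            for rep in range(m.n_replicates):
                records.append((strain, trait, rep + 1, means.iloc[si, ti] + noise[si, ti, rep]))
    return pd.DataFrame(records, columns=["strain", "trait", "replicate", "value"]), truth
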