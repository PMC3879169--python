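"""Seeded simulator of a cattle cohort segregating a recessive lethal deletion.

The generator emulates the statistical structure that the downstream analyses
assume: a multi-generation, multi-breed pedigree of progeny-tested bulls;
phased biallelic SNP haplotypes on one chromosome at 50K- and HD-array
densities; a large deletion whose carriers are hemizygous across the interval
(miscalled homozygous with depressed Log R Ratio by array software);
insemination records with cumulative return-to-oestrus outcomes at 35, 56,
100 and 150 days; and de-regressed trait proofs with reliabilities.

All randomness flows from a single master seed through
``numpy.random.Generator`` spawns, so regenerating with the same config and
seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayDataset",
    "ArrayNoiseConfig",
    "BreedConfig",
    "DeletionConfig",
    "DeletionTruth",
    "InseminationRecords",
    "MarkerMap",
    "Pedigree",
    "PhasedGenotypes",
    "PopulationConfig",
    "ReproConfig",
    "SimulatedCohort",
    "TraitConfig",
    "TraitRecords",
    "emit_array_signals",
    "gene_drop",
    "simulate_inseminations",
    "simulate_population",
    "simulate_trait_proofs",
]

UNKNOWN = 0  # pedigree code for an unknown parent

# Trait catalogue. Fertility component traits enter the fertility index with
# equal weights (the national index composition is not public); milk traits
# carry the antagonistic positive deletion effect.
FERTILITY_INDEX_TRAITS = ("AISC", "AISH", "ICF", "IFLC", "IFLH")
FERTILITY_TRAITS = FERTILITY_INDEX_TRAITS + ("NRRC", "NRRH", "HS")
MILK_TRAITS = ("milk", "fat", "protein")
ALL_TRAITS = ("fertility_index",) + FERTILITY_TRAITS + MILK_TRAITS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Pedigree table; parent id 0 means unknown.

    Invariants: acyclic, sires male, dams female, non-founders have both
    parents present or both unknown.
    """

    table: pd.DataFrame  # animal_id, sire_id, dam_id, sex, breed, generation

    def __post_init__(self) -> None:
        t = self.table
        required = {"animal_id", "sire_id", "dam_id", "sex", "breed", "generation"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValueError("empty pedigree")
        self.validate()

    def validate(self) -> None:
        t = self.table
        ids = set(t["animal_id"])
        sex = dict(zip(t["animal_id"], t["sex"]))
        for col, want in (("sire_id", "M"), ("dam_id", "F")):
            known = t[col][t[col] != UNKNOWN]
            bad = [a for a in known if a in sex and sex[a] != want]
            if bad:
                raise ValueError(f"{col} entries with wrong sex: {bad[:5]}")
        # both parents known-or-absent together is a convention we enforce at
        # generation time; here we only check ids resolve or are unknown.
        for col in ("sire_id", "dam_id"):
            unresolved = set(t[col]) - ids - {UNKNOWN}
            if unresolved:
                raise ValueError(f"{col} references absent animals: {sorted(unresolved)[:5]}")
        # acyclicity: parents must appear before offspring in generation order
        gen = dict(zip(t["animal_id"], t["generation"]))
        for col in ("sire_id", "dam_id"):
            for a, p in zip(t["animal_id"], t[col]):
                if p != UNKNOWN and gen[p] >= gen[a]:
                    raise ValueError(f"parent {p} not older than offspring {a}")

    @property
    def animal_ids(self) -> np.ndarray:
        return self.table["animal_id"].to_numpy()


@dataclass
class MarkerMap:
    """SNP map for one chromosome; 1-based bp positions, strictly increasing."""

    table: pd.DataFrame  # marker_id, chromosome, position, panel, allele_a, allele_b

    def __post_init__(self) -> None:
        t = self.table
        for chrom, sub in t.groupby("chromosome"):
            pos = sub["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def panel(self, name: str) -> "MarkerMap":
        sub = self.table[self.table["panel"] == name].reset_index(drop=True)
        return MarkerMap(sub)

    def in_interval(self, start_bp: int, end_bp: int) -> np.ndarray:
        """Boolean mask of markers inside [start_bp, end_bp] (1-based closed)."""
        pos = self.positions
        return (pos >= start_bp) & (pos <= end_bp)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PhasedGenotypes:
    """Phased haplotypes: alleles coded 0 (A) / 1 (B), shape (n, 2, m).

    Haplotype 0 is paternal, haplotype 1 maternal. ``del_flags`` marks
    haplotypes carrying the deletion allele (shape (n, 2), bool).
    """

    animal_ids: np.ndarray
    haplotypes: np.ndarray
    del_flags: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if self.del_flags.shape != self.haplotypes.shape[:2]:
            raise ValueError("del_flags shape mismatch")

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def deletion_copies(self) -> np.ndarray:
        return self.del_flags.sum(axis=1).astype(np.int64)

    def genotype_dosage(self) -> np.ndarray:
        """Additive B-allele dosage (n, m)."""
        return self.haplotypes.sum(axis=1)


@dataclass
class DeletionTruth:
    """Ground truth for the planted deletion."""

    chromosome: str
    start_bp: int
    end_bp: int
    length_bp: int
    freq_by_breed: dict
    carrier_copies: np.ndarray  # per animal, 0/1/2 (2 only if lethality incomplete)
    lethality: dict  # day -> cumulative fraction of homozygotes dead by that day
    trait_effects: dict  # trait -> additive effect of one deletion copy
    fully_lethal_at_term: bool = True

    def __post_init__(self) -> None:
        days = sorted(d for d in self.lethality if isinstance(d, (int, float)))
        vals = [self.lethality[d] for d in days] + [self.lethality.get("term", 1.0)]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("lethality schedule must be non-decreasing in day")
        for p in self.freq_by_breed.values():
            if not (0.0 <= p <= 0.5):
                raise ValueError(f"deletion frequency {p} outside [0, 0.5]")
        if self.fully_lethal_at_term and np.any(self.carrier_copies == 2):
            raise ValueError("live homozygote present despite full lethality")

    @property
    def interval(self) -> tuple:
        return (self.chromosome, self.start_bp, self.end_bp)


@dataclass
class ArrayDataset:
    """Array genotyping output: called genotypes, Log R Ratio, call quality.

    Calls coded 0=AA, 1=AB, 2=BB, -1=missing.
    """

    animal_ids: np.ndarray
    markers: MarkerMap
    calls: np.ndarray  # (n, m) int8
    lrr: np.ndarray  # (n, m) float
    quality: np.ndarray  # (n, m) float in [0, 1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.lrr)):
            raise ValueError("LRR must be finite")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    def subset_markers(self, mask: np.ndarray) -> "ArrayDataset":
        mm = MarkerMap(self.markers.table[mask].reset_index(drop=True))
        return ArrayDataset(self.animal_ids, mm, self.calls[:, mask],
                            self.lrr[:, mask], self.quality[:, mask])

    def subset_samples(self, mask: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(self.animal_ids[mask], self.markers,
                            self.calls[mask], self.lrr[mask], self.quality[mask])


@dataclass
class InseminationRecords:
    """Insemination outcomes with non-return coding.

    ``table`` columns: cow_id, sire_id, mgs_id, parity, month_year and
    failure_<d> (0 success / 1 failure) for each day d. Failure is cumulative:
    a return by day d is recorded as failure at every later day as well.
    ``truth`` (optional) carries simulation ground truth per record
    (sire_carrier, dam_copies, conceptus_copies).
    """

    table: pd.DataFrame
    days: tuple = (35, 56, 100, 150)
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = [f"failure_{d}" for d in self.days]
        f = self.table[cols].to_numpy()
        if np.any(np.diff(f, axis=1) < 0):
            raise ValueError("failure coding not cumulative across days")

    def failure_matrix(self) -> np.ndarray:
        return self.table[[f"failure_{d}" for d in self.days]].to_numpy()


@dataclass
class TraitRecords:
    """De-regressed proofs with reliabilities, long format."""

    table: pd.DataFrame  # animal_id, trait, value, reliability

    def __post_init__(self) -> None:
        r2 = self.table["reliability"].to_numpy()
        if np.any((r2 <= 0) | (r2 >= 1)):
            raise ValueError("reliabilities must lie in (0, 1)")

    def trait(self, name: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == name].reset_index(drop=True)


@dataclass
class SimulatedCohort:
    config: "PopulationConfig"
    seed: int
    pedigree: Pedigree
    markers: MarkerMap
    phased: PhasedGenotypes
    deletion: DeletionTruth
    array: ArrayDataset | None = None
    inseminations: InseminationRecords | None = None
    traits: TraitRecords | None = None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class BreedConfig:
    name: str
    n_founder_males: int
    n_founder_females: int
    n_offspring_per_generation: int
    deletion_freq: float


@dataclass
class DeletionConfig:
    chromosome: str = "12"
    start_bp: int = 20_100_650
    length_bp: int = 662_463
    # cumulative fraction of homozygous conceptuses dead by each day;
    # term value 1.0 encodes full embryonic lethality
    lethality: dict = field(default_factory=lambda: {35: 0.20, 56: 0.40, 100: 0.60, 150: 0.79, "term": 1.0})

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length_bp - 1


@dataclass
class ArrayNoiseConfig:
    """LRR mixture by copy number and genotype-call noise."""

    lrr_mean: dict = field(default_factory=lambda: {2: 0.0, 1: -0.66, 0: -5.0})
    lrr_sd: dict = field(default_factory=lambda: {2: 0.20, 1: 0.25, 0: 1.0})
    genotype_error_rate: float = 0.002
    opposite_hom_error_fraction: float = 0.05  # of hom-call errors
    missing_rate: float = 0.01
    zero_copy_missing_rate: float = 0.95


@dataclass
class ReproConfig:
    """Insemination-outcome model.

    ``background_failure``: cumulative background failure probability by day
    (defaults are field-scale averages). Parity/month effects shift the
    cumulative curve additively; the MGS random effect is a per-MGS normal
    deviate on the probability scale.
    """

    background_failure: dict = field(
        default_factory=lambda: {35: 0.278, 56: 0.396, 100: 0.475, 150: 0.493})
    n_records: int = 100_000
    records_per_cow: float = 3.0
    n_parities: int = 5
    parity_effect_sd: float = 0.01
    n_month_years: int = 24
    month_effect_sd: float = 0.01
    mgs_effect_sd: float = 0.01

    def __post_init__(self) -> None:
        days = sorted(self.background_failure)
        f = [self.background_failure[d] for d in days]
        if any(b < a for a, b in zip(f, f[1:])):
            raise ValueError("background failure must be non-decreasing in day")
        if any(not (0 <= x < 1) for x in f):
            raise ValueError("background failure must lie in [0, 1)")


@dataclass
class TraitConfig:
    """Trait-proof model: proofs = polygenic BV + deletion effect + noise.

    Effects are on the genetic-standard-deviation scale (sigma_a = 1).
    The deletion depresses fertility and raises milk traits (the antagonism
    that keeps it segregating).
    """

    genetic_sd: float = 1.0
    fertility_effect: float = -0.5  # per deletion copy, each fertility trait
    milk_effect: float = 0.5  # per deletion copy, milk/fat/protein
    reliability_range: tuple = (0.55, 0.95)
    index_weights: dict = field(
        default_factory=lambda: {t: 1.0 / len(FERTILITY_INDEX_TRAITS)
                                 for t in FERTILITY_INDEX_TRAITS})

    def effect_of(self, trait: str) -> float:
        if trait in FERTILITY_TRAITS:
            return self.fertility_effect
        if trait in MILK_TRAITS:
            return self.milk_effect
        return 0.0


def _default_breeds() -> list:
    # three Nordic-Red-style populations with distinct carrier frequencies;
    # founder pools sized so genotyped half-sib families stay realistic
    return [
        BreedConfig("DNK", 60, 240, 150, 0.065),
        BreedConfig("SWE", 80, 320, 250, 0.115),
        BreedConfig("FIN", 100, 400, 350, 0.16),
    ]


@dataclass
class PopulationConfig:
    breeds: list = field(default_factory=_default_breeds)
    n_generations: int = 2
    chromosome_length_bp: int = 30_000_000
    n_markers_50k: int = 600
    n_markers_hd: int = 6_000
    n_markers_in_deletion_50k: int = 5
    n_markers_in_deletion_hd: int = 174
    deletion: DeletionConfig = field(default_factory=DeletionConfig)
    n_ancestral_haplotypes: int = 12
    ancestral_switch_per_bp: float = 1.0e-7
    miscopy_rate: float = 0.01
    tag_leak_rate: float = 0.005
    cm_per_mb: float = 1.0
    noise: ArrayNoiseConfig = field(default_factory=ArrayNoiseConfig)
    repro: ReproConfig = field(default_factory=ReproConfig)
    traits: TraitConfig = field(default_factory=TraitConfig)

    def __post_init__(self) -> None:
        if not self.breeds:
            raise ValueError("at least one breed required")
        for b in self.breeds:
            if not (0.0 <= b.deletion_freq <= 0.5):
                raise ValueError(
                    f"deletion frequency {b.deletion_freq} for breed {b.name} outside [0, 0.5]")
        d = self.deletion
        days = sorted(k for k in d.lethality if k != "term")
        vals = [d.lethality[k] for k in days]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("non-monotone lethality schedule")
        if d.end_bp > self.chromosome_length_bp:
            raise ValueError("deletion extends beyond simulated chromosome")


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------


def build_marker_map(config: PopulationConfig, rng: np.random.Generator) -> MarkerMap:
    """Lay out 50K and HD panels with a fixed marker count inside the deletion.

    Markers outside the deletion are uniformly spaced with positional jitter;
    a prescribed number falls inside the interval (five 50K and 174 HD
    in-deletion markers by default).
    """
    d = config.deletion
    rows = []
    for panel, n_total, n_in in (
        ("50K", config.n_markers_50k, config.n_markers_in_deletion_50k),
        ("HD", config.n_markers_hd, config.n_markers_in_deletion_hd),
    ):
        n_out = n_total - n_in
        L = config.chromosome_length_bp
        out_len = L - d.length_bp
        # uniform grid over the non-deleted coordinate axis, then re-insert
        grid = (np.arange(n_out) + 0.5) * out_len / n_out
        jitter = rng.uniform(-0.3, 0.3, size=n_out) * out_len / n_out
        pos_out = np.clip(grid + jitter, 1, out_len).astype(np.int64)
        pos_out = np.where(pos_out >= d.start_bp, pos_out + d.length_bp, pos_out)
        pos_in = np.linspace(d.start_bp + 1_000, d.end_bp - 1_000, n_in).astype(np.int64)
        pos = np.unique(np.concatenate([pos_out, pos_in]))
        for i, p in enumerate(pos):
            rows.append((f"{panel}_{d.chromosome}_{p}", d.chromosome, int(p), panel, "A", "B"))
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position",
                                     "panel", "allele_a", "allele_b"])
    df = (df.sort_values("position", kind="stable")
            .drop_duplicates("position")
            .reset_index(drop=True))
    return MarkerMap(df)


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------


def _ancestral_pool(n_anc: int, n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral haplotype sequences with array-style common-variant
    ascertainment: every marker segregates on 25-75% of the ancestral
    haplotypes, mirroring the fact that array SNPs are chosen to be common."""
    lo = max(1, int(np.ceil(0.25 * n_anc)))
    hi = max(lo, int(np.floor(0.75 * n_anc)))
    n_b = rng.integers(lo, hi + 1, size=n_markers)
    anc = np.zeros((n_anc, n_markers), dtype=np.uint8)
    order = np.argsort(rng.random((n_markers, n_anc)), axis=1)
    cols = np.arange(n_markers)
    for k in range(hi):
        sel = n_b > k
        anc[order[sel, k], cols[sel]] = 1
    return anc


def _founder_haplotypes(
    n_hap: int,
    carries_del: np.ndarray,
    markers: MarkerMap,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes as mosaics of ancestral sequences.

    Haplotypes carrying the deletion copy a single designated ancestral
    background across a window around the deletion, so a tag haplotype exists
    for the HMM to find; non-carriers enter that state only at a small leak
    rate there.
    """
    pos = markers.positions
    m = len(pos)
    anc = _ancestral_pool(config.n_ancestral_haplotypes, m, rng)
    del_anc = config.n_ancestral_haplotypes - 1
    d = config.deletion
    window = (pos >= d.start_bp - 2_000_000) & (pos <= d.end_bp + 2_000_000)

    gaps = np.diff(pos, prepend=pos[0])
    switch_p = 1.0 - np.exp(-config.ancestral_switch_per_bp * gaps)
    haps = np.empty((n_hap, m), dtype=np.uint8)
    states = np.empty((n_hap, m), dtype=np.int16)
    cur = rng.integers(0, config.n_ancestral_haplotypes, size=n_hap)
    for j in range(m):
        sw = rng.random(n_hap) < switch_p[j]
        cur = np.where(sw, rng.integers(0, config.n_ancestral_haplotypes, size=n_hap), cur)
        if window[j]:
            # carriers are locked to the deletion background in the window;
            # non-carriers avoid it except for a small leak
            cur = np.where(carries_del, del_anc, cur)
            on_del_bg = (~carries_del) & (cur == del_anc)
            leak = rng.random(n_hap) < config.tag_leak_rate
            reassign = on_del_bg & ~leak
            cur = np.where(reassign,
                           rng.integers(0, config.n_ancestral_haplotypes - 1, size=n_hap),
                           cur)
        states[:, j] = cur
        haps[:, j] = anc[cur, j]
    miscopy = rng.random((n_hap, m)) < config.miscopy_rate
    haps[miscopy] ^= 1
    return haps


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _meiosis(haps: np.ndarray, dflags: np.ndarray, parent_row: int,
             pos: np.ndarray, morgans: float, del_site: int,
             rng: np.random.Generator) -> tuple:
    """One gamete from a parent: Poisson crossovers, uniform on the map."""
    m = len(pos)
    n_co = rng.poisson(morgans)
    start = int(rng.integers(0, 2))
    if n_co:
        co = np.sort(rng.uniform(pos[0], pos[-1], size=n_co))
        seg = np.searchsorted(co, pos, side="right")
        strand = (start + seg) % 2
    else:
        strand = np.full(m, start, dtype=np.int64)
    gam = haps[parent_row, strand, np.arange(m)]
    gflag = bool(dflags[parent_row, strand[del_site]])
    return gam, gflag


def _drop(
    pedigree: Pedigree,
    founder_haplotypes: dict,
    markers: MarkerMap,
    rng: np.random.Generator,
    cm_per_mb: float,
    founder_del_flags: dict | None,
    reject_hom_prob: float = 0.0,
) -> PhasedGenotypes:
    pos = markers.positions
    m = len(pos)
    for fid, h in founder_haplotypes.items():
        if h.shape != (2, m):
            raise ValueError(f"founder {fid}: haplotypes do not cover the marker map")
    t = pedigree.table.sort_values("generation", kind="stable")
    ids = t["animal_id"].to_numpy()
    index = {a: i for i, a in enumerate(ids)}
    haps = np.zeros((len(ids), 2, m), dtype=np.uint8)
    dflags = np.zeros((len(ids), 2), dtype=bool)
    morgans = cm_per_mb * (pos[-1] - pos[0]) / 1e8 if m > 1 else 0.0
    if founder_del_flags is None:
        founder_del_flags = {}
    del_site = m // 2

    sires = t["sire_id"].to_numpy()
    dams = t["dam_id"].to_numpy()
    for i, (aid, sire, dam) in enumerate(zip(ids, sires, dams)):
        if sire == UNKNOWN and dam == UNKNOWN:
            haps[i] = founder_haplotypes[aid]
            fl = founder_del_flags.get(aid)
            if fl is not None:
                dflags[i] = fl
        elif sire == UNKNOWN or dam == UNKNOWN:
            raise ValueError("non-founder with a single known parent")
        else:
            si, di = index[sire], index[dam]
            while True:
                haps[i, 0], dflags[i, 0] = _meiosis(haps, dflags, si, pos, morgans, del_site, rng)
                haps[i, 1], dflags[i, 1] = _meiosis(haps, dflags, di, pos, morgans, del_site, rng)
                # a homozygous-deletion conceptus dies (is resampled) with the
                # terminal lethality; this models founder viability only
                if dflags[i].all() and rng.random() < reject_hom_prob:
                    continue
                break
    return PhasedGenotypes(ids, haps, dflags)


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: dict,
    markers: MarkerMap,
    seed: int,
    cm_per_mb: float = 1.0,
    founder_del_flags: dict | None = None,
) -> PhasedGenotypes:
    """Drop founder haplotypes through the pedigree with crossovers.

    ``founder_haplotypes`` maps founder animal_id -> (2, m) array;
    ``founder_del_flags`` maps founder animal_id -> (2,) bool for the deletion
    allele, which is inherited with the haplotype segment overlapping the
    deletion midpoint marker. Crossover counts per meiosis are Poisson with
    mean equal to the map length in Morgans; positions uniform on the map.
    Every child haplotype is a crossover mosaic of the transmitting parent's
    two haplotypes, so Mendelian consistency holds at every marker.
    """
    rng = np.random.default_rng(seed)
    return _drop(pedigree, founder_haplotypes, markers, rng, cm_per_mb,
                 founder_del_flags, reject_hom_prob=0.0)


def set_deletion_site(phased: PhasedGenotypes, markers: MarkerMap,
                      start_bp: int, end_bp: int) -> int:
    """Index of the marker used to anchor the deletion allele (midpoint)."""
    pos = markers.positions
    return int(np.searchsorted(pos, (start_bp + end_bp) // 2))


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def simulate_population(config: PopulationConfig, seed: int) -> SimulatedCohort:
    """Generate the full cohort: pedigree, phased haplotypes, deletion truth.

    Founder haplotypes carry the deletion allele at the configured per-breed
    frequency. Offspring genotypes are gene-dropped; homozygous-deletion
    conceptuses die before entering the live cohort with probability equal to
    the terminal lethality, so under full lethality no live animal carries two
    copies (dead conceptuses are resampled at cohort construction only).
    """
    rng = np.random.default_rng(seed)
    markers = build_marker_map(config, rng)
    d = config.deletion
    term_lethality = float(d.lethality.get("term", 1.0))

    # --- pedigree ---
    rows = []
    next_id = 1
    founders_by_breed = {}
    for b in config.breeds:
        males, females = [], []
        for _ in range(b.n_founder_males):
            rows.append((next_id, UNKNOWN, UNKNOWN, "M", b.name, 0))
            males.append(next_id)
            next_id += 1
        for _ in range(b.n_founder_females):
            rows.append((next_id, UNKNOWN, UNKNOWN, "F", b.name, 0))
            females.append(next_id)
            next_id += 1
        founders_by_breed[b.name] = (males, females)

    # founder deletion flags (haplotype-level), conditioned on viability
    founder_ids_all = [r[0] for r in rows]
    fdel = {}
    for b in config.breeds:
        p = b.deletion_freq
        for fid in founders_by_breed[b.name][0] + founders_by_breed[b.name][1]:
            while True:
                fl = rng.random(2) < p
                if fl.all() and rng.random() < term_lethality:
                    continue  # homozygous founder died; redraw
                break
            fdel[fid] = fl

    # offspring generations: random sire x random dam within breed
    parents_prev = {b.name: founders_by_breed[b.name] for b in config.breeds}
    for g in range(1, config.n_generations + 1):
        new_parents = {}
        for b in config.breeds:
            males, females = parents_prev[b.name]
            n_off = b.n_offspring_per_generation
            sires = rng.choice(males, size=n_off)
            dams = rng.choice(females, size=n_off)
            sexes = np.where(rng.random(n_off) < 0.5, "M", "F")
            gm, gf = [], []
            for s, dm, sx in zip(sires, dams, sexes):
                rows.append((next_id, int(s), int(dm), sx, b.name, g))
                (gm if sx == "M" else gf).append(next_id)
                next_id += 1
            new_parents[b.name] = (gm or males, gf or females)
        parents_prev = new_parents

    ped = Pedigree(pd.DataFrame(
        rows, columns=["animal_id", "sire_id", "dam_id", "sex", "breed", "generation"]))

    # --- founder haplotypes ---
    hap_carry = np.concatenate([fdel[f] for f in founder_ids_all])
    fh_matrix = _founder_haplotypes(len(founder_ids_all) * 2, hap_carry,
                                    markers, config, rng)
    founder_haps = {
        fid: fh_matrix[2 * i: 2 * i + 2]
        for i, fid in enumerate(founder_ids_all)
    }

    # --- gene drop with per-conceptus lethal-homozygote rejection ---
    phased = _drop(ped, founder_haps, markers, rng, config.cm_per_mb,
                   founder_del_flags=fdel, reject_hom_prob=term_lethality)
    copies = phased.deletion_copies
    if term_lethality == 1.0 and np.any(copies == 2):
        raise RuntimeError("live homozygote survived a fully lethal schedule")

    truth = DeletionTruth(
        chromosome=d.chromosome,
        start_bp=d.start_bp,
        end_bp=d.end_bp,
        length_bp=d.length_bp,
        freq_by_breed={b.name: b.deletion_freq for b in config.breeds},
        carrier_copies=copies,
        lethality=d.lethality,
        trait_effects={t: config.traits.effect_of(t) for t in ALL_TRAITS},
        fully_lethal_at_term=(term_lethality == 1.0),
    )
    return SimulatedCohort(config=config, seed=seed, pedigree=ped,
                           markers=markers, phased=phased, deletion=truth)


# ---------------------------------------------------------------------------
# array signals
# ---------------------------------------------------------------------------


def emit_array_signals(
    phased: PhasedGenotypes,
    markers: MarkerMap,
    deletion: DeletionTruth | None,
    noise: ArrayNoiseConfig,
    seed: int,
) -> ArrayDataset:
    """Turn true haplotypes into array calls, LRR and call-quality scores.

    Inside the deletion, carriers are hemizygous: the assay sees only the
    intact chromosome, so the call is homozygous for that allele and the LRR
    is drawn from the one-copy intensity distribution. Zero-copy samples
    mostly fail to call. A small genotype-error and missing rate apply
    everywhere; errors never create a heterozygous call at an in-deletion
    marker of a carrier (there is no second allele to see).
    """
    rng = np.random.default_rng(seed)
    n, m = phased.n_animals, phased.n_markers
    geno = phased.genotype_dosage().astype(np.int8)  # 0/1/2 = AA/AB/BB
    copy_number = np.full((n, m), 2, dtype=np.int8)
    calls = geno.copy()

    in_del = np.zeros(m, dtype=bool)
    if deletion is not None:
        in_del = markers.in_interval(deletion.start_bp, deletion.end_bp)
        if not in_del.any():
            import warnings

            warnings.warn("deletion interval off the marker map; signals unchanged")
        copies = phased.del_flags.sum(axis=1)
        carrier = copies == 1
        hom_del = copies == 2
        if in_del.any():
            # carriers: genotype = allele on the intact (non-deleted) haplotype
            intact = np.where(phased.del_flags[:, 0], 1, 0)  # index of intact hap
            intact_allele = phased.haplotypes[np.arange(n), intact][:, in_del]
            block = calls[:, in_del]
            block[carrier] = (2 * intact_allele[carrier]).astype(np.int8)
            calls[:, in_del] = block
            copy_number[np.ix_(carrier, np.where(in_del)[0])] = 1
            copy_number[np.ix_(hom_del, np.where(in_del)[0])] = 0

    # LRR from the copy-number mixture
    lrr = np.empty((n, m), dtype=np.float64)
    for cn in (2, 1, 0):
        mask = copy_number == cn
        if mask.any():
            lrr[mask] = rng.normal(noise.lrr_mean[cn], noise.lrr_sd[cn], size=int(mask.sum()))

    # genotype errors: cluster-boundary miscalls are overwhelmingly between
    # adjacent genotypes (hom <-> het); opposite-homozygote errors are rare
    err = rng.random((n, m)) < noise.genotype_error_rate
    opposite = rng.random((n, m)) < noise.opposite_hom_error_fraction
    u = rng.random((n, m))
    new_call = np.where(calls == 1, np.where(u < 0.5, 0, 2),  # het -> a hom
                        np.where(opposite, 2 - calls, 1))  # hom -> het (mostly)
    calls = np.where(err, new_call, calls).astype(np.int8)

    # hemizygote masking is physical, not statistical: force in-deletion
    # carrier calls away from heterozygous
    if deletion is not None and in_del.any():
        cblock = calls[:, in_del]
        het = cblock == 1
        fix = het & carrier[:, None]
        repl = (2 * intact_allele).astype(np.int8)
        cblock[fix] = repl[fix]
        calls[:, in_del] = cblock

    # missingness: background plus near-total failure for zero-copy assays
    miss = rng.random((n, m)) < noise.missing_rate
    miss |= (copy_number == 0) & (rng.random((n, m)) < noise.zero_copy_missing_rate)
    calls = np.where(miss, -1, calls).astype(np.int8)

    quality = np.clip(rng.beta(14, 2.5, size=(n, m)), 0.0, 1.0)
    quality[copy_number < 2] *= 0.92  # weaker clusters for reduced copy number
    return ArrayDataset(phased.animal_ids.copy(), markers, calls, lrr, quality)


# ---------------------------------------------------------------------------
# insemination outcomes
# ---------------------------------------------------------------------------


def simulate_inseminations(
    cohort: SimulatedCohort,
    repro: ReproConfig | None = None,
    seed: int = 0,
) -> InseminationRecords:
    """Simulate mating outcomes with recessive-lethal extra failure.

    Service sires and maternal grand-sires (MGS) are drawn from the cohort's
    male pool (carrier status from truth). Each cow's deletion genotype is
    assembled from her MGS gamete and a maternal-grand-dam gamete at the
    population frequency; cows homozygous for the deletion are never born, so
    dam genotypes are conditioned on viability. Conceptus genotype is drawn
    from parental gametes; a homozygous conceptus fails by day d with the
    cumulative lethality delta(d), combined multiplicatively with the
    background failure process. Failures are recorded, never replaced.
    """
    if repro is None:
        repro = cohort.config.repro
    rng = np.random.default_rng(seed)
    days = tuple(sorted(repro.background_failure))
    f_bg = np.array([repro.background_failure[d] for d in days])
    leth = cohort.deletion.lethality
    delta = np.array([float(leth.get(d, 0.0)) for d in days])

    ped = cohort.pedigree.table
    males = ped[ped["sex"] == "M"]["animal_id"].to_numpy()
    carrier_of = dict(zip(cohort.phased.animal_ids, cohort.phased.deletion_copies))
    male_copies = np.array([carrier_of[a] for a in males])
    # population deletion frequency among gametes (pooled across breeds,
    # weighted by breed founder counts)
    breed_sizes = {b.name: b.n_founder_males + b.n_founder_females
                   for b in cohort.config.breeds}
    tot = sum(breed_sizes.values())
    p_pool = sum(b.deletion_freq * breed_sizes[b.name] for b in cohort.config.breeds) / tot

    n_rec = repro.n_records
    n_cows = max(1, int(round(n_rec / repro.records_per_cow)))

    # cows: MGS drawn from male pool; dam genotype from MGS gamete + grand-dam
    # gamete, rejected if homozygous (not viable)
    mgs_idx = rng.integers(0, len(males), size=n_cows)
    mgs_ids = males[mgs_idx]
    mgs_copies = male_copies[mgs_idx]
    mgs_gamete = rng.random(n_cows) < mgs_copies / 2.0
    gd_gamete = rng.random(n_cows) < p_pool
    dam_copies = mgs_gamete.astype(int) + gd_gamete.astype(int)
    dead = dam_copies == 2
    while dead.any():
        k = int(dead.sum())
        mg = rng.random(k) < mgs_copies[dead] / 2.0
        gg = rng.random(k) < p_pool
        dam_copies[dead] = mg.astype(int) + gg.astype(int)
        dead = dam_copies == 2

    mgs_effects = rng.normal(0.0, repro.mgs_effect_sd, size=len(males))
    parity_eff = rng.normal(0.0, repro.parity_effect_sd, size=repro.n_parities)
    month_eff = rng.normal(0.0, repro.month_effect_sd, size=repro.n_month_years)

    # records
    cow_of = rng.integers(0, n_cows, size=n_rec)
    sire_idx = rng.integers(0, len(males), size=n_rec)
    sire_ids = males[sire_idx]
    sire_copies = male_copies[sire_idx]
    parity = rng.integers(1, repro.n_parities + 1, size=n_rec)
    month = rng.integers(0, repro.n_month_years, size=n_rec)

    sire_gam = rng.random(n_rec) < sire_copies / 2.0
    dam_gam = rng.random(n_rec) < dam_copies[cow_of] / 2.0
    conceptus = sire_gam.astype(int) + dam_gam.astype(int)
    hom = conceptus == 2

    shift = (parity_eff[parity - 1] + month_eff[month]
             + mgs_effects[mgs_idx[cow_of]])
    p_day = np.clip(f_bg[None, :] + shift[:, None], 0.0, 1.0)  # (n_rec, n_days)
    u_bg = rng.random(n_rec)
    fail_bg = u_bg[:, None] < p_day
    u_leth = rng.random(n_rec)
    dead_by = hom[:, None] & (u_leth[:, None] < delta[None, :])
    failure = (fail_bg | dead_by).astype(np.int8)

    table = pd.DataFrame({
        "cow_id": cow_of + 1,
        "sire_id": sire_ids,
        "mgs_id": mgs_ids[cow_of],
        "parity": parity,
        "month_year": month,
    })
    for j, d in enumerate(days):
        table[f"failure_{d}"] = failure[:, j]
    truth = pd.DataFrame({
        "sire_copies": sire_copies,
        "mgs_copies": mgs_copies[cow_of],
        "dam_copies": dam_copies[cow_of],
        "conceptus_copies": conceptus,
    })
    return InseminationRecords(table=table, days=days, truth=truth)


# ---------------------------------------------------------------------------
# trait proofs
# ---------------------------------------------------------------------------


def simulate_trait_proofs(
    cohort: SimulatedCohort,
    traits: TraitConfig | None = None,
    seed: int = 0,
) -> TraitRecords:
    """De-regressed proofs: polygenic value + deletion effect + scaled noise.

    Polygenic breeding values follow the pedigree (parent average plus
    Mendelian sampling); proof noise variance is sigma_a^2 (1 - r2) / r2 so a
    proof with reliability r2 has the usual accuracy interpretation.
    """
    if traits is None:
        traits = cohort.config.traits
    rng = np.random.default_rng(seed)
    ped = cohort.pedigree.table.sort_values("generation", kind="stable")
    ids = ped["animal_id"].to_numpy()
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    copies = dict(zip(cohort.phased.animal_ids, cohort.phased.deletion_copies))
    copies_vec = np.array([copies[a] for a in ids], dtype=float)
    sa = traits.genetic_sd

    records = []
    base_traits = FERTILITY_TRAITS + MILK_TRAITS
    bv = {}
    for trait in base_traits:
        v = np.zeros(n)
        ms = rng.normal(0.0, 1.0, size=n)
        for i, (a, s, dm) in enumerate(zip(ids, ped["sire_id"], ped["dam_id"])):
            if s == UNKNOWN:
                v[i] = ms[i] * sa
            else:
                v[i] = 0.5 * (v[index[s]] + v[index[dm]]) + ms[i] * sa * np.sqrt(0.5)
        bv[trait] = v
        r2 = rng.uniform(*traits.reliability_range, size=n)
        noise_sd = sa * np.sqrt((1.0 - r2) / r2)
        proof = v + traits.effect_of(trait) * sa * copies_vec + rng.normal(0, 1, n) * noise_sd
        records.append(pd.DataFrame({"animal_id": ids, "trait": trait,
                                     "value": proof, "reliability": r2}))
    df = pd.concat(records, ignore_index=True)

    # fertility index: configured weighted sum of component-trait proofs;
    # its reliability is the mean component reliability
    wide = df.pivot(index="animal_id", columns="trait", values="value")
    rel = df.pivot(index="animal_id", columns="trait", values="reliability")
    w = traits.index_weights
    idx_val = sum(w[t] * wide[t] for t in w)
    idx_rel = np.clip(sum(rel[t] for t in w) / len(w), 1e-6, 1 - 1e-6)
    idx_df = pd.DataFrame({
        "animal_id": wide.index.to_numpy(),
        "trait": "fertility_index",
        "value": idx_val.to_numpy(),
        "reliability": np.asarray(idx_rel),
    })
    return TraitRecords(pd.concat([df, idx_df], ignore_index=True))


def simulate_cohort_full(config: PopulationConfig, seed: int) -> SimulatedCohort:
    """Convenience: population + array + inseminations + proofs, one seed."""
    root = np.random.default_rng(seed)
    s_pop, s_arr, s_ins, s_tr = root.integers(0, 2**31 - 1, size=4)
    cohort = simulate_population(config, int(s_pop))
    cohort.array = emit_array_signals(cohort.phased, cohort.markers,
                                      cohort.deletion, config.noise, int(s_arr))
    cohort.inseminations = simulate_inseminations(cohort, config.repro, int(s_ins))
    cohort.traits = simulate_trait_proofs(cohort, config.traits, int(s_tr))
    return cohort
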