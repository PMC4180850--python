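"""Forward-in-time multi-breed population simulator.

Generates sheep-like multi-breed genotype, pedigree, phenotype and
progeny-test data with the statistical structure that multi-breed genomic
prediction assumes: several breeds derived by drift from a common base,
purebred and crossbred (F1 and three-way) progeny in paternal half-sib
families, one quantitative trait with additive, maternal and sire-by-flock
variance, and withheld progeny-tested purebred validation sires.

The simulation is locus-explicit and diploid. Haplotypes are binary allele
sequences on a uniform genetic map; meiosis draws a Poisson number of
crossovers per Morgan without interference. Every haplotype allele carries
a breed-of-origin code, so true breeding values can use breed-specific QTL
effects and gamete-level breed labels are available as ground truth for
haplotype-based relationship matrices.

All randomness flows from a single integer seed: each operation derives an
independent, order-insensitive stream via a salted ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno_qc import MISSING, GenotypeTable

BASE_ANCESTRY = 255  # ancestry code before breed divergence

# per-operation salts for deterministic, order-insensitive RNG streams
_SALT = {
    "founders": 11,
    "breeds": 13,
    "qtl": 17,
    "design": 19,
    "phenotypes": 23,
    "ebv": 29,
    "defects": 31,
}

__all__ = [
    "SimConfig",
    "SimPopulation",
    "DesignSpec",
    "QTLModel",
    "DefectSpec",
    "simulate_founders",
    "derive_breeds",
    "sample_qtl",
    "build_design",
    "true_breeding_values",
    "simulate_phenotypes",
    "simulate_progeny_test_ebv",
    "draw_validation_reliabilities",
    "plant_qc_defects",
    "drift_fst",
    "true_haplotype_origins",
    "clean_genotype_table",
    "genotype_table",
    "panel_haplotypes",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    The defaults describe the "sheep-like" preset: four breeds with one
    numerically dominant Merino-analog, three 1-Morgan chromosomes at 50k-
    chip-like uniform spacing (desk scale), heritability 0.30 with small
    maternal and sire-by-flock variance shares, and progeny-test
    reliability floors of 0.70 (0.64 for the White-Suffolk-analog, handled
    by the caller).
    """

    seed: int = 0
    n_chromosomes: int = 3
    snps_per_chromosome: int = 550
    chromosome_length: float = 1.0  # Morgans
    n_breeds: int = 4
    breed_names: tuple[str, ...] = ("MER", "BL", "PD", "WS")
    divergence_generations: tuple[int, ...] = (120, 80, 50, 50)
    effective_size: int = 150  # per breed during divergence
    n_base: int = 250
    ld_generations: int = 50  # random mating in the base before divergence
    male_fraction: float = 0.45
    n_qtl: int = 150
    across_breed_qtl_correlation: float = 0.2
    qtl_on_panel: bool = False
    trait_mean: float = 40.0  # post-weaning-weight-like, kg
    trait_sd: float = 7.6
    trait_h2: float = 0.30
    maternal_variance_ratio: float = 0.05
    sire_flock_variance_ratio: float = 0.05
    n_flocks: int = 3
    family_size_range: tuple[int, int] = (10, 30)
    validation_reliability_floor: float = 0.70

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "n_breeds": self.n_breeds,
            "effective_size": self.effective_size,
            "n_base": self.n_base,
            "n_qtl": self.n_qtl,
            "n_flocks": self.n_flocks,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if not 0 < self.trait_h2 <= 1:
            raise ValueError("trait_h2 must be in (0,1]")
        if self.maternal_variance_ratio < 0 or self.sire_flock_variance_ratio < 0:
            raise ValueError("variance ratios must be >= 0")
        if (
            self.trait_h2
            + self.maternal_variance_ratio
            + self.sire_flock_variance_ratio
            > 1
        ):
            raise ValueError("h2 + maternal + sire-flock ratios must be <= 1")
        if len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length must equal n_breeds")
        if abs(self.across_breed_qtl_correlation) > 1:
            raise ValueError("across_breed_qtl_correlation must lie in [-1,1]")
        if len(self.divergence_generations) != self.n_breeds:
            raise ValueError("divergence_generations must list one count per breed")
        lo, hi = self.family_size_range
        if not 0 < lo <= hi:
            raise ValueError("family_size_range must be an increasing positive pair")
        if not 0 < self.validation_reliability_floor < 1:
            raise ValueError("validation_reliability_floor must be in (0,1)")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def rng(self, op: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _SALT[op], int(extra)])
        )


@dataclass(frozen=True)
class GeneticMap:
    """Uniformly spaced markers on equal-length chromosomes."""

    n_chromosomes: int
    loci_per_chromosome: int
    length: float  # Morgans per chromosome

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def positions(self) -> np.ndarray:
        """Genetic position (Morgans) of each locus within its chromosome."""
        m = self.loci_per_chromosome
        within = (np.arange(m) + 0.5) / m * self.length
        return np.tile(within, self.n_chromosomes)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.repeat(np.arange(1, self.n_chromosomes + 1), self.loci_per_chromosome)

    def chrom_slice(self, c: int) -> slice:
        m = self.loci_per_chromosome
        return slice(c * m, (c + 1) * m)


@dataclass
class QTLModel:
    """QTL positions with breed-specific additive effects.

    ``effects[b, k]`` is the allele-substitution effect of QTL ``k`` when
    the allele's breed of origin is breed ``b``; across breeds the effect
    vectors are correlated at the configured level. ``loci`` indexes into
    the simulated locus array; ``panel`` is the marker panel (all loci
    minus the QTL, unless QTL are kept on-panel).
    """

    loci: np.ndarray
    effects: np.ndarray  # (n_breeds, n_qtl)
    panel: np.ndarray
    target_additive_variance: float


@dataclass
class SimPopulation:
    """A diploid population with haplotypes, ancestry and pedigree.

    ``haplotypes[i, 0]`` is animal i's paternal gamete, ``[i, 1]`` the
    maternal one. ``ancestry`` holds the breed-of-origin code of every
    allele. The pedigree uses id 0 for unknown parents; founders carry
    their breed label.
    """

    config: SimConfig
    gmap: GeneticMap
    haplotypes: np.ndarray  # (n, 2, L) uint8
    ancestry: np.ndarray  # (n, 2, L) uint8
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation, breed, cohort
    breed_freqs: np.ndarray | None = None  # (n_breeds, L) truth pools
    base_freqs: np.ndarray | None = None
    qtl: QTLModel | None = None
    true_bv: np.ndarray | None = None
    validation_sires: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.haplotypes.shape[0]
        if self.ancestry.shape != self.haplotypes.shape:
            raise ValueError("ancestry and haplotypes must have the same shape")
        if len(self.pedigree) != n:
            raise ValueError("pedigree must have one row per animal")
        ids = self.pedigree["id"].to_numpy()
        known = set(ids) | {0}
        for col in ("sire", "dam"):
            if not self.pedigree[col].isin(known).all():
                raise ValueError(f"every non-founder {col} must be in the pedigree")
        self._index = {int(a): i for i, a in enumerate(ids)}

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    def row(self, animal_id: int) -> int:
        return self._index[int(animal_id)]

    def rows(self, animal_ids: Sequence[int]) -> np.ndarray:
        return np.array([self._index[int(a)] for a in animal_ids])

    def genotypes(self) -> np.ndarray:
        """Second-allele counts (n, L)."""
        return self.haplotypes.sum(axis=1, dtype=np.int16).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# meiosis


def _gamete_phases(gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Phase indicator (0/1, which parental strand is copied) per locus for
    one meiosis: Poisson(length) crossovers per chromosome, uniform
    positions, random start strand, no interference."""
    phase = np.empty(gmap.n_loci, dtype=np.intp)
    m = gmap.loci_per_chromosome
    within = (np.arange(m) + 0.5) / m * gmap.length
    for c in range(gmap.n_chromosomes):
        k = rng.poisson(gmap.length)
        start = rng.integers(2)
        sl = gmap.chrom_slice(c)
        if k == 0:
            phase[sl] = start
        else:
            cx = np.sort(rng.uniform(0.0, gmap.length, k))
            phase[sl] = (start + np.searchsorted(cx, within)) % 2
    return phase


def _make_gametes(
    haps: np.ndarray,
    anc: np.ndarray,
    parents: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete (alleles + ancestry) per entry of ``parents``."""
    k = len(parents)
    g_h = np.empty((k, gmap.n_loci), dtype=np.uint8)
    g_a = np.empty((k, gmap.n_loci), dtype=np.uint8)
    for i, p in enumerate(parents):
        phase = _gamete_phases(gmap, rng)
        g_h[i] = np.where(phase == 0, haps[p, 0], haps[p, 1])
        g_a[i] = np.where(phase == 0, anc[p, 0], anc[p, 1])
    return g_h, g_a


def _random_mating_generation(
    haps: np.ndarray,
    anc: np.ndarray,
    n_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One generation of random mating (monoecious, no selfing)."""
    n = haps.shape[0]
    sires = rng.integers(0, n, n_offspring)
    dams = rng.integers(0, n, n_offspring)
    clash = sires == dams
    while clash.any():
        dams[clash] = rng.integers(0, n, clash.sum())
        clash = sires == dams
    ph, pa = _make_gametes(haps, anc, sires, gmap, rng)
    mh, ma = _make_gametes(haps, anc, dams, gmap, rng)
    return np.stack([ph, mh], axis=1), np.stack([pa, ma], axis=1)


# ---------------------------------------------------------------------------
# founders and breed divergence


def simulate_founders(config: SimConfig) -> SimPopulation:
    """Simulate the common base population.

    Base allele frequencies are drawn from Beta(2, 2); haplotypes start in
    linkage equilibrium and within-chromosome LD is then built up by
    ``ld_generations`` rounds of random mating at census size ``n_base``.
    """
    rng = config.rng("founders")
    gmap = GeneticMap(
        config.n_chromosomes, config.snps_per_chromosome, config.chromosome_length
    )
    freqs = rng.beta(2.0, 2.0, gmap.n_loci)
    haps = (rng.random((config.n_base, 2, gmap.n_loci)) < freqs).astype(np.uint8)
    anc = np.full_like(haps, BASE_ANCESTRY)
    for _ in range(config.ld_generations):
        haps, anc = _random_mating_generation(haps, anc, config.n_base, gmap, rng)
    ped = pd.DataFrame(
        {
            "id": np.arange(1, config.n_base + 1),
            "sire": 0,
            "dam": 0,
            "sex": np.where(np.arange(config.n_base) % 2 == 0, "M", "F"),
            "generation": 0,
            "breed": "",
            "cohort": "base",
        }
    )
    return SimPopulation(
        config=config,
        gmap=gmap,
        haplotypes=haps,
        ancestry=anc,
        pedigree=ped,
        base_freqs=haps.mean(axis=(0, 1)),
    )


def derive_breeds(base: SimPopulation, config: SimConfig) -> SimPopulation:
    """Split the base into ``n_breeds`` breeds by independent drift.

    Each breed starts from a random sample of the base and random-mates at
    effective size ``effective_size`` for its own number of divergence
    generations. The animals returned are the breed founders of the study
    pedigree (generation 0, parents unknown, labelled with their breed);
    truth allele-frequency pools per breed are recorded.
    """
    cfg = config
    ne = cfg.effective_size
    if ne > base.n_animals:
        raise ValueError(
            f"effective_size {ne} exceeds base population size {base.n_animals}"
        )
    rng = cfg.rng("breeds")
    all_h, all_a, rows = [], [], []
    breed_freqs = np.empty((cfg.n_breeds, base.gmap.n_loci))
    next_id = 1
    n_male = max(1, int(round(cfg.male_fraction * ne)))
    for b, (name, t) in enumerate(zip(cfg.breed_names, cfg.divergence_generations)):
        pick = rng.choice(base.n_animals, ne, replace=False)
        haps = base.haplotypes[pick].copy()
        anc = base.ancestry[pick].copy()
        for _ in range(t):
            haps, anc = _random_mating_generation(haps, anc, ne, base.gmap, rng)
        anc[:] = b
        breed_freqs[b] = haps.mean(axis=(0, 1))
        all_h.append(haps)
        all_a.append(anc)
        sex = np.where(np.arange(ne) < n_male, "M", "F")
        rows.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + ne),
                    "sire": 0,
                    "dam": 0,
                    "sex": sex,
                    "generation": 0,
                    "breed": name,
                    "cohort": f"founder_{name}",
                }
            )
        )
        next_id += ne
    return SimPopulation(
        config=cfg,
        gmap=base.gmap,
        haplotypes=np.concatenate(all_h),
        ancestry=np.concatenate(all_a),
        pedigree=pd.concat(rows, ignore_index=True),
        breed_freqs=breed_freqs,
        base_freqs=base.base_freqs,
    )


# ---------------------------------------------------------------------------
# QTL model and true breeding values


def sample_qtl(population: SimPopulation, config: SimConfig) -> QTLModel:
    """Sample QTL among segregating loci and draw breed-specific effects.

    Per QTL, the vector of effects across breeds is multivariate normal
    with unit marginals and equicorrelation ``across_breed_qtl_correlation``.
    Effects are then rescaled jointly so that the variance of true breeding
    values among the focal-breed (first-listed breed) founders equals
    ``trait_h2 * trait_sd**2``. By default QTL are excluded from the marker
    panel, mimicking a chip that tags but does not include causal variants.
    """
    cfg = config
    rho = cfg.across_breed_qtl_correlation
    rng = cfg.rng("qtl")
    freqs = population.allele_frequencies()
    segregating = np.flatnonzero((freqs > 0) & (freqs < 1))
    if cfg.n_qtl > len(segregating):
        raise ValueError(
            f"n_qtl={cfg.n_qtl} exceeds the {len(segregating)} segregating loci"
        )
    loci = np.sort(rng.choice(segregating, cfg.n_qtl, replace=False))

    nb = cfg.n_breeds
    cov = np.full((nb, nb), rho) + (1 - rho) * np.eye(nb)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10:
        raise ValueError(
            f"equicorrelation {rho} is not positive semi-definite for {nb} breeds"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    effects = (root @ rng.standard_normal((nb, cfg.n_qtl)))  # (n_breeds, n_qtl)

    qtl = QTLModel(
        loci=loci,
        effects=effects,
        panel=_panel_indices(population.gmap.n_loci, loci, cfg.qtl_on_panel),
        target_additive_variance=cfg.trait_h2 * cfg.trait_sd**2,
    )
    focal_rows = np.flatnonzero(
        population.pedigree["breed"].to_numpy() == cfg.breed_names[0]
    )
    if len(focal_rows) == 0:
        raise ValueError("no focal-breed animals available for effect scaling")
    g = _raw_breeding_values(population, qtl)[focal_rows]
    v = g.var()
    if v == 0:
        raise ValueError("zero additive variance in the focal breed; cannot scale")
    qtl.effects *= np.sqrt(qtl.target_additive_variance / v)
    return qtl


def _panel_indices(n_loci: int, qtl_loci: np.ndarray, qtl_on_panel: bool) -> np.ndarray:
    if qtl_on_panel:
        return np.arange(n_loci)
    mask = np.ones(n_loci, dtype=bool)
    mask[qtl_loci] = False
    return np.flatnonzero(mask)


def _raw_breeding_values(pop: SimPopulation, qtl: QTLModel) -> np.ndarray:
    alleles = pop.haplotypes[:, :, qtl.loci]
    origin = pop.ancestry[:, :, qtl.loci]
    if (origin == BASE_ANCESTRY).any():
        # pre-divergence animals: use focal-breed effects everywhere
        origin = np.where(origin == BASE_ANCESTRY, 0, origin)
    eff = qtl.effects[origin, np.arange(qtl.loci.size)]
    return (alleles * eff).sum(axis=(1, 2))


def true_breeding_values(pop: SimPopulation, qtl: QTLModel | None = None) -> np.ndarray:
    """Additive genetic value of each animal: sum over QTL alleles of
    allele content times the effect for that allele's breed of origin."""
    model = qtl or pop.qtl
    if model is None:
        raise ValueError("population has no QTL model")
    return _raw_breeding_values(pop, model)


# ---------------------------------------------------------------------------
# mating design


@dataclass
class DesignSpec:
    """Progeny cohorts of the study design.

    ``n_purebred`` maps a breed to the number of purebred progeny;
    ``f1_crosses`` lists (sire_breed, dam_breed, n) cohorts; ``three_way``
    lists (sire_breed, f1_sire_breed, f1_dam_breed, n) cohorts whose dams
    are F1 females generated on demand. ``n_sires`` caps the breeding sire
    pool per breed. ``validation_sires[breed]`` progeny-tested validation
    candidates are generated as purebred *sons* of the breeding sire pool
    (one per pool sire, cycling): young industry rams from the same
    paternal lines as the reference, so the reference's paternal
    haplotypes are more related to the validation set than dam haplotypes
    are — without any validation animal being a parent of a reference
    animal.

    ``n_dams[breed]``, when set, breeds an expanded generation of research
    ewes (purebred daughters of founder males *outside* the breeding sire
    pool) that replaces the founder females as the dam pool for that
    breed: each ewe then has only one or two lambs, and the dam side is
    less related to the validation sires than the sire side, as in
    research-flock data.
    """

    n_purebred: Mapping[str, int] = field(default_factory=dict)
    f1_crosses: Sequence[tuple[str, str, int]] = ()
    three_way: Sequence[tuple[str, str, str, int]] = ()
    n_sires: Mapping[str, int] = field(default_factory=dict)
    validation_sires: Mapping[str, int] = field(default_factory=dict)
    n_dams: Mapping[str, int] = field(default_factory=dict)


def _family_sizes(total: int, rng: np.random.Generator, lo: int, hi: int) -> list[int]:
    sizes: list[int] = []
    left = total
    while left > 0:
        s = int(rng.integers(lo, hi + 1))
        sizes.append(min(s, left))
        left -= sizes[-1]
    return sizes


def build_design(
    breeds: SimPopulation, config: SimConfig, design: DesignSpec
) -> SimPopulation:
    """Generate the progeny cohorts of a mating design.

    Progeny are produced in paternal half-sib families whose sizes are
    drawn from ``family_size_range``; within a family, dams are sampled
    without replacement. Sires rotate through the breed's sire pool so
    every pool sire (including validation sires) contributes families.
    Each progeny records its sire and dam; haplotype slot 0 is the
    paternal gamete, slot 1 the maternal one. Families are assigned to
    flocks at random.
    """
    cfg = config
    rng = cfg.rng("design")
    ped = breeds.pedigree
    males = {
        b: ped.loc[(ped["breed"] == b) & (ped["sex"] == "M"), "id"].to_numpy()
        for b in cfg.breed_names
    }
    females = {
        b: ped.loc[(ped["breed"] == b) & (ped["sex"] == "F"), "id"].to_numpy()
        for b in cfg.breed_names
    }
    sire_pool: dict[str, np.ndarray] = {}
    for b in cfg.breed_names:
        cap = design.n_sires.get(b, len(males[b]))
        if cap > len(males[b]):
            raise ValueError(f"breed {b}: requested {cap} sires, have {len(males[b])}")
        sire_pool[b] = males[b][:cap]

    haps = [breeds.haplotypes]
    ancs = [breeds.ancestry]
    rows = [ped.copy()]
    rows[0]["flock"] = 0
    next_id = int(ped["id"].max()) + 1
    n_rows = breeds.n_animals
    row_lookup = {int(a): i for i, a in enumerate(ped["id"].to_numpy())}
    lo, hi = cfg.family_size_range

    def emit_cohort(sires, dam_ids, n, cohort, generation):
        nonlocal next_id, n_rows
        if len(sires) == 0 or len(dam_ids) == 0:
            raise ValueError(f"empty parent pool for cohort {cohort}")
        # parents may come from any earlier cohort: rebuild the full arrays
        cat_h, cat_a = np.concatenate(haps), np.concatenate(ancs)
        sizes = _family_sizes(n, rng, lo, hi)
        out = []
        for fam, size in enumerate(sizes):
            sire = int(sires[fam % len(sires)])
            if size > len(dam_ids):
                raise ValueError(
                    f"cohort {cohort}: family of {size} needs more dams than "
                    f"the {len(dam_ids)} available"
                )
            dams = rng.choice(dam_ids, size, replace=False)
            flock = int(rng.integers(1, cfg.n_flocks + 1))
            s_rows = np.full(size, row_lookup[sire])
            d_rows = np.array([row_lookup[int(d)] for d in dams])
            ph, pa = _make_gametes(cat_h, cat_a, s_rows, breeds.gmap, rng)
            mh, ma = _make_gametes(cat_h, cat_a, d_rows, breeds.gmap, rng)
            haps.append(np.stack([ph, mh], axis=1))
            ancs.append(np.stack([pa, ma], axis=1))
            ids = np.arange(next_id, next_id + size)
            next_id += size
            for aid in ids:
                row_lookup[int(aid)] = n_rows
                n_rows += 1
            out.append(
                pd.DataFrame(
                    {
                        "id": ids,
                        "sire": sire,
                        "dam": dams,
                        "sex": rng.choice(["M", "F"], size),
                        "generation": generation,
                        "breed": "",
                        "cohort": cohort,
                        "flock": flock,
                    }
                )
            )
        return pd.concat(out, ignore_index=True)

    # expanded research-ewe generation (dams outside the paternal lines)
    for b, n in design.n_dams.items():
        if n <= 0:
            continue
        non_pool = males[b][len(sire_pool[b]):]
        if len(non_pool) == 0:
            raise ValueError(f"breed {b}: no non-pool males to breed a dam cohort")
        ewes = emit_cohort(non_pool, females[b], n, f"ewes_{b}", 1)
        ewes["sex"] = "F"
        rows.append(ewes)
        females[b] = ewes["id"].to_numpy()

    for b, n in design.n_purebred.items():
        rows.append(emit_cohort(sire_pool[b], females[b], n, f"purebred_{b}", 1))
    for sb, db, n in design.f1_crosses:
        rows.append(emit_cohort(sire_pool[sb], females[db], n, f"f1_{sb}_{db}", 1))
    for sb, fsb, fdb, n in design.three_way:
        # generate F1 dams first, then the terminal cross
        n_f1_dams = max(n // 2, lo)
        f1 = emit_cohort(sire_pool[fsb], females[fdb], n_f1_dams, f"f1dam_{fsb}_{fdb}", 1)
        f1["sex"] = "F"
        rows.append(f1)
        rows.append(
            emit_cohort(sire_pool[sb], f1["id"].to_numpy(), n, f"threeway_{sb}_{fsb}{fdb}", 2)
        )

    # validation sires: purebred sons of the breeding pool, one dam each
    val_ids: dict[str, list[int]] = {}
    for b, k in design.validation_sires.items():
        if k <= 0:
            continue
        pool = sire_pool[b]
        if len(pool) == 0 or len(females[b]) == 0:
            raise ValueError(f"breed {b}: empty parent pool for validation sires")
        cat_h, cat_a = np.concatenate(haps), np.concatenate(ancs)
        sire_ids_k = [int(pool[i % len(pool)]) for i in range(k)]
        sires_k = np.array([row_lookup[s] for s in sire_ids_k])
        dams_k_ids = rng.choice(females[b], k, replace=k > len(females[b]))
        dams_k = np.array([row_lookup[int(d)] for d in dams_k_ids])
        ph, pa = _make_gametes(cat_h, cat_a, sires_k, breeds.gmap, rng)
        mh, ma = _make_gametes(cat_h, cat_a, dams_k, breeds.gmap, rng)
        haps.append(np.stack([ph, mh], axis=1))
        ancs.append(np.stack([pa, ma], axis=1))
        ids = np.arange(next_id, next_id + k)
        next_id += k
        for aid in ids:
            row_lookup[int(aid)] = n_rows
            n_rows += 1
        rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "sire": sire_ids_k,
                    "dam": dams_k_ids,
                    "sex": "M",
                    "generation": 1,
                    "breed": "",
                    "cohort": f"valsire_{b}",
                    "flock": 0,
                }
            )
        )
        val_ids[b] = [int(a) for a in ids]

    pedigree = pd.concat(rows, ignore_index=True)
    pedigree["flock"] = pedigree["flock"].fillna(0).astype(int)
    out = SimPopulation(
        config=cfg,
        gmap=breeds.gmap,
        haplotypes=np.concatenate(haps),
        ancestry=np.concatenate(ancs),
        pedigree=pedigree,
        breed_freqs=breeds.breed_freqs,
        base_freqs=breeds.base_freqs,
        qtl=breeds.qtl,
        validation_sires=val_ids,
    )
    return out


# ---------------------------------------------------------------------------
# phenotypes and validation EBV


def simulate_phenotypes(
    population: SimPopulation,
    config: SimConfig,
    seed: int | None = None,
    include_fixed_effects: bool = True,
) -> pd.DataFrame:
    """Simulate one trait record for every progeny (generation >= 1).

    The record model is ``y = mu + fixed + g + w_dam + s_sire.flock + e``
    with fixed effects for birth type, rearing type, sex, an age covariate
    and contemporary group (site x birth year x management group; site is
    the family's flock). Variance shares follow the configuration: the
    additive variance is carried by the true breeding values, maternal and
    sire-by-flock effects are i.i.d. normal per dam and per sire-flock
    combination, and the residual takes the remainder of ``trait_sd**2``.
    """
    cfg = config
    if population.qtl is None:
        raise ValueError("simulate phenotypes after sampling a QTL model")
    rng = (
        cfg.rng("phenotypes")
        if seed is None
        else np.random.default_rng(np.random.SeedSequence([int(seed), _SALT["phenotypes"]]))
    )
    ped = population.pedigree
    # record cohorts: purebred, F1 and three-way progeny (not breeding
    # ewes, F1 dams or validation sires)
    phenotyped = ped["cohort"].str.match(r"(purebred_|f1_[A-Z]|threeway_)")
    rec = ped[(ped["generation"] >= 1) & phenotyped].copy()
    if (rec["dam"] == 0).any():
        raise ValueError("progeny with unknown dam cannot receive a maternal effect")
    n = len(rec)
    sigma_p = cfg.trait_sd
    var_p = sigma_p**2

    tbv = true_breeding_values(population)[population.rows(rec["id"])]

    dams = rec["dam"].to_numpy()
    u_dams = np.unique(dams)
    w = dict(
        zip(u_dams, rng.normal(0, np.sqrt(cfg.maternal_variance_ratio * var_p), len(u_dams)))
    )
    sf_key = rec["sire"].astype(str) + ":" + rec["flock"].astype(str)
    u_sf = sf_key.unique()
    s = dict(
        zip(u_sf, rng.normal(0, np.sqrt(cfg.sire_flock_variance_ratio * var_p), len(u_sf)))
    )
    resid_ratio = 1 - cfg.trait_h2 - cfg.maternal_variance_ratio - cfg.sire_flock_variance_ratio
    e = rng.normal(0, np.sqrt(resid_ratio * var_p), n)

    rec["birth_type"] = rng.choice([1, 2, 3], n, p=[0.4, 0.5, 0.1])
    rec["rear_type"] = np.minimum(rec["birth_type"], rng.choice([1, 2], n, p=[0.3, 0.7]))
    rec["age"] = rng.uniform(125, 300, n)
    rec["year"] = 1
    rec["mgmt"] = rng.integers(1, 3, n)
    rec["cg"] = (
        rec["flock"].astype(str) + "_" + rec["year"].astype(str) + "_" + rec["mgmt"].astype(str)
    )

    y = cfg.trait_mean + tbv + np.array([w[d] for d in dams]) + np.array(
        [s[k] for k in sf_key]
    ) + e
    if include_fixed_effects:
        bt_eff = {1: 0.0, 2: -0.45 * sigma_p, 3: -0.8 * sigma_p}
        rt_eff = {1: 0.0, 2: -0.2 * sigma_p}
        sex_eff = {"M": 0.25 * sigma_p, "F": 0.0}
        cg_levels = rec["cg"].unique()
        cg_eff = dict(zip(cg_levels, rng.normal(0, 0.4 * sigma_p, len(cg_levels))))
        y = (
            y
            + rec["birth_type"].map(bt_eff).to_numpy()
            + rec["rear_type"].map(rt_eff).to_numpy()
            + rec["sex"].map(sex_eff).to_numpy()
            + 0.04 * (rec["age"].to_numpy() - 212.5)
            + rec["cg"].map(cg_eff).to_numpy()
        )
    rec["y"] = y
    rec["true_bv"] = tbv
    cols = [
        "id", "sire", "dam", "sex", "cohort", "flock", "birth_type", "rear_type",
        "age", "year", "mgmt", "cg", "y", "true_bv",
    ]
    return rec[cols].reset_index(drop=True)


def draw_validation_reliabilities(
    n: int, floor: float, rng: np.random.Generator, ceiling: float = 0.98
) -> np.ndarray:
    """Per-sire progeny-test accuracies, uniform on [floor, ceiling]."""
    if not 0 < floor < ceiling <= 1:
        raise ValueError("need 0 < floor < ceiling <= 1")
    return rng.uniform(floor, ceiling, n)


def simulate_progeny_test_ebv(
    true_bv: np.ndarray,
    reliability: float | np.ndarray,
    seed: int,
    animal_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Simulate progeny-test EBVs at a stated accuracy.

    ``reliability`` is interpreted as the *accuracy* r, i.e. the
    correlation between the EBV and the true breeding value (the usual
    sheep-industry reporting scale, derived from prediction error
    variance), not as r squared. Each EBV is
    ``r * z + sqrt(1 - r^2) * eps`` in standardized true-breeding-value
    units, mapped back to trait units, so realized cor(EBV, TBV)
    approaches r as the group grows.
    """
    g = np.asarray(true_bv, dtype=float)
    r = np.broadcast_to(np.asarray(reliability, dtype=float), g.shape).copy()
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("reliability (accuracy) must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SALT["ebv"]]))
    sd = g.std()
    if sd == 0:
        raise ValueError("true breeding values have zero variance")
    z = (g - g.mean()) / sd
    ebv_std = r * z + np.sqrt(1 - r**2) * rng.standard_normal(g.shape)
    ebv = g.mean() + sd * ebv_std
    return pd.DataFrame(
        {
            "animal": animal_ids if animal_ids is not None else np.arange(len(g)),
            "ebv": ebv,
            "accuracy": r,
        }
    )


# ---------------------------------------------------------------------------
# genotype-table bridge and QC defect planting


def genotype_table(
    pop: SimPopulation,
    panel: np.ndarray | None = None,
    with_confidence: bool = True,
    animal_rows: np.ndarray | None = None,
) -> GenotypeTable:
    """Export a (subset of the) population as a clean genotype table on the
    marker panel (QTL excluded by default when the population has one)."""
    if panel is None:
        panel = pop.qtl.panel if pop.qtl is not None else np.arange(pop.gmap.n_loci)
    rows = np.arange(pop.n_animals) if animal_rows is None else animal_rows
    calls = pop.genotypes()[np.ix_(rows, panel)]
    chroms = pop.gmap.chromosomes[panel]
    pos_cm = np.round(pop.gmap.positions[panel] * 100, 4)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{j}" for c, j in zip(chroms, panel)],
            "chrom": chroms.astype(str),
            "pos": pos_cm,
            "a1": "1",
            "a2": "2",
            "locus": panel,  # simulator locus index, survives QC subsetting
        }
    )
    conf = np.ones(calls.shape) if with_confidence else None
    ids = [str(a) for a in pop.ids[rows]]
    return GenotypeTable(ids, snps, calls, conf)


def panel_haplotypes(pop: SimPopulation, panel: np.ndarray | None = None) -> np.ndarray:
    """Phased 0/1 haplotypes (n, 2, panel loci); slot 0 paternal."""
    if panel is None:
        panel = pop.qtl.panel if pop.qtl is not None else np.arange(pop.gmap.n_loci)
    return pop.haplotypes[:, :, panel]


def drift_fst(freqs_a: np.ndarray, freqs_b: np.ndarray, base_freqs: np.ndarray) -> float:
    """Fixation index between two populations drifted from a known base.

    Uses the base-frequency form matched to Wright's pure-drift
    expectation: FST = sum (p_a - p_b)^2 / (2 sum p0 (1 - p0)), whose
    expectation after t generations at size Ne is 1 - (1 - 1/(2Ne))^t.
    """
    p0 = np.asarray(base_freqs, float)
    w = p0 * (1 - p0)
    if w.sum() == 0:
        raise ValueError("base population is monomorphic everywhere")
    num = ((np.asarray(freqs_a, float) - np.asarray(freqs_b, float)) ** 2).sum()
    return float(num / (2 * w.sum()))


def true_haplotype_origins(
    pop: SimPopulation, purity_threshold: float = 0.97
) -> pd.DataFrame:
    """Ground-truth breed-of-origin label per parental haplotype.

    For each animal and gamete, the fraction of loci whose recorded
    ancestry comes from the majority breed is the gamete's purity; the
    gamete is labelled with that breed when purity exceeds the threshold,
    else ``mixed`` (e.g. the recombinant maternal gamete of a three-way
    cross). Animals with any mixed gamete are ineligible for the gametic
    breed-specific-frequency relationship matrix.
    """
    names = pop.config.breed_names
    recs = {}
    for i, aid in enumerate(pop.ids):
        labs = []
        purs = []
        for slot in (0, 1):
            anc = pop.ancestry[i, slot]
            codes, counts = np.unique(anc, return_counts=True)
            k = int(np.argmax(counts))
            purity = counts[k] / anc.size
            code = int(codes[k])
            if purity > purity_threshold and code != BASE_ANCESTRY:
                labs.append(names[code])
            else:
                labs.append("mixed")
            purs.append(float(purity))
        recs[int(aid)] = (labs[0], labs[1], purs[0], purs[1],
                          labs[0] != "mixed" and labs[1] != "mixed")
    df = pd.DataFrame.from_dict(
        recs,
        orient="index",
        columns=["paternal_breed", "maternal_breed", "paternal_purity",
                 "maternal_purity", "g2_eligible"],
    )
    df.index.name = "id"
    return df


def clean_genotype_table(
    n_animals: int = 200, n_snps: int = 100, seed: int = 0
) -> GenotypeTable:
    """A genotype table guaranteed to pass the SNP QC cascade untouched.

    Genotypes are i.i.d. Hardy-Weinberg draws at minor allele frequencies
    uniform on [0.08, 0.45] (both allele orientations), with full call rate
    and confidence 1. Because the heterozygosity filter is relative to the
    panel, the table is passed through the cascade repeatedly until it is a
    fixed point, then trimmed to ``n_snps``; the result is the natural
    starting point for :func:`plant_qc_defects`.
    """
    from .geno_qc import qc_snps  # local import to avoid cycle at module load

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SALT["defects"], 1]))
    m0 = int(n_snps * 1.4) + 10
    maf = rng.uniform(0.08, 0.45, m0)
    p = np.where(rng.random(m0) < 0.5, maf, 1 - maf)
    calls = rng.binomial(2, p, size=(n_animals, m0)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp_id": [f"fix{j}" for j in range(m0)],
            "chrom": "1",
            "pos": np.arange(m0, dtype=float),
            "a1": "1",
            "a2": "2",
        }
    )
    table = GenotypeTable([f"an{i}" for i in range(n_animals)], snps, calls,
                          np.ones((n_animals, m0)))
    for _ in range(20):
        nxt, rep = qc_snps(table)
        if nxt.n_snps == table.n_snps:
            break
        table = nxt
    if table.n_snps < n_snps:
        raise ValueError("fixture generation lost too many SNPs; use a larger pool")
    table = table.subset(snp_idx=np.arange(n_snps))
    for _ in range(20):
        nxt, rep = qc_snps(table)
        if nxt.n_snps == table.n_snps:
            return table
        table = nxt
    raise RuntimeError("clean fixture did not reach a QC fixed point")


@dataclass
class DefectSpec:
    """How many QC violations of each kind to plant."""

    n_low_confidence: int = 0
    n_call_rate: int = 0
    n_heterozygosity: int = 0
    n_maf: int = 0
    n_sex_chromosome: int = 0
    n_hwe: int = 0
    n_duplicate_samples: int = 0
    missing_fraction: float = 0.08  # per defective-call-rate SNP
    duplicate_discordant_calls: int = 0  # flipped calls per planted duplicate

    @property
    def n_snp_defects(self) -> int:
        return (
            self.n_low_confidence
            + self.n_call_rate
            + self.n_heterozygosity
            + self.n_maf
            + self.n_sex_chromosome
            + self.n_hwe
        )


def plant_qc_defects(
    table: GenotypeTable, defect_spec: DefectSpec, seed: int
) -> tuple[GenotypeTable, dict]:
    """Inject known QC violations into a clean table.

    Each defect type is planted on its own randomly chosen SNPs (samples
    for duplicates) and recorded in the returned ground-truth ledger:
    low-confidence scores and missing calls that push the call rate under
    95%, an all-heterozygote column, a near-monomorphic column (MAF below
    1%), a relabelled sex chromosome, and a heterozygote-deficient column
    whose exact genotype counts violate Hardy-Weinberg far beyond p=1e-15
    while keeping its heterozygosity inside the 3-SD panel band.
    Duplicates append a copy of an existing sample with one discordant
    call. An empty spec returns an identical copy.
    """
    spec = defect_spec
    if spec.n_snp_defects > table.n_snps:
        raise ValueError("more planted SNP defects than SNPs")
    if spec.n_duplicate_samples > table.n_animals:
        raise ValueError("more planted duplicates than samples")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _SALT["defects"]]))
    out = table.copy()
    n, m = out.n_animals, out.n_snps
    if out.confidence is None and spec.n_low_confidence > 0:
        out.confidence = np.ones((n, m))
    targets = rng.choice(m, spec.n_snp_defects, replace=False)
    it = iter(targets)
    ledger: dict = {"snps": {}, "samples": [], "all_snps": []}

    def take(kind: str, count: int):
        cols = [int(next(it)) for _ in range(count)]
        if cols:
            ids = out.snps["snp_id"].iloc[cols].tolist()
            ledger["snps"][kind] = ids
            ledger["all_snps"].extend(ids)
        return cols

    n_bad_calls = max(int(np.ceil(spec.missing_fraction * n)), int(0.051 * n) + 1)
    for j in take("low_confidence", spec.n_low_confidence):
        rows = rng.choice(n, n_bad_calls, replace=False)
        out.confidence[rows, j] = 0.3
    for j in take("call_rate", spec.n_call_rate):
        rows = rng.choice(n, n_bad_calls, replace=False)
        out.calls[rows, j] = MISSING
    for j in take("heterozygosity", spec.n_heterozygosity):
        out.calls[:, j] = 1
    for j in take("maf", spec.n_maf):
        out.calls[:, j] = 0
        out.calls[int(rng.integers(n)), j] = 1
    for j in take("sex_chromosome", spec.n_sex_chromosome):
        out.snps.loc[j, "chrom"] = "X"
    for j in take("hwe", spec.n_hwe):
        # counts (0.45n, 0.10n, 0.45n): het ~0.10 stays inside the band,
        # chi-square ~ 0.64 n blows far past the HWE threshold for n >= 150
        n1 = int(round(0.10 * n))
        n0 = (n - n1) // 2
        col = np.array([0] * n0 + [1] * n1 + [2] * (n - n0 - n1), dtype=np.int8)
        rng.shuffle(col)
        out.calls[:, j] = col

    if spec.n_duplicate_samples > 0:
        src = rng.choice(n, spec.n_duplicate_samples, replace=False)
        new_calls, new_conf, new_ids = [], [], []
        for i in src:
            dup = out.calls[i].copy()
            for flip in rng.choice(m, spec.duplicate_discordant_calls, replace=False):
                dup[flip] = 1 if dup[flip] != 1 else 0
            new_calls.append(dup)
            if out.confidence is not None:
                new_conf.append(out.confidence[i].copy())
            new_ids.append(f"{out.animal_ids[i]}_dup")
        out = GenotypeTable(
            out.animal_ids + new_ids,
            out.snps,
            np.vstack([out.calls, np.array(new_calls)]),
            None
            if out.confidence is None
            else np.vstack([out.confidence, np.array(new_conf)]),
        )
        ledger["samples"] = new_ids
    return out, ledger
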