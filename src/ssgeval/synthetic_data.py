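"""Multi-breed pedigree, genotype and withers-height simulator.

The generator emulates the structure of a German Warmblood mare reference
population: five studbooks of very unequal size, a shallow (three ancestral
generations) pedigree roughly seven times the genotyped cohort, a few
heavily used sires with tens of offspring next to many sires with one or
two, dams reused at most a couple of times, withers height around
167.6 +/- 3.5 cm shaped by one major stature QTL (on chromosome 3, near
*LCORL* in the real genome) plus a polygenic background, and five age
classes at measurement.

Genotypes are produced by gene dropping: founder haplotypes are drawn from
breed-specific allele frequencies (a Balding-Nichols perturbation of a
shared ancestral frequency, with the divergence parameter playing the role
of Fst) and transmitted with crossovers placed as a Poisson process on a
uniform genetic map of 1 Morgan per chromosome.

The polygenic value is simulated along the pedigree (founder draw plus
Mendelian sampling), *not* from the markers, so pedigree-based and
SNP-based heritability can legitimately differ — as they do in real horse
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io_formats import MISSING_CALL, GenotypeMatrix, Pedigree, PhenotypeTable, age_class

logger = logging.getLogger("ssgeval.sim")

#: studbook sizes of the emulated reference population (HOL, OL, OS, TRAK, WESTF)
PAPER_BREED_SIZES = (982, 444, 98, 416, 173)
PAPER_BREEDS = ("HOL", "OL", "OS", "TRAK", "WESTF")


@dataclass
class SimConfig:
    """All knobs of the simulator; ``seed`` is mandatory.

    ``breed_sizes`` are the *final generation* (genotyped mare) counts.
    ``qtl_spec`` entries are ``(chrom, bp, variance_fraction)`` with the
    fraction expressed relative to total phenotypic variance.  Defaults are
    the emulated study's conditions: one major QTL carrying 23% of the
    phenotypic variance, a polygenic share of 27% (total heritability 0.5),
    mean height 167.6 cm and total SD 3.5 cm.
    """

    seed: int
    n_breeds: int = 5
    breed_sizes: tuple = PAPER_BREED_SIZES
    breed_names: tuple = PAPER_BREEDS
    n_founders_per_breed: int | None = None  # None: 2.5x the breed size
    n_generations: int = 3  # ancestral generations before the final one
    sire_sharing_rate: float = 0.15
    n_chromosomes: int = 31
    markers_per_chrom: int = 200
    chrom_length_morgans: float = 1.0
    founder_freq_divergence: float = 0.05
    qtl_spec: tuple = ((3, 105_500_000, 0.23),)
    h2_polygenic: float = 0.27
    mean_height: float = 167.6
    sd_total: float = 3.5
    age_class_effects: tuple = (-2.0, -0.7, 0.0, 0.4, 0.8)
    missing_rate: float = 0.02
    first_birth_year: int = 1988
    years_per_generation: int = 7

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.breed_sizes) != self.n_breeds:
            raise ValueError("breed_sizes length must equal n_breeds")
        if any(s <= 0 for s in self.breed_sizes):
            raise ValueError("breed_sizes must be positive")
        if len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names length must equal n_breeds")
        frac = self.h2_polygenic + sum(q[2] for q in self.qtl_spec)
        if not (0 <= self.h2_polygenic <= 1) or any(
            not (0 <= q[2] <= 1) for q in self.qtl_spec
        ):
            raise ValueError("variance fractions must lie in [0,1]")
        if frac > 1:
            raise ValueError(
                f"QTL fractions + h2_polygenic = {frac:.3f} exceed 1"
            )
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0,1)")
        if len(self.age_class_effects) != 5:
            raise ValueError("age_class_effects needs exactly 5 entries")

    @property
    def total_variance(self) -> float:
        return self.sd_total**2

    @property
    def sd_env(self) -> float:
        frac = self.h2_polygenic + sum(q[2] for q in self.qtl_spec)
        return float(np.sqrt(self.total_variance * (1.0 - frac)))

    def scaled(self, factor: float) -> "SimConfig":
        """Shrink every breed by ``factor`` (at least 5 mares each)."""
        sizes = tuple(max(5, int(round(s * factor))) for s in self.breed_sizes)
        return replace(self, breed_sizes=sizes)


def paper_shaped_config(seed: int, scale: float = 1.0, **overrides) -> SimConfig:
    """The default preset at the emulated study's shape, optionally scaled."""
    cfg = SimConfig(seed=seed, **overrides)
    return cfg.scaled(scale) if scale != 1.0 else cfg


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def _family_sizes(rng: np.random.Generator, total: int) -> list[int]:
    """Long-tailed sire family sizes summing to ``total``.

    Mostly geometric around 2.5 offspring, with a small admixture of
    heavily used sires (20-60 offspring) so the distribution has the
    1-to-82 spread of real studbooks while keeping the mean near 3.5.
    """
    sizes: list[int] = []
    remaining = total
    while remaining > 0:
        if rng.random() < 0.03:
            k = int(rng.integers(20, 61))
        else:
            k = int(rng.geometric(1 / 2.5))
        k = min(k, remaining)
        sizes.append(k)
        remaining -= k
    return sizes


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a multi-breed pedigree, deterministic given ``config.seed``.

    Generation 0 founders shrink linearly to the configured breed sizes in
    the final generation; each offspring's sire is drawn via long-tailed
    family sizes, its dam is reused at most three times, and a fraction of
    sires serve more than one breed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    G = config.n_generations  # ancestral generations; final is generation G
    records: list[tuple] = []
    generations: dict[str, int] = {}
    # per breed, per generation: lists of (id,) for males / females
    males: dict[tuple[int, int], list[str]] = {}
    females: dict[tuple[int, int], list[str]] = {}

    def gen_size(b: int, g: int) -> int:
        n_final = config.breed_sizes[b]
        n0 = (
            config.n_founders_per_breed
            if config.n_founders_per_breed is not None
            else max(8, int(round(2.5 * n_final)))
        )
        if n0 <= 0:
            raise ValueError("infeasible config: zero founders")
        # linear shrink from founders to the final cohort
        return max(4, int(round(n0 + (n_final - n0) * g / G)))

    def birth(g: int) -> date:
        y = (
            config.first_birth_year
            + g * config.years_per_generation
            + int(rng.integers(0, 4))
        )
        return date(y, 1, 1) + timedelta(days=int(rng.integers(0, 365)))

    for b in range(config.n_breeds):
        breed = config.breed_names[b]
        n0 = gen_size(b, 0)
        ms, fs = [], []
        for i in range(n0):
            aid = f"{breed}_G0_{i:05d}"
            sex = "M" if rng.random() < 0.4 else "F"
            records.append((aid, "0", "0", birth(0), sex, breed))
            generations[aid] = 0
            (ms if sex == "M" else fs).append(aid)
        males[(b, 0)], females[(b, 0)] = ms, fs

    for g in range(1, G + 1):
        final = g == G
        for b in range(config.n_breeds):
            breed = config.breed_names[b]
            n_off = gen_size(b, g)
            # sire pool: own breed, plus shared sires from other breeds
            pool = list(males[(b, g - 1)])
            if config.sire_sharing_rate > 0 and config.n_breeds > 1:
                for b2 in range(config.n_breeds):
                    if b2 == b:
                        continue
                    other = males[(b2, g - 1)]
                    share = [
                        s for s in other if rng.random() < config.sire_sharing_rate
                    ]
                    pool.extend(share)
            if not pool or not females[(b, g - 1)]:
                raise ValueError(
                    f"infeasible config: no parents for breed {breed} gen {g}"
                )
            fam = _family_sizes(rng, n_off)
            sires_used = rng.choice(
                len(pool), size=len(fam), replace=len(fam) > len(pool)
            )
            sire_per_off = np.repeat(
                [pool[i] for i in sires_used], fam
            )
            # dams: reuse at most 3 times, mostly once
            dam_pool = list(females[(b, g - 1)])
            if n_off > 3 * len(dam_pool):
                raise ValueError(
                    f"infeasible config: breed {breed} generation {g} needs "
                    f"{n_off} offspring but {len(dam_pool)} dams allow at most "
                    f"{3 * len(dam_pool)}"
                )
            rng.shuffle(dam_pool)
            # cycle through the shuffled pool: every dam used once before any
            # second use, so most dams have a single offspring
            dams = [dam_pool[i % len(dam_pool)] for i in range(n_off)]
            ms, fs = [], []
            for i in range(n_off):
                aid = f"{breed}_G{g}_{i:05d}"
                sex = "F" if final else ("M" if rng.random() < 0.4 else "F")
                records.append(
                    (aid, sire_per_off[i], dams[i], birth(g), sex, breed)
                )
                generations[aid] = g
                (ms if sex == "M" else fs).append(aid)
            males[(b, g)], females[(b, g)] = ms, fs

    return Pedigree.from_records(records, generations=generations)


# ---------------------------------------------------------------------------
# Genotype simulation (gene dropping)
# ---------------------------------------------------------------------------


def _marker_map(config: SimConfig) -> pd.DataFrame:
    m = config.markers_per_chrom
    chrom_bp = 120_000_000  # nominal physical span per autosome
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        bp = np.linspace(chrom_bp / m, chrom_bp, m).astype(np.int64)
        for j in range(m):
            rows.append((f"SNP{c}_{j + 1:05d}", c, int(bp[j]), "A", "B"))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "bp", "alleleA", "alleleB"]
    )


def qtl_marker_indices(config: SimConfig, markers: pd.DataFrame) -> np.ndarray:
    """Indices of the markers acting as QTLs (nearest marker to each spec)."""
    out = []
    chrom = markers["chrom"].to_numpy()
    bp = markers["bp"].to_numpy()
    for c, pos, _frac in config.qtl_spec:
        on = np.nonzero(chrom == c)[0]
        if len(on) == 0:
            raise ValueError(f"QTL chromosome {c} outside the simulated map")
        if not (0 < pos <= bp[on].max() * 1.05):
            raise ValueError(
                f"QTL position {c}:{pos} outside the simulated map"
            )
        out.append(int(on[np.argmin(np.abs(bp[on] - pos))]))
    return np.asarray(out, dtype=np.int64)


def _gamete(
    rng: np.random.Generator,
    hap: np.ndarray,  # (2, M) parent haplotypes
    chrom_starts: np.ndarray,
    gpos: np.ndarray,  # genetic position (Morgan) per marker, per chromosome
    chrom_len: float,
) -> np.ndarray:
    """One recombinant gamete: Poisson crossovers on each chromosome."""
    choose = np.empty(hap.shape[1], dtype=np.int64)
    for k in range(len(chrom_starts) - 1):
        a, b = chrom_starts[k], chrom_starts[k + 1]
        n_x = rng.poisson(chrom_len)
        start = rng.integers(0, 2)
        if n_x == 0:
            choose[a:b] = start
        else:
            xp = np.sort(rng.uniform(0, chrom_len, size=n_x))
            seg = np.searchsorted(xp, gpos[a:b], side="right")
            choose[a:b] = (start + seg) % 2
    return hap[choose, np.arange(hap.shape[1])]


def simulate_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    animals: list[str] | None = None,
    _return_haplotypes: bool = False,
):
    """Gene-drop genotypes down the pedigree.

    Founder haplotypes come from breed-specific allele frequencies
    (Balding-Nichols with Fst ``founder_freq_divergence`` around a common
    ancestral frequency); descendants inherit recombinant gametes.  QTL
    markers are forced polymorphic in every breed.  Missing calls are
    planted at ``missing_rate`` (never at QTL markers' truth is preserved
    through the phenotype stage, which receives the pre-masking calls).

    Returns the :class:`GenotypeMatrix` for ``animals`` (default: all
    pedigree animals).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    markers = _marker_map(config)
    M = len(markers)
    qtl_idx = qtl_marker_indices(config, markers)

    # ancestral + breed frequencies
    p_anc = rng.uniform(0.05, 0.95, size=M)
    F = config.founder_freq_divergence
    breeds = sorted(set(pedigree.breed))
    p_breed: dict[str, np.ndarray] = {}
    for b in breeds:
        if F > 0:
            a = p_anc * (1 - F) / F
            bb = (1 - p_anc) * (1 - F) / F
            p = rng.beta(a, bb)
        else:
            p = p_anc.copy()
        p[qtl_idx] = np.clip(p[qtl_idx], 0.25, 0.75)  # keep QTLs segregating
        p_breed[b] = p

    chrom = markers["chrom"].to_numpy()
    chrom_starts = np.concatenate(
        [
            np.searchsorted(chrom, np.arange(1, config.n_chromosomes + 1)),
            [M],
        ]
    )
    bp = markers["bp"].to_numpy().astype(np.float64)
    gpos = np.empty(M)
    for k in range(config.n_chromosomes):
        a, b = chrom_starts[k], chrom_starts[k + 1]
        span = bp[a:b].max()
        gpos[a:b] = bp[a:b] / span * config.chrom_length_morgans

    n = len(pedigree)
    hap = np.empty((n, 2, M), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for h, parent in enumerate((s, d)):
            if parent < 0:
                p = p_breed[pedigree.breed[i]]
                hap[i, h] = rng.random(M) < p
            else:
                hap[i, h] = _gamete(
                    rng,
                    hap[parent],
                    chrom_starts,
                    gpos,
                    config.chrom_length_morgans,
                )

    calls = hap.sum(axis=1, dtype=np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, MISSING_CALL, calls)
    if animals is not None:
        idx = pedigree.indices_of(animals)
        g = GenotypeMatrix(list(animals), markers, calls[idx])
    else:
        g = GenotypeMatrix(list(pedigree.ids), markers, calls)
    if _return_haplotypes:
        return g, hap
    return g


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def polygenic_values(
    pedigree: Pedigree, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive polygenic values down the pedigree.

    Founders ~ N(0, variance); offspring = parent average + Mendelian
    sampling with variance ``variance/2`` (one known parent: 3/4; none:
    full).  Inbreeding is ignored in the Mendelian-sampling variance — the
    simulated pedigrees are founder-rich and shallow, so F is negligible.
    """
    n = len(pedigree)
    a = np.empty(n)
    sd_full = np.sqrt(variance)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s < 0 and d < 0:
            a[i] = rng.normal(0.0, sd_full)
        elif s >= 0 and d >= 0:
            a[i] = 0.5 * (a[s] + a[d]) + rng.normal(0.0, np.sqrt(variance / 2))
        else:
            p = s if s >= 0 else d
            a[i] = 0.5 * a[p] + rng.normal(0.0, np.sqrt(0.75 * variance))
    return a


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    animals: list[str] | None = None,
) -> PhenotypeTable:
    """Withers heights for the phenotyped cohort.

    ``height = mean + age-class effect + QTL effects + polygenic + env``.
    Each QTL's additive effect is scaled so that it contributes its
    configured fraction of the total phenotypic variance given its allele
    frequency in the phenotyped cohort; the polygenic variance is
    ``h2_polygenic * total`` and the environmental SD fills the remainder.
    Ages at measurement are drawn so that all five age classes occur.

    Default cohort: final-generation females (the genotyped-mare design).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    if animals is None:
        animals = pedigree.leaf_females()
    if not animals:
        raise ValueError("no animals to phenotype")
    missing_geno = set(animals) - set(genotypes.animal_ids)
    if missing_geno:
        raise ValueError(
            f"genotypes do not cover phenotyped animals: {sorted(missing_geno)[:5]}"
        )
    V = config.total_variance
    g_idx = [genotypes._index[a] for a in animals]
    qtl_idx = qtl_marker_indices(config, genotypes.markers)
    n = len(animals)

    qtl_part = np.zeros(n)
    for (c, pos, frac), j in zip(config.qtl_spec, qtl_idx):
        calls = genotypes.calls[g_idx, j].astype(np.float64)
        obs = calls >= 0
        p = calls[obs].sum() / (2 * obs.sum())
        if p <= 0 or p >= 1:
            raise ValueError(f"QTL marker {c}:{pos} monomorphic in cohort")
        dose = np.where(obs, calls, 2 * p)  # mean-impute planted missing
        # scale by the realised dose variance so the QTL contributes its
        # configured share exactly in this cohort (family structure and
        # HWE deviations make 2p(1-p) only an approximation)
        v_dose = dose.var()
        beta = np.sqrt(frac * V / v_dose) * rng.choice((-1.0, 1.0))
        qtl_part += beta * (dose - dose.mean())

    # joint rescale: linkage between causal loci adds random covariance
    # terms, so pin the realised total QTL variance to its configured share
    total_qtl_frac = sum(q[2] for q in config.qtl_spec)
    if total_qtl_frac > 0 and qtl_part.var() > 0:
        qtl_part *= np.sqrt(total_qtl_frac * V / qtl_part.var())

    poly = polygenic_values(pedigree, config.h2_polygenic * V, rng)[
        pedigree.indices_of(animals)
    ]
    env = rng.normal(0.0, config.sd_env, size=n)

    # ages: guarantee every class occurs, then multinomial for the rest
    class_probs = np.array([0.25, 0.20, 0.20, 0.15, 0.20])
    cls = np.concatenate(
        [np.arange(1, 6), rng.choice(5, size=max(0, n - 5), p=class_probs) + 1]
    )[:n]
    rng.shuffle(cls)
    # keep a small margin inside each bin so day-rounding cannot cross it
    lo = np.array([1.0, 3.05, 4.05, 5.05, 6.05])[cls - 1]
    hi = np.array([2.95, 3.95, 4.95, 5.95, 12.0])[cls - 1]
    ages = rng.uniform(lo, hi)

    effects = np.asarray(config.age_class_effects)[cls - 1]
    height = config.mean_height + effects + qtl_part + poly + env

    ped_idx = pedigree.indices_of(animals)
    meas_dates = [
        pedigree.birth_date[i] + timedelta(days=int(round(a * 365.25)))
        for i, a in zip(ped_idx, ages)
    ]
    # recompute exact fractional age from the realised dates
    exact_age = np.array(
        [
            (md - pedigree.birth_date[i]).days / 365.25
            for i, md in zip(ped_idx, meas_dates)
        ]
    )
    source = np.where(rng.random(n) < 0.94, "SBR", "MPT")
    df = pd.DataFrame(
        {
            "animal_id": animals,
            "height": height,
            "measurement_date": meas_dates,
            "source": source,
            "age": exact_age,
            "age_class": [age_class(a) for a in exact_age],
        }
    )
    return PhenotypeTable(df)
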