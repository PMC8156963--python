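"""Synthetic screens, segregant pools and annotations.

The generators emulate the three data layers the pipeline consumes:

* replicated log-normal colony sizes with planted suppression effects
  (:func:`simulate_screen`),
* pooled-segregant sequencing of a haploid cross with Haldane-map
  recombination, selection at planted suppressor loci, and binomial read
  sampling (:func:`simulate_pool`),
* random functional annotation sets with planted concordant groups
  (:func:`simulate_annotations`).

Closed-form Mendelian expectations for rearrangement crosses
(:func:`mendelian_expectations`) and the strong-modifier-count estimate from
random-spore viability (:func:`estimate_modifier_count`) support the screen's
positive-control genetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AlleleCountTable, AnnotationSet, ScreenTable, SCREEN_COLUMNS

# ---------------------------------------------------------------------------
# Genetic map and cross design
# ---------------------------------------------------------------------------


@dataclass
class Chromosome:
    name: str
    length_bp: int


@dataclass
class GeneticMap:
    """Marker grid and uniform recombination rate for the simulated cross.

    ``recombination_rate`` is in Morgans per bp; the default 4e-6 M/bp
    (0.4 cM/kb) is the yeast genome-wide average.
    """

    chromosomes: list[Chromosome]
    recombination_rate: float = 4e-6
    marker_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.recombination_rate <= 0:
            raise ValueError("recombination rate must be positive")
        for c in self.chromosomes:
            if c.length_bp <= 0:
                raise ValueError(f"chromosome {c.name} has non-positive length")
            pos = np.asarray(self.marker_positions.get(c.name, ()), dtype=int)
            if pos.size and (pos.min() < 1 or pos.max() > c.length_bp):
                raise ValueError(f"markers outside {c.name} bounds")
            self.marker_positions[c.name] = pos

    @classmethod
    def default(cls, n_chromosomes: int = 3, length_bp: int = 1_000_000,
                marker_spacing: int = 5_000,
                recombination_rate: float = 4e-6) -> "GeneticMap":
        """Desk-scale genome: 3 chromosomes x 1 Mb, one marker per 5 kb."""
        chroms = [Chromosome(f"chr{i + 1}", length_bp) for i in range(n_chromosomes)]
        markers = {c.name: np.arange(marker_spacing, length_bp + 1, marker_spacing)
                   for c in chroms}
        return cls(chroms, recombination_rate, markers)


@dataclass
class Locus:
    chrom: str
    pos: int


@dataclass
class SuppressorLocus(Locus):
    effect_model: str = "any_sufficient"  # or "all_required"
    fitness_advantage: float = 1.0


@dataclass
class CrossDesign:
    """One TS-allele x wild-strain cross feeding a segregant pool.

    All segregants carry the reference allele at ``ts_locus`` and every
    ``marker_loci`` entry (selection in the crossing protocol). At the
    restrictive temperature, segregants whose suppressor genotype satisfies
    the effect model expand with relative weight
    exp(fitness_advantage * selection_generations).
    """

    suppressor_loci: list[SuppressorLocus] = field(default_factory=list)
    ts_locus: Locus = field(default_factory=lambda: Locus("chr1", 500_000))
    marker_loci: list[Locus] = field(default_factory=list)
    pool_size: int = 60_000
    read_depth: float = 100.0
    rearrangement: str | None = None
    selection_generations: float = 1.0
    cross_id: str = "cross"

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for s in self.suppressor_loci:
            if s.chrom == self.ts_locus.chrom and s.pos == self.ts_locus.pos:
                raise ValueError("suppressor locus coincident with ts_locus "
                                 "(confounded design)")


# ---------------------------------------------------------------------------
# Colony-size screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimParams:
    """Generative model of the replicated colony-size screen.

    log2 colony size = baseline + strain effect + query effect
    − ts_effect·[restrictive] + suppression·[restrictive, planted pair]
    + plate effect + biological noise + technical noise; sizes are
    exponentiated to a pixel scale and dropped at ``missing_rate``.
    Strain ``REF`` is the reference (same-background) cross.
    """

    n_queries: int = 100
    n_strains: int = 2
    n_bioreps: int = 2
    n_techreps: int = 4
    ts_effect: float = 2.0
    suppression_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    technical_sd: float = 0.25
    biological_sd: float = 0.1
    missing_rate: float = 0.02
    baseline_log2: float = 10.0
    query_sd: float = 0.5
    strain_sd: float = 0.2
    insensitive_queries: frozenset[str] = frozenset()
    insensitive_fraction: float = 0.2
    plate_effects: dict[int, float] = field(default_factory=dict)
    queries_per_plate: int = 96

    def __post_init__(self) -> None:
        if self.technical_sd < 0 or self.biological_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")

    @property
    def query_ids(self) -> list[str]:
        return [f"q{i:04d}" for i in range(self.n_queries)]

    @property
    def strain_ids(self) -> list[str]:
        return ["REF"] + [f"W{i:02d}" for i in range(1, self.n_strains + 1)]


def simulate_screen(params: ScreenSimParams, seed: int) -> ScreenTable:
    """Generate a replicated colony-size table; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    queries = params.query_ids
    strains = params.strain_ids
    query_eff = rng.normal(0.0, params.query_sd, size=len(queries))
    strain_eff = rng.normal(0.0, params.strain_sd, size=len(strains))
    strain_eff[0] = 0.0  # reference defines the scale
    insensitive_set = set(params.insensitive_queries)
    if not insensitive_set and params.insensitive_fraction > 0:
        n_ins = int(round(params.insensitive_fraction * len(queries)))
        insensitive_set = set(
            rng.choice(queries, size=n_ins, replace=False).tolist())

    rows = []
    for qi, query in enumerate(queries):
        plate = qi // params.queries_per_plate
        row_pos, col_pos = divmod(qi % params.queries_per_plate, 12)
        insensitive = query in insensitive_set
        for si, strain in enumerate(strains):
            supp = params.suppression_effects.get((query, strain), 0.0)
            for temp in ("permissive", "restrictive"):
                drop = 0.0
                if temp == "restrictive" and not insensitive:
                    drop = params.ts_effect - (supp if strain != "REF" else 0.0)
                base = (params.baseline_log2 + query_eff[qi] + strain_eff[si] - drop
                        + math.log2(params.plate_effects.get(plate, 1.0)))
                for biorep in range(1, params.n_bioreps + 1):
                    bio_noise = rng.normal(0.0, params.biological_sd)
                    tech_noise = rng.normal(0.0, params.technical_sd,
                                            size=params.n_techreps)
                    for techrep in range(1, params.n_techreps + 1):
                        log2size = base + bio_noise + tech_noise[techrep - 1]
                        size: float = 2.0 ** log2size
                        if params.missing_rate and rng.random() < params.missing_rate:
                            size = np.nan
                        rows.append((query, query.upper(), strain, temp, biorep,
                                     techrep, plate, row_pos, col_pos, size))
    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    return ScreenTable(df)


# ---------------------------------------------------------------------------
# Segregant pools
# ---------------------------------------------------------------------------


def _haldane_prob(distance_bp: np.ndarray, rate: float) -> np.ndarray:
    """Crossover probability between adjacent sites: (1 − e^{−2d})/2,
    d in Morgans. Poisson crossovers without interference."""
    d = distance_bp * rate
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _simulate_chromosome(n: int, positions: np.ndarray, rate: float,
                         condition_ref: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw n haplotypes (0=reference, 1=wild) at ``positions``, conditioned
    on allele 0 at the site indices in ``condition_ref`` (rejection sampling).
    """
    m = len(positions)
    if m == 0:
        return np.zeros((n, 0), dtype=np.int8)
    switch_p = _haldane_prob(np.diff(positions).astype(float), rate)
    out = np.empty((n, m), dtype=np.int8)
    filled = 0
    while filled < n:
        batch = max(n - filled, 1)
        if condition_ref.size:
            batch = int(batch * 2 ** condition_ref.size * 1.2) + 16
        haplo = np.empty((batch, m), dtype=bool)
        haplo[:, 0] = rng.integers(0, 2, size=batch, dtype=bool)
        np.less(rng.random((batch, m - 1), dtype=np.float32),
                switch_p.astype(np.float32), out=haplo[:, 1:])
        np.bitwise_xor.accumulate(haplo, axis=1, out=haplo)
        if condition_ref.size:
            keep = ~haplo[:, condition_ref].any(axis=1)
            haplo = haplo[keep]
        take = min(len(haplo), n - filled)
        out[filled:filled + take] = haplo[:take]
        filled += take
    return out


def simulate_pool(gmap: GeneticMap, design: CrossDesign, seed: int,
                  n_replicates: int = 2) -> AlleleCountTable:
    """Simulate pooled-segregant sequencing of one cross.

    Each biological replicate is an independent pool of ``design.pool_size``
    recombinant haploid genomes, all carrying the reference allele at the TS
    locus and SGA marker loci. The permissive-temperature sample reads the
    pool as is; the restrictive-temperature sample reads the pool after one
    round of weighted multinomial resampling in which segregants satisfying
    the suppressor effect model carry weight
    exp(fitness_advantage x selection_generations). Per-site read depth is
    Poisson(read_depth) and alt reads are Binomial(depth, pool wild-allele
    frequency). A ``disomy(chrom)`` rearrangement doubles the read-sampling
    rate on that chromosome (the pool is disomic for it).
    """
    rng = np.random.default_rng(seed)
    # conditioning sites per chromosome: TS locus + selection markers,
    # inserted into the marker grid so selection is exact at those sites
    condition: dict[str, list[int]] = {}
    for locus in [design.ts_locus, *design.marker_loci]:
        condition.setdefault(locus.chrom, []).append(locus.pos)
    positions: dict[str, np.ndarray] = {}
    cond_idx: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        pos = np.union1d(gmap.marker_positions[chrom.name],
                         np.array(condition.get(chrom.name, []), dtype=int))
        positions[chrom.name] = pos
        cond = np.array(condition.get(chrom.name, []), dtype=int)
        cond_idx[chrom.name] = np.searchsorted(pos, cond)
    sup_idx = [(s.chrom, int(np.searchsorted(positions[s.chrom], s.pos)), s)
               for s in design.suppressor_loci]

    disomic_chrom = None
    if design.rearrangement and design.rearrangement.startswith("disomy"):
        disomic_chrom = design.rearrangement.split("(", 1)[1].rstrip(")")

    rows = []
    for rep in range(1, n_replicates + 1):
        haplos = {c.name: _simulate_chromosome(
            design.pool_size, positions[c.name], gmap.recombination_rate,
            cond_idx[c.name], rng) for c in gmap.chromosomes}
        # selection weights from suppressor genotypes (1 = wild allele)
        if sup_idx:
            genos = np.stack([haplos[ch][:, i] for ch, i, _ in sup_idx]).astype(bool)
            models = {s.effect_model for _, _, s in sup_idx}
            if models == {"all_required"}:
                satisfied = genos.all(axis=0)
            else:  # any one suppressor allele suffices
                satisfied = genos.any(axis=0)
            advantage = max(s.fitness_advantage for _, _, s in sup_idx)
            weights = np.where(satisfied,
                               math.exp(advantage * design.selection_generations),
                               1.0)
        else:
            weights = np.ones(design.pool_size)

        for temperature in ("permissive", "restrictive"):
            if temperature == "restrictive" and sup_idx:
                # one round of weighted multinomial resampling of the pool
                p = weights / weights.sum()
                copies = rng.multinomial(design.pool_size, p).astype(float)
            else:
                copies = None
            sample_id = f"{design.cross_id}_{temperature}_r{rep}"
            for chrom in gmap.chromosomes:
                h = haplos[chrom.name]
                if copies is None:
                    freqs = h.mean(axis=0)
                else:
                    freqs = (copies @ h) / design.pool_size
                depth_rate = design.read_depth
                if disomic_chrom == chrom.name:
                    depth_rate *= 2.0
                depths = rng.poisson(depth_rate, size=freqs.size)
                alts = rng.binomial(depths, freqs)
                pos = positions[chrom.name]
                for j in range(freqs.size):
                    rows.append((sample_id, chrom.name, int(pos[j]),
                                 int(depths[j] - alts[j]), int(alts[j])))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                     "ref_count", "alt_count"])
    metadata = {}
    for rep in range(1, n_replicates + 1):
        for temperature in ("permissive", "restrictive"):
            metadata[f"{design.cross_id}_{temperature}_r{rep}"] = {
                "cross_id": design.cross_id, "temperature": temperature,
                "replicate": rep}
    return AlleleCountTable(df, metadata)


def expected_selected_frequency(fitness_advantage: float,
                                selection_generations: float = 1.0) -> float:
    """Deterministic post-selection wild-allele frequency at an unlinked
    suppressor locus starting from 0.5: w·0.5 / (w·0.5 + 0.5)."""
    w = math.exp(fitness_advantage * selection_generations)
    return 0.5 * w / (0.5 * w + 0.5)


# ---------------------------------------------------------------------------
# Mendelian cross models
# ---------------------------------------------------------------------------


@dataclass
class SegregationModel:
    kind: str  # "translocation_heterozygote" | "trisomic"


def mendelian_expectations(model: SegregationModel | str) -> dict[str, float]:
    """Expected progeny classes for the screen's rearrangement crosses.

    ``translocation_heterozygote``: a cross of the reference strain to a
    strain carrying a reciprocal translocation between two chromosomes. The
    two rearranged/normal centromere pairs segregate independently, so of the
    four equally likely gamete combinations one lacks an essential
    chromosome-arm complement (inviable, 1/4); the three viable classes —
    parental reference arrangement, parental translocated arrangement, and
    the combination carrying a duplicated arm segment — are each 1/3 of
    viable spores.

    ``trisomic``: a haploid parent disomic for one chromosome gives a
    trisomic hybrid; random 2:1 segregation of the three homologs sends one
    or two copies to a spore with equal probability.
    """
    kind = model.kind if isinstance(model, SegregationModel) else model
    if kind == "translocation_heterozygote":
        return {
            "inviable": 0.25,
            "viable": 0.75,
            "parental_reference_among_viable": 1.0 / 3.0,
            "parental_translocated_among_viable": 1.0 / 3.0,
            "duplication_among_viable": 1.0 / 3.0,
        }
    if kind == "trisomic":
        return {"one_copy": 0.5, "two_copies": 0.5}
    raise ValueError(f"unknown segregation model kind: {kind!r}")


def estimate_modifier_count(fraction_growing: float, n_spores: int | None = None,
                            k_max: int = 5) -> dict:
    """Estimate the number k of strong modifier variants from the fraction of
    random spores growing at the restrictive temperature.

    Under independent 1:1 segregation of k modifiers, the expected growing
    fraction is 1 − 2^−k when any single modifier suffices, and 2^−k when
    all are required. Returns the nearest k under each model, and (when the
    spore count is given) the set of k whose binomial 95% interval covers
    the observation.
    """
    if not 0.0 <= fraction_growing <= 1.0:
        raise ValueError("fraction_growing must be in [0, 1]")
    ks = np.arange(1, k_max + 1)
    exp_any = 1.0 - 2.0 ** (-ks)
    exp_all = 2.0 ** (-ks.astype(float))
    result = {
        "k_any": int(ks[np.argmin(np.abs(exp_any - fraction_growing))]),
        "k_all": int(ks[np.argmin(np.abs(exp_all - fraction_growing))]),
    }
    if n_spores is not None:
        grew = int(round(fraction_growing * n_spores))
        compatible_any, compatible_all = [], []
        for k, ea, el in zip(ks, exp_any, exp_all):
            lo_a, hi_a = stats.binom.interval(0.95, n_spores, ea)
            if lo_a <= grew <= hi_a:
                compatible_any.append(int(k))
            lo_l, hi_l = stats.binom.interval(0.95, n_spores, el)
            if lo_l <= grew <= hi_l:
                compatible_all.append(int(k))
        result["compatible_k_any"] = compatible_any
        result["compatible_k_all"] = compatible_all
    return result


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------


def simulate_annotations(n_genes: int, n_complexes: int,
                         planted_consistent: set[str] | None = None,
                         seed: int = 0, complex_size: tuple[int, int] = (3, 6),
                         n_pathways: int = 5, n_compartments: int = 6,
                         essential_fraction: float = 0.3) -> AnnotationSet:
    """Random gene-set memberships over a gene universe g0000..g{n-1}.

    Genes in ``planted_consistent`` are grouped into one extra complex
    (``planted``); give their alleles a shared strain profile via
    ``ScreenSimParams.suppression_effects`` to plant a concordant group.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:04d}" for i in range(n_genes)]
    planted = set(planted_consistent or ())
    unknown = planted - set(universe)
    universe.extend(sorted(unknown))

    def random_sets(prefix: str, count: int) -> dict[str, set[str]]:
        sets = {}
        for i in range(count):
            size = rng.integers(complex_size[0], complex_size[1] + 1)
            members = rng.choice(universe, size=min(size, len(universe)),
                                 replace=False)
            sets[f"{prefix}{i:03d}"] = set(members.tolist())
        return sets

    complexes = random_sets("cpx", n_complexes)
    if planted:
        complexes["planted"] = set(planted)
    pathways = random_sets("pwy", n_pathways)
    pairs = set()
    for _ in range(n_genes):
        a, b = rng.choice(universe, size=2, replace=False)
        pairs.add(frozenset((str(a), str(b))))
    localization = {g: {f"loc{int(rng.integers(n_compartments))}"}
                    for g in universe}
    essential = {g for g in universe if rng.random() < essential_fraction}
    return AnnotationSet(complexes=complexes, pathways=pathways,
                         coexpression_partners=pairs, localization=localization,
                         essential=essential)


def planted_profile_effects(genes: list[str], strains: list[str], seed: int,
                            alleles_per_gene: int = 2, effect: float = 1.5
                            ) -> dict[tuple[str, str], float]:
    """Suppression effects giving every allele of ``genes`` the same
    strain-response profile (a shared suppressing strain subset)."""
    rng = np.random.default_rng(seed)
    n_on = max(1, len(strains) // 2)
    on = set(rng.choice(strains, size=n_on, replace=False).tolist())
    effects = {}
    for gene in genes:
        for a in range(alleles_per_gene):
            allele = f"{gene}-ts{a + 1}"
            for strain in strains:
                if strain in on:
                    effects[(allele, strain)] = effect
    return effects
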