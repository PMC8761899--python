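"""Simulation of connected RIL populations and multi-environment trials.

The generator mirrors the design of a three-way connected-cross panel:
three fully homozygous parent cultivars, three biparental RIL populations
obtained by single-seed descent, GBS-like SNP matrices with structured
missingness, and plot phenotypes from randomized complete blocks in several
environments with genotype, genotype x environment (GEI) and residual
variance components under direct user control.

Meiosis uses Haldane's map function (no interference): the recombination
fraction between two markers separated by ``d`` centiMorgans is
``r = (1 - exp(-2 d / 100)) / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rilgs.matrix import GenotypeMatrix

# ---------------------------------------------------------------------------
# genome map and parents
# ---------------------------------------------------------------------------


@dataclass
class GenomeMap:
    """Genetic map: chromosome names/lengths and marker positions in cM."""

    chromosomes: list[tuple[str, float]]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("no markers")
        for name, length in self.chromosomes:
            pos = np.asarray(self.positions.get(name, ()), dtype=float)
            if pos.size == 0:
                raise ValueError("no markers")
            if (pos < 0).any() or (np.diff(pos) < 0).any() or pos.max() > length:
                raise ValueError(f"invalid marker positions on {name}")
            self.positions[name] = pos

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[name]) for name, _ in self.chromosomes)

    def marker_table(self) -> pd.DataFrame:
        """One row per marker: id, chrom, pos (bp-like integer, 1e4 x cM)."""
        rows = []
        for name, _ in self.chromosomes:
            for cm in self.positions[name]:
                bp = int(round(cm * 10_000)) + 1
                rows.append((f"{name}_{bp}", name, bp))
        return pd.DataFrame(rows, columns=["id", "chrom", "pos"])

    def chrom_slices(self) -> list[slice]:
        out, start = [], 0
        for name, _ in self.chromosomes:
            stop = start + len(self.positions[name])
            out.append(slice(start, stop))
            start = stop
        return out


def default_map(
    n_chromosomes: int = 7,
    length_cm: float = 100.0,
    markers_per_chromosome: int = 1000,
    seed: int | None = 0,
) -> GenomeMap:
    """Uniform-random marker placement on equally sized chromosomes.

    Defaults (7 x 100 cM, 1000 markers each) are an arbitrary but realistic
    stand-in for a legume genetic map and are fully configurable.
    """
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", length_cm) for i in range(n_chromosomes)]
    positions = {}
    for name, _ in chromosomes:
        pos = np.sort(rng.uniform(0.0, length_cm, size=markers_per_chromosome))
        positions[name] = pos
    return GenomeMap(chromosomes, positions)


@dataclass
class ParentSet:
    """Three fully homozygous parental genomes over a shared map."""

    genome_map: GenomeMap
    alleles: np.ndarray  # (3, n_markers) in {0, 1}

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (3, self.genome_map.n_markers):
            raise ValueError("parent alleles must be 3 x n_markers")

    def divergence(self, i: int, j: int) -> float:
        """Fraction of markers at which parents i and j carry different alleles."""
        return float(np.mean(self.alleles[i] != self.alleles[j]))


def simulate_parents(
    genome_map: GenomeMap,
    divergences: tuple[float, float, float],
    seed: int | None = None,
) -> ParentSet:
    """Draw three homozygous parents with requested pairwise divergences.

    ``divergences`` are the target marker-difference fractions for the pairs
    (1,2), (1,3) and (2,3). Parent 1 carries the reference allele everywhere;
    parent 2 differs from it at a Bernoulli(d12) subset; parent 3 alleles are
    drawn marker-wise so that both remaining pairwise fractions have the
    requested expectation (the three targets must satisfy the triangle-type
    constraints of binary sequences).
    """
    d12, d13, d23 = (float(d) for d in divergences)
    for d in (d12, d13, d23):
        if not 0.0 <= d <= 1.0:
            raise ValueError("divergences must lie in [0, 1]")
    m = genome_map.n_markers
    if m == 0:
        raise ValueError("no markers")
    rng = np.random.default_rng(seed)

    p1 = np.zeros(m, dtype=np.int8)
    p2 = (rng.random(m) < d12).astype(np.int8)

    # P(p3 != p1 | p2 == p1) = a and P(p3 != p1 | p2 != p1) = b solve the
    # two marginal constraints d13 and d23.
    if d12 in (0.0, 1.0):
        if d12 == 0.0:
            if abs(d13 - d23) > 1e-12:
                raise ValueError("identical parents 1,2 require d13 == d23")
            a, b = d13, 0.5
        else:
            if abs(d13 + d23 - 1.0) > 1e-12:
                raise ValueError("fully divergent parents 1,2 require d13 + d23 == 1")
            a, b = 0.5, d13
    else:
        b = (d13 - d23 + d12) / (2.0 * d12)
        a = (d13 + d23 - d12) / (2.0 * (1.0 - d12))
        if not (0.0 - 1e-12 <= a <= 1.0 + 1e-12 and 0.0 - 1e-12 <= b <= 1.0 + 1e-12):
            raise ValueError("divergence targets are jointly infeasible")
        a, b = float(np.clip(a, 0, 1)), float(np.clip(b, 0, 1))
    flip_prob = np.where(p2 == p1, a, b)
    p3 = np.where(rng.random(m) < flip_prob, 1 - p1, p1).astype(np.int8)
    return ParentSet(genome_map, np.stack([p1, p2, p3]))


# ---------------------------------------------------------------------------
# meiosis and RIL construction
# ---------------------------------------------------------------------------


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _gametes(haplotypes: np.ndarray, genome_map: GenomeMap, rng) -> np.ndarray:
    """One gamete per individual. ``haplotypes``: (n, 2, M) -> (n, M)."""
    n = haplotypes.shape[0]
    out = np.empty((n, haplotypes.shape[2]), dtype=haplotypes.dtype)
    for sl, (name, _) in zip(genome_map.chrom_slices(), genome_map.chromosomes):
        pos = genome_map.positions[name]
        L = len(pos)
        r = haldane_r(np.diff(pos))
        state = np.empty((n, L), dtype=np.int8)
        state[:, 0] = rng.random(n) < 0.5
        if L > 1:
            switches = rng.random((n, L - 1)) < r
            state[:, 1:] = switches
            np.cumsum(state, axis=1, out=state)  # int8 overflow-safe: mod 2 below
            state &= 1
        block = haplotypes[:, :, sl]
        out[:, sl] = np.where(state == 0, block[:, 0, :], block[:, 1, :])
    return out


def simulate_ril_population(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_lines: int,
    generations: int,
    genome_map: GenomeMap,
    seed: int | None = None,
    population: str = "pop",
    line_prefix: str | None = None,
) -> GenotypeMatrix:
    """RILs from a biparental cross by repeated selfing (single-seed descent).

    ``generations`` counts selfing meioses applied to the F1, so
    ``generations=1`` yields F2 genotypes and the expected residual
    heterozygosity per marker is ``0.5**generations``.
    """
    p1 = np.asarray(parent1, dtype=np.int8)
    p2 = np.asarray(parent2, dtype=np.int8)
    if p1.shape != (genome_map.n_markers,) or p2.shape != p1.shape:
        raise ValueError("parent allele vectors must match the map")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if np.array_equal(p1, p2):
        warnings.warn("monomorphic population: parents identical at all markers")
    rng = np.random.default_rng(seed)
    m = genome_map.n_markers
    # every line starts as the (identical) F1: one haplotype from each parent
    haps = np.empty((n_lines, 2, m), dtype=np.int8)
    haps[:, 0, :] = p1
    haps[:, 1, :] = p2
    for _ in range(generations):
        g1 = _gametes(haps, genome_map, rng)
        g2 = _gametes(haps, genome_map, rng)
        haps = np.stack([g1, g2], axis=1)
    values = haps.sum(axis=1).astype(float)
    prefix = line_prefix if line_prefix is not None else population
    line_ids = np.array([f"{prefix}_{i + 1:04d}" for i in range(n_lines)])
    return GenotypeMatrix(
        values, line_ids, np.full(n_lines, population), genome_map.marker_table()
    )


def concat_populations(mats: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack populations genotyped on the same marker set."""
    first = mats[0]
    for m in mats[1:]:
        if not first.markers["id"].equals(m.markers["id"]):
            raise ValueError("populations must share the same marker set")
    return GenotypeMatrix(
        np.vstack([m.values for m in mats]),
        np.concatenate([m.line_ids for m in mats]),
        np.concatenate([m.populations for m in mats]),
        first.markers,
    )


# ---------------------------------------------------------------------------
# trait architecture and genetic values
# ---------------------------------------------------------------------------


@dataclass
class TraitSpec:
    """Targets for one simulated trait (units of the trait itself)."""

    mean: float
    s_g2: float
    s_ge2: float
    s_e2: float
    env_effects: np.ndarray | None = None  # fixed deviations, one per environment

    def __post_init__(self) -> None:
        for v in (self.s_g2, self.s_ge2, self.s_e2):
            if v < 0:
                raise ValueError("variance targets must be >= 0")


@dataclass
class TraitArchitecture:
    """Bivariate architecture for a yield-like and a protein-like trait.

    Protein yield is never parameterized here: it is derived per plot as
    yield x protein/100 by :func:`simulate_trial`.
    """

    traits: dict[str, TraitSpec]
    n_causal: int = 100
    genetic_corr: float = 0.15
    block_effects: np.ndarray | None = None  # fixed, one per block

    def __post_init__(self) -> None:
        if not -1.0 <= self.genetic_corr <= 1.0:
            raise ValueError("genetic correlation target must lie in [-1, 1]")
        if "protein_yield" in self.traits:
            raise ValueError("protein yield is derived, not independently parameterized")


def default_architecture(n_env: int = 3) -> TraitArchitecture:
    """Study-like defaults for a pea-type panel in three environments.

    Genotypic and GEI components: yield 0.575 / 1.435 (GEI-dominated),
    protein content 0.724 / 0.302 (genetics-dominated). Residual variances
    (0.472 and 0.524) are calibrated so that the multi-environment
    genotype-mean heritability with e=3 environments and n=3 blocks comes
    out near 0.52 (yield) and 0.82 (protein content). Environment fixed
    effects echo the observed spread of environment means; the genetic
    correlation between the traits is slightly positive (0.15).
    """
    env_yield = np.array([1.71, -0.01, -1.70])[:n_env]
    env_prot = np.array([1.05, -1.05, -0.01])[:n_env]
    return TraitArchitecture(
        traits={
            "yield": TraitSpec(4.60, 0.575, 1.435, 0.472, env_yield),
            "protein": TraitSpec(24.27, 0.724, 0.302, 0.524, env_prot),
        },
        n_causal=100,
        genetic_corr=0.15,
    )


@dataclass
class TraitValues:
    """True per-line genetic values and GEI deviations for each trait."""

    line_ids: np.ndarray
    populations: np.ndarray
    genetic: dict[str, np.ndarray]  # trait -> (n_lines,)
    gei: dict[str, np.ndarray]  # trait -> (n_lines, n_env)
    causal_markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_env(self) -> int:
        first = next(iter(self.gei.values()))
        return first.shape[1]

    def total(self, trait: str) -> np.ndarray:
        """Genetic value per line and environment: main effect + GEI deviation."""
        return self.genetic[trait][:, None] + self.gei[trait]


def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so that var(x, ddof=1) equals the target exactly."""
    x = x - x.mean()
    v = x.var(ddof=1)
    if target_var == 0.0 or v == 0.0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def assign_trait_values(
    G: GenotypeMatrix,
    arch: TraitArchitecture,
    n_env: int = 3,
    seed: int | None = None,
) -> TraitValues:
    """Draw causal effects and GEI deviations hitting the targets exactly.

    Additive genetic values are sums over shared causal loci with effect
    sizes drawn from a bivariate normal whose correlation is the
    between-trait target; values are then centered and rescaled so the
    realized line-value variance equals the target genotypic variance
    exactly (finite-sample standardization). GEI deviations are iid normal
    per line x environment (unrestricted compound-symmetry structure, the
    estimand of REML with an iid genotype-x-environment random effect),
    rescaled by one factor so the realized interaction mean square --
    the sum of squared double-centered deviations over (n-1)(e-1) --
    equals the target exactly.
    """
    if np.isnan(G.values).any():
        raise ValueError("genotype matrix must be complete (pre-missingness)")
    rng = np.random.default_rng(seed)
    poly = np.flatnonzero(G.values.std(axis=0) > 0)
    if arch.n_causal > poly.size:
        raise ValueError(
            f"more causal loci ({arch.n_causal}) than polymorphic markers ({poly.size})"
        )
    causal = np.sort(rng.choice(poly, size=arch.n_causal, replace=False))
    X = G.values[:, causal]
    names = list(arch.traits)
    rho = arch.genetic_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    if len(names) == 1:
        effects = rng.standard_normal((arch.n_causal, 1))
    else:
        effects = rng.multivariate_normal(np.zeros(2), cov, size=arch.n_causal)
    genetic, gei = {}, {}
    n = G.n_lines
    # GEI deviations share the between-trait correlation so that the
    # per-environment (total) genetic correlation stays near the target
    if len(names) == 1:
        gei_draws = rng.standard_normal((n, n_env, 1))
    else:
        gei_draws = rng.multivariate_normal(
            np.zeros(2), cov, size=(n, n_env)
        )
    for t, name in enumerate(names):
        spec = arch.traits[name]
        raw = X @ effects[:, min(t, effects.shape[1] - 1)]
        if abs(rho) == 1.0 and t == 1:
            raw = np.sign(rho) * (X @ effects[:, 0])
        genetic[name] = _standardize(raw, spec.s_g2)
        dev = gei_draws[..., min(t, gei_draws.shape[2] - 1)]
        dc = dev - dev.mean(axis=1, keepdims=True)
        dc -= dc.mean(axis=0, keepdims=True)
        ss = (dc**2).sum()
        if spec.s_ge2 == 0.0 or ss == 0.0:
            dev = np.zeros_like(dev)
        else:
            df = (n - 1) * (n_env - 1)
            dev *= np.sqrt(spec.s_ge2 * df / ss)
        gei[name] = dev
    return TraitValues(G.line_ids, G.populations, genetic, gei, causal)


# ---------------------------------------------------------------------------
# field trial
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Panel and trial dimensions of the simulated study design."""

    population_sizes: tuple[int, int, int] = (102, 100, 104)
    generations: int = 6
    n_blocks: int = 3
    n_env: int = 3
    divergences: tuple[float, float, float] = (0.25, 0.35, 0.35)
    marker_missing_rate: float = 0.0
    sample_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.population_sizes):
            raise ValueError("population sizes must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_blocks < 2 or self.n_env < 2:
            raise ValueError("need >= 2 blocks and >= 2 environments")


ENV_NAMES = ("env1", "env2", "env3", "env4", "env5", "env6")


def simulate_trial(
    values: TraitValues,
    arch: TraitArchitecture,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Plot-level phenotypes from randomized complete blocks in each environment.

    Plot value = trait mean + environment effect + block effect + genetic
    value + GEI deviation + iid error. Protein yield is computed per plot
    as yield x protein/100, never simulated independently.
    """
    rng = np.random.default_rng(seed)
    n = len(values.line_ids)
    e, b = config.n_env, config.n_blocks
    envs = ENV_NAMES[:e]
    blocks = arch.block_effects
    if blocks is None:
        blocks = np.zeros(b)
    plot = {}
    for name, spec in arch.traits.items():
        env_eff = spec.env_effects
        if env_eff is None:
            env_eff = np.zeros(e)
        g = values.total(name)  # (n, e)
        err = rng.normal(0.0, np.sqrt(spec.s_e2), size=(n, e, b))
        plot[name] = (
            spec.mean
            + env_eff[None, :, None]
            + blocks[None, None, :]
            + g[:, :, None]
            + err
        )
    records = []
    line_idx = np.repeat(np.arange(n), e * b)
    env_idx = np.tile(np.repeat(np.arange(e), b), n)
    blk_idx = np.tile(np.arange(b), n * e)
    frames = []
    for name in arch.traits:
        frames.append(
            pd.DataFrame(
                {
                    "line": values.line_ids[line_idx],
                    "population": values.populations[line_idx],
                    "environment": np.asarray(envs)[env_idx],
                    "block": blk_idx + 1,
                    "trait": name,
                    "value": plot[name][line_idx, env_idx, blk_idx],
                }
            )
        )
    if {"yield", "protein"} <= set(arch.traits):
        py = plot["yield"] * plot["protein"] / 100.0
        frames.append(
            pd.DataFrame(
                {
                    "line": values.line_ids[line_idx],
                    "population": values.populations[line_idx],
                    "environment": np.asarray(envs)[env_idx],
                    "block": blk_idx + 1,
                    "trait": "protein_yield",
                    "value": py[line_idx, env_idx, blk_idx],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return records


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def add_missingness(
    G: GenotypeMatrix,
    marker_rates: float | np.ndarray = 0.0,
    sample_rates: float | np.ndarray = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Mask entries with marker- and sample-specific missingness.

    Entry (i, j) is masked with probability 1 - (1 - mpm_j)(1 - mps_i), so
    with one profile at zero the realized marginal rates match the other
    profile up to binomial sampling error. Observed entries are unchanged.
    """
    mpm = np.broadcast_to(np.asarray(marker_rates, dtype=float), (G.n_markers,))
    mps = np.broadcast_to(np.asarray(sample_rates, dtype=float), (G.n_lines,))
    if (mpm < 0).any() or (mpm > 1).any() or (mps < 0).any() or (mps > 1).any():
        raise ValueError("missingness rates must lie in [0, 1]")
    prob = 1.0 - np.outer(1.0 - mps, 1.0 - mpm)
    if np.all(prob >= 1.0):
        raise ValueError("no data left")
    rng = np.random.default_rng(seed)
    mask = rng.random(G.values.shape) < prob
    out = G.copy()
    out.values[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# panel orchestration
# ---------------------------------------------------------------------------

POP_NAMES = ("AxI", "KxA", "KxI")
# which parents found each cross, as indices into ParentSet.alleles
POP_PARENTS = ((0, 1), (2, 0), (2, 1))  # A x I, K x A, K x I with (A, I, K)=(0, 1, 2)


def simulate_panel(
    config: SimConfig | None = None,
    genome_map: GenomeMap | None = None,
    arch: TraitArchitecture | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, TraitValues]:
    """End-to-end generation of a connected three-population panel.

    Returns the (possibly missingness-masked) genotype matrix, the
    plot-phenotype table, and the true genetic values used to build it.
    Sub-seeds for each stochastic stage derive deterministically from the
    master seed.
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    if genome_map is None:
        genome_map = default_map(seed=seeds[0])
    arch = arch or default_architecture(config.n_env)
    parents = simulate_parents(genome_map, config.divergences, seed=seeds[1])
    pops = []
    for k, (name, (ia, ib)) in enumerate(zip(POP_NAMES, POP_PARENTS)):
        pops.append(
            simulate_ril_population(
                parents.alleles[ia],
                parents.alleles[ib],
                config.population_sizes[k],
                config.generations,
                genome_map,
                seed=seeds[2 + k],
                population=name,
            )
        )
    G = concat_populations(pops)
    values = assign_trait_values(G, arch, n_env=config.n_env, seed=seeds[5])
    plots = simulate_trial(values, arch, config, seed=seeds[6])
    if config.marker_missing_rate > 0 or config.sample_missing_rate > 0:
        G = add_missingness(
            G, config.marker_missing_rate, config.sample_missing_rate, seed=seeds[7]
        )
    return G, plots, values


def write_phenotypes(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
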