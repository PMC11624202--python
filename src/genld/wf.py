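"""Forward-in-time diploid Wright-Fisher simulation with selection and epistasis.

The simulator evolves a panmictic (optionally subdivided) diploid population
generation by generation: fitness-proportional parent sampling, gamete
formation with Poisson-distributed crossovers, infinite-sites mutation along
a continuous sequence, multi-epoch demography (size changes implement
bottlenecks; per-pair migration fractions implement gene flow), and a final
multinomial-free sample of individuals returned as a derived-allele
:class:`~genld.matrix.GenotypeMatrix` together with the true haplotypes.

Fitness of an individual with deleterious dosages d_j is

    w = prod_j w_j * (1 - eps)^(k(k-1)/2),   w_j = 1 + s (hom), 1 + h s (het)

with k the total number of deleterious allele copies carried (an alternative
counts deleterious loci instead of copies); eps > 0 is synergistic epistasis,
the pairwise-interaction penalty that makes log-fitness concave in the
mutation burden and drives deleterious alleles into repulsion (negative LD).

Population-size rescaling is supported the standard way: a scaling factor Q
divides population sizes and epoch durations and multiplies mu, r, s and eps,
preserving the population-scaled parameters (N*mu, N*r, N*s) at Q-fold less
compute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, LocusSet
from . import ldstats

__all__ = [
    "DemographyEpoch",
    "SimulationConfig",
    "SimulationResult",
    "Population",
    "genotype_fitness",
    "simulate_population",
    "run_replicates",
    "neutral_fixation_probability",
]

logger = logging.getLogger("genld.wf")

#: raise rather than let a runaway site table exhaust memory
DEFAULT_MEMORY_BUDGET_BYTES = 2_000_000_000


@dataclass(frozen=True)
class DemographyEpoch:
    """A constant-demography stretch: per-deme diploid sizes and migration.

    ``migration[d][e]`` is the per-generation probability that a parent of an
    offspring born in deme d is drawn from deme e (rows must sum to < 1 over
    off-diagonal entries; the remainder stays within the deme).
    """

    duration: int
    sizes: tuple[int, ...]
    migration: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("epoch duration must be >= 0")
        if any(s < 2 for s in self.sizes):
            raise ValueError("deme sizes must be >= 2")
        if self.migration is not None:
            m = np.asarray(self.migration, dtype=float)
            if m.shape != (len(self.sizes), len(self.sizes)):
                raise ValueError("migration matrix shape must match the number of demes")
            off = m - np.diag(np.diag(m))
            if (off < 0).any() or (off.sum(axis=1) >= 1).any():
                raise ValueError("off-diagonal migration rows must be >= 0 and sum < 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a forward simulation needs; YAML-serializable.

    Defaults follow the validation setup this package targets: 1 Mb of
    sequence, mutation rate 1.5e-8 /bp/generation, additive dominance
    (h = 0.5), and selection/epistasis grids supplied per run. ``s`` applies
    to the deleterious fraction of new mutations (s <= 0), the rest are
    neutral. ``scaling_factor`` rescales the whole run (see module docstring).
    """

    epochs: tuple[DemographyEpoch, ...] = (DemographyEpoch(duration=0, sizes=(1000,)),)
    seq_length: float = 1_000_000.0
    mu: float = 1.5e-8
    rec_rate: float = 1e-8
    s: float = 0.0
    h: float = 0.5
    epsilon: float = 0.0
    neutral_fraction: float = 0.5
    sample_n: int = 100
    sample_deme: int = 0
    seed: int | None = None
    scaling_factor: float = 1.0
    burn_in_factor: float = 10.0
    epistasis_mode: str = "copies"  # or "loci": k counts mutated loci, not copies
    memory_budget_bytes: int = DEFAULT_MEMORY_BUDGET_BYTES

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rec_rate < 0 or self.epsilon < 0:
            raise ValueError("rates must be >= 0")
        if self.s > 0:
            raise ValueError("the deleterious class requires s <= 0")
        if not 0 <= self.neutral_fraction <= 1:
            raise ValueError("neutral_fraction must be in [0, 1]")
        if self.epistasis_mode not in ("copies", "loci"):
            raise ValueError("epistasis_mode must be 'copies' or 'loci'")

    def scaled(self) -> "SimulationConfig":
        """Apply ``scaling_factor``: N and durations / Q; mu, r, s, eps * Q."""
        q = self.scaling_factor
        if q == 1.0:
            return self
        if q <= 0:
            raise ValueError("scaling_factor must be > 0")
        if self.s * q <= -1:
            raise ValueError(f"scaled selection coefficient {self.s * q} <= -1")
        epochs = tuple(
            DemographyEpoch(
                duration=max(0, round(e.duration / q)),
                sizes=tuple(max(2, round(s / q)) for s in e.sizes),
                migration=e.migration,
            )
            for e in self.epochs
        )
        return replace(
            self,
            epochs=epochs,
            mu=self.mu * q,
            rec_rate=self.rec_rate * q,
            s=self.s * q,
            epsilon=min(self.epsilon * q, 1.0),
            scaling_factor=1.0,
        )

    # -- YAML round trip ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "epochs": [
                {
                    "duration": e.duration,
                    "sizes": list(e.sizes),
                    "migration": None
                    if e.migration is None
                    else [list(row) for row in e.migration],
                }
                for e in self.epochs
            ]
        }
        for name in (
            "seq_length", "mu", "rec_rate", "s", "h", "epsilon", "neutral_fraction",
            "sample_n", "sample_deme", "seed", "scaling_factor", "burn_in_factor",
            "epistasis_mode",
        ):
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        epochs = tuple(
            DemographyEpoch(
                duration=int(e["duration"]),
                sizes=tuple(int(s) for s in e["sizes"]),
                migration=None
                if e.get("migration") is None
                else tuple(tuple(float(x) for x in row) for row in e["migration"]),
            )
            for e in d.pop("epochs")
        )
        return cls(epochs=epochs, **d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def genotype_fitness(
    dosages: np.ndarray, s: float, h: float, epsilon: float, mode: str = "copies"
) -> float:
    """Multiplicative fitness of one individual from deleterious dosages.

    ``w = prod_j w_j * (1 - epsilon)^(k(k-1)/2)`` with w_j = 1+s for a derived
    homozygote, 1+h*s for a heterozygote, 1 otherwise; k is the deleterious
    allele-copy burden (``mode="copies"``) or the number of mutated loci
    (``mode="loci"``). Floored at 0.
    """
    d = np.asarray(dosages)
    if d.size and not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0, 1, 2}")
    n_het = int((d == 1).sum())
    n_hom = int((d == 2).sum())
    w = (1.0 + h * s) ** n_het * (1.0 + s) ** n_hom
    k = n_het + 2 * n_hom if mode == "copies" else n_het + n_hom
    w *= (1.0 - epsilon) ** (k * (k - 1) / 2.0)
    return float(max(w, 0.0))


class Population:
    """Mutable simulation state: 2N haplotypes over segregating sites.

    ``haplotypes`` is (2N, S) uint8 with row 2i, 2i+1 the two gametes of
    individual i; ``positions`` are float bp coordinates on a continuum
    (infinite sites: collisions have probability zero). Columns are kept in
    insertion order for speed and sorted by position only when sampling;
    ``site_s`` carries each site's selection coefficient (0 for neutral
    sites). Lost sites are pruned lazily; fixed sites are pruned eagerly
    whenever they could still influence fitness (under epistasis the pairwise
    penalty is computed on segregating deleterious copies only).
    """

    def __init__(
        self,
        cfg: SimulationConfig,
        rng: np.random.Generator,
        haplotypes: np.ndarray | None = None,
        positions: np.ndarray | None = None,
        site_s: np.ndarray | None = None,
        sizes: tuple[int, ...] | None = None,
    ):
        self.cfg = cfg
        self.rng = rng
        self.sizes = tuple(sizes if sizes is not None else cfg.epochs[0].sizes)
        n_total = sum(self.sizes)
        if haplotypes is None:
            haplotypes = np.zeros((2 * n_total, 0), dtype=np.uint8)
            positions = np.empty(0)
            site_s = np.empty(0)
        self.haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        self.positions = np.asarray(positions, dtype=float)
        self.site_s = np.asarray(site_s, dtype=float)
        if self.haplotypes.shape[0] != 2 * n_total:
            raise ValueError("haplotype rows must equal 2 * total population size")
        self.generation = 0
        self.n_fixed = 0  # cumulative count of sites pruned as fixed

    # deme d occupies individuals [offset_d, offset_d + N_d)
    def _deme_slices(self, sizes: tuple[int, ...]) -> list[slice]:
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        return [slice(int(offsets[d]), int(offsets[d + 1])) for d in range(len(sizes))]

    def fitness(self) -> np.ndarray:
        """Per-individual fitness; all ones on a selectively neutral state."""
        n_total = self.haplotypes.shape[0] // 2
        sel = np.flatnonzero(self.site_s != 0.0)
        if sel.size == 0:
            return np.ones(n_total)
        Hs = self.haplotypes if sel.size == self.site_s.size else self.haplotypes[:, sel]
        dos = Hs[0::2] + Hs[1::2]  # uint8, max 2: no overflow
        s_sel = self.site_s[sel]
        with np.errstate(divide="ignore"):
            log_het = np.log(np.maximum(1.0 + self.cfg.h * s_sel, 0.0))
            log_hom = np.log(np.maximum(1.0 + s_sel, 0.0))
        # per-site term: dos * log_het + [dos == 2] * (log_hom - 2 log_het)
        logw = dos @ log_het + (dos == 2) @ (log_hom - 2.0 * log_het)
        if self.cfg.epsilon > 0:
            if self.cfg.epistasis_mode == "copies":
                k = dos.sum(axis=1, dtype=np.int64)
            else:
                k = (dos > 0).sum(axis=1, dtype=np.int64)
            logw = logw + k * (k - 1) / 2.0 * np.log1p(-self.cfg.epsilon)
        w = np.exp(logw)
        w[~np.isfinite(w)] = 0.0
        return w

    def _make_gametes(self, parents: np.ndarray) -> np.ndarray:
        """One recombinant gamete per entry of ``parents`` (individual ids)."""
        g = len(parents)
        L = self.cfg.seq_length
        start_hap = self.rng.integers(0, 2, size=g)
        rows = 2 * parents + start_hap
        gametes = self.haplotypes[rows]  # fancy indexing copies
        n_x = self.rng.poisson(self.cfg.rec_rate * L, size=g) if self.cfg.rec_rate > 0 else None
        if n_x is not None and self.positions.size:
            rec = np.flatnonzero(n_x)
            if rec.size:
                # batched parity: a site takes the other parental haplotype
                # iff an odd number of breakpoints lies to its left; counted
                # by bucketing every breakpoint into sorted-site intervals
                s_count = self.positions.size
                counts = n_x[rec]
                breaks = self.rng.uniform(0.0, L, size=int(counts.sum()))
                owner = np.repeat(np.arange(rec.size), counts)
                order = np.argsort(self.positions, kind="stable")
                bins = np.searchsorted(self.positions[order], breaks)
                m = np.bincount(
                    owner * (s_count + 1) + bins, minlength=rec.size * (s_count + 1)
                ).reshape(rec.size, s_count + 1)
                parity_sorted = (np.cumsum(m[:, :s_count], axis=1) & 1).astype(bool)
                rank = np.empty(s_count, dtype=np.int64)
                rank[order] = np.arange(s_count)
                parity = parity_sorted[:, rank]
                others = self.haplotypes[2 * parents[rec] + (1 - start_hap[rec])]
                sub = gametes[rec]  # fancy indexing copies; write back below
                np.copyto(sub, others, where=parity)
                gametes[rec] = sub
        return gametes

    def step(
        self,
        new_sizes: tuple[int, ...] | None = None,
        migration: tuple[tuple[float, ...], ...] | None = None,
    ) -> None:
        """Advance one generation; optionally resize demes (bottleneck/growth)."""
        old_slices = self._deme_slices(self.sizes)
        new_sizes = tuple(new_sizes if new_sizes is not None else self.sizes)
        if len(new_sizes) != len(self.sizes):
            raise ValueError("cannot change the number of demes mid-run")
        w = self.fitness()
        mig = None if migration is None else np.asarray(migration, dtype=float)

        parent_ids = np.empty(2 * sum(new_sizes), dtype=np.int64)
        out = 0
        for d, n_d in enumerate(new_sizes):
            n_gam = 2 * n_d
            if mig is None:
                src = None  # every parent from deme d
            else:
                probs = mig[d].copy()
                probs[d] = 1.0 - (probs.sum() - probs[d])
                src = self.rng.choice(len(new_sizes), size=n_gam, p=probs)
            for e in range(len(new_sizes)) if src is not None else (d,):
                pick = np.arange(n_gam) if src is None else np.flatnonzero(src == e)
                if pick.size == 0:
                    continue
                sl = old_slices[e]
                w_e = w[sl]
                parent_ids[out + pick] = sl.start + self._draw_parents(w_e, pick.size, e)
            out += n_gam

        gametes = self._make_gametes(parent_ids)
        self.haplotypes = self._mutate(gametes)
        self.sizes = new_sizes
        self.generation += 1
        self._prune()
        if self.haplotypes.nbytes > self.cfg.memory_budget_bytes:
            raise MemoryError(
                "site table exceeds the memory budget; increase scaling_factor"
            )

    def _draw_parents(self, w: np.ndarray, size: int, deme: int) -> np.ndarray:
        """Fitness-proportional parent indices within one deme."""
        if w.max() == w.min():  # neutral fast path: uniform sampling
            if w[0] <= 0:
                raise RuntimeError(f"all individuals in deme {deme} have zero fitness")
            return self.rng.integers(0, len(w), size=size)
        cdf = np.cumsum(w)
        if cdf[-1] <= 0:
            raise RuntimeError(f"all individuals in deme {deme} have zero fitness")
        idx = np.searchsorted(cdf, self.rng.random(size) * cdf[-1], side="right")
        return np.minimum(idx, len(w) - 1)

    def _mutate(self, gametes: np.ndarray) -> np.ndarray:
        """Append Poisson(2N * mu * L) infinite-sites mutation columns."""
        g = gametes.shape[0]
        mean_new = g * self.cfg.mu * self.cfg.seq_length
        n_new = self.rng.poisson(mean_new) if mean_new > 0 else 0
        if n_new == 0:
            return gametes
        new_pos = self.rng.uniform(0.0, self.cfg.seq_length, size=n_new)
        carrier = self.rng.integers(0, g, size=n_new)
        deleterious = self.rng.random(n_new) >= self.cfg.neutral_fraction
        new_s = np.where(deleterious, self.cfg.s, 0.0)
        cols = np.zeros((g, n_new), dtype=np.uint8)
        cols[carrier, np.arange(n_new)] = 1
        self.positions = np.concatenate([self.positions, new_pos])
        self.site_s = np.concatenate([self.site_s, new_s])
        return np.concatenate([gametes, cols], axis=1)

    #: generations between lazy prunes when fixed columns cannot bias fitness
    _PRUNE_EVERY = 8

    def _prune(self) -> None:
        # fixed deleterious columns are inert multiplicatively but would leak
        # into the epistatic burden k, so prune every generation in that case
        lazy = not (self.cfg.epsilon > 0 and self.cfg.s < 0)
        if lazy and self.generation % self._PRUNE_EVERY and self.haplotypes.shape[1]:
            return
        counts = self.haplotypes.sum(axis=0, dtype=np.int64)
        full = self.haplotypes.shape[0]
        self.n_fixed += int((counts == full).sum())
        keep = np.flatnonzero((counts > 0) & (counts < full))
        if len(keep) < self.haplotypes.shape[1]:
            self.haplotypes = np.ascontiguousarray(self.haplotypes[:, keep])
            self.positions = self.positions[keep]
            self.site_s = self.site_s[keep]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimulationResult:
    """A sampled endpoint of one simulation: genotypes plus true haplotypes."""

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # (2 * sample_n, m), aligned to genotypes.loci
    config: SimulationConfig

    def locus_set(
        self,
        category: str,
        mdac: int | None = None,
        mdaf: float | None = None,
        min_dac: int = 2,
    ) -> LocusSet:
        from .vcfio import select_locus_set

        return select_locus_set(self.genotypes, category, mdac=mdac, mdaf=mdaf, min_dac=min_dac)


def simulate_population(cfg: SimulationConfig) -> SimulationResult:
    """Run burn-in plus all epochs and sample individuals at the end.

    Burn-in lasts ``burn_in_factor * N0`` generations at the first epoch's
    demography (N0 = its total size), then the epochs run in order; entering
    an epoch with different sizes resamples parents fitness-proportionally at
    the new size — the bottleneck / expansion mechanism. Sampled loci are
    restricted to sites polymorphic within the sample; the returned matrix
    carries per-locus position, selection coefficient, dac and a
    neutral/deleterious category label. Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg.scaled()
    rng = np.random.default_rng(cfg.seed)
    pop = Population(cfg, rng)
    n0 = sum(cfg.epochs[0].sizes)
    burn_in = int(round(cfg.burn_in_factor * n0))
    first = cfg.epochs[0]
    for _ in range(burn_in):
        pop.step(new_sizes=first.sizes, migration=first.migration)
    for epoch in cfg.epochs:
        for _ in range(epoch.duration):
            pop.step(new_sizes=epoch.sizes, migration=epoch.migration)
    return _sample(pop, cfg, rng)


def _sample(
    pop: Population, cfg: SimulationConfig, rng: np.random.Generator
) -> SimulationResult:
    slices = pop._deme_slices(pop.sizes)
    sl = slices[cfg.sample_deme]
    n_avail = sl.stop - sl.start
    if cfg.sample_n > n_avail:
        raise ValueError(f"sample_n={cfg.sample_n} exceeds deme size {n_avail}")
    chosen = np.sort(rng.choice(n_avail, size=cfg.sample_n, replace=False)) + sl.start
    rows = np.empty(2 * cfg.sample_n, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    H = pop.haplotypes[rows]
    dac = H.sum(axis=0, dtype=np.int64)
    poly = np.flatnonzero((dac > 0) & (dac < 2 * cfg.sample_n))
    poly = poly[np.argsort(pop.positions[poly], kind="stable")]
    H = np.ascontiguousarray(H[:, poly])
    dosages = (H[0::2] + H[1::2]).astype(np.int8)
    site_s = pop.site_s[poly]
    loci = pd.DataFrame(
        {
            "chrom": "sim",
            "pos": pop.positions[poly],
            "s": site_s,
            "category": np.where(site_s < 0, "deleterious", "neutral"),
        }
    )
    gm = GenotypeMatrix(dosages=dosages, loci=loci)
    return SimulationResult(genotypes=gm, haplotypes=H, config=cfg)


def neutral_fixation_probability(
    n_diploid: int, n_reps: int, seed: int | None = None, max_generations: int | None = None
) -> float:
    """Fraction of single-copy neutral mutants that reach fixation.

    Each replicate seeds one derived copy into a monomorphic population of
    ``n_diploid`` individuals (no further mutation) and steps until the allele
    fixes or is lost. The diffusion prediction is 1 / (2N).
    """
    ss = np.random.SeedSequence(seed)
    cfg = SimulationConfig(
        epochs=(DemographyEpoch(duration=0, sizes=(n_diploid,)),),
        mu=0.0,
        rec_rate=0.0,
        sample_n=n_diploid,
    )
    cap = max_generations or 100 * n_diploid
    fixed = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        hap = np.zeros((2 * n_diploid, 1), dtype=np.uint8)
        hap[rng.integers(0, 2 * n_diploid), 0] = 1
        pop = Population(cfg, rng, haplotypes=hap, positions=np.array([0.5]),
                         site_s=np.array([0.0]))
        for _ in range(cap):
            pop.step()
            if pop.n_sites == 0:
                break
        else:
            raise RuntimeError("allele neither fixed nor lost within the generation cap")
        fixed += int(pop.n_fixed > 0)
    return fixed / n_reps


def _stats_for_class(
    result: SimulationResult,
    category: str,
    mdac: int | None,
    mdaf: float | None,
    min_dac: int,
    stats: list[str],
) -> dict[str, float] | None:
    from .matrix import InsufficientLociError

    try:
        ls = result.locus_set(category, mdac=mdac, mdaf=mdaf, min_dac=min_dac)
    except InsufficientLociError:
        return None
    out: dict[str, float] = {"n_loci": float(len(ls))}
    if "ldcor" in stats:
        out["ldcor"] = ldstats.ldcor(ls).value
    if "ldcorabs" in stats:
        out["ldcorabs"] = ldstats.ldcorabs(ls).value
    if "netld" in stats:
        out["netld"] = ldstats.netld(ls).value
    if "signed_sqrt_r2" in stats:
        out["signed_sqrt_r2"] = ldstats.signed_sqrt_r2_mean(
            result.haplotypes[:, ls.indices]
        )
    return out


def run_replicates(
    cfg_grid: list[SimulationConfig],
    n_reps: int,
    stats: list[str] | None = None,
    mdac: int | None | list = None,
    mdaf: float | None = None,
    min_dac: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Seeded replicate sweeps over a grid of configurations.

    For every grid cell, runs ``n_reps`` independent simulations and computes
    the requested statistics separately on the neutral and the deleterious
    locus class (pairs never mix selection coefficients), each conditioned on
    the mdac/mdaf ceiling; ``nldcor`` is the deleterious-minus-neutral LDcor
    difference. ``mdac`` may be a list of ceilings — each replicate is then
    summarized at every level, at no extra simulation cost. Returns one row
    per (cell, class, mdac, statistic) with the mean, s.e.m. and replicate
    counts; replicates with fewer than two usable loci in a class are
    excluded from that class and counted.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to report a s.e.m.")
    stats = stats or ["ldcor", "ldcorabs", "netld", "signed_sqrt_r2"]
    base_stats = [s for s in stats if s != "nldcor"]
    mdac_levels = mdac if isinstance(mdac, list) else [mdac]
    ss = np.random.SeedSequence(seed)
    rows = []
    for cell, cfg in enumerate(cfg_grid):
        per_key: dict[tuple, dict[str, list[float]]] = {}
        failures: dict[tuple, int] = {}
        for child in ss.spawn(n_reps):
            rep_cfg = replace(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
            res = simulate_population(rep_cfg)
            for level in mdac_levels:
                vals = {}
                for category in ("neutral", "deleterious"):
                    if category == "deleterious" and cfg.s == 0:
                        continue
                    key = (category, level)
                    v = _stats_for_class(res, category, level, mdaf, min_dac, base_stats)
                    if v is None:
                        failures[key] = failures.get(key, 0) + 1
                        continue
                    vals[category] = v
                    for k, x in v.items():
                        per_key.setdefault(key, {}).setdefault(k, []).append(x)
                if "nldcor" in stats and "neutral" in vals and "deleterious" in vals:
                    per_key.setdefault(("nldcor", level), {}).setdefault(
                        "nldcor", []
                    ).append(vals["deleterious"]["ldcor"] - vals["neutral"]["ldcor"])
        for (category, level), by_stat in per_key.items():
            for stat, values in by_stat.items():
                arr = np.asarray(values)
                rows.append(
                    {
                        "cell": cell,
                        "s": cfg.s,
                        "epsilon": cfg.epsilon,
                        "rec_rate": cfg.rec_rate,
                        "class": category,
                        "mdac": level,
                        "statistic": stat,
                        "mean": float(arr.mean()),
                        "sem": float(arr.std(ddof=1) / np.sqrt(len(arr)))
                        if len(arr) > 1
                        else np.nan,
                        "n_reps": len(arr),
                        "n_failed": failures.get((category, level), 0),
                    }
                )
    return pd.DataFrame(rows)
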