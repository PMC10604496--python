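"""Synthetic genotype generation for multi-allelic codominant markers.

:func:`simulate_genotypes` draws Fst-structured diploid genotype tables
under the Balding-Nichols construction: per locus, an ancestral allele
frequency vector comes from a symmetric Dirichlet; each subpopulation's
vector from a Dirichlet centered on the ancestral one with concentration
``(1 - Fst) / Fst``; genotypes follow Hardy-Weinberg within populations,
and whole genotypes are masked to missing at a fixed rate (both alleles
together, matching the missing-genotype convention of the I/O layer).

:func:`make_planted_instance` builds a benchmark dataset whose optimal
marker panel is known by construction, for oracle and convergence tests:

* ``n_best`` *signal* loci carry all usable between-population
  differentiation.  Six populations split into two sides; each signal locus
  has an 8-allele pool split into two half-pools, and a side's frequency
  vector mixes the uniform pool with its own half-pool at a per-locus
  divergence ``d_i``.  The divergence profile is deliberately heterogeneous
  (one strong locus, the rest graded) so that no proper subset of the
  signal loci reproduces the full-set AGD.
* the remaining *filler* loci are genotyped in a single population only —
  the amplification-failure pattern real microsatellite panels exhibit — so
  the pairwise-distance no-data rule excludes them from every population
  pair.  The signal panel therefore reproduces the full AGD essentially
  exactly, while any smaller panel misses it by a wide margin.  Where
  observed, filler frequencies are strongly skewed, giving them distinctly
  lower PIC than the signal loci; PIC-seeded pheromones genuinely point at
  the planted optimum.

Signal loci are named ``SIG01…``; filler loci ``JNK01…``; columns are
shuffled so position encodes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["SimConfig", "simulate_genotypes", "make_planted_instance"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults describe a moderately structured multi-population
    microsatellite survey at desk scale: 4 subpopulations of 30, 12 loci
    with 5-20 alleles each, Fst 0.15, 2 percent missing genotypes.
    """

    n_pops: int = 4
    n_per_pop: int = 30
    n_loci: int = 12
    allele_range: tuple[int, int] = (5, 20)
    concentration: float = 1.0
    fst: float = 0.15
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1 or self.n_loci < 1:
            raise ValueError("population, individual and locus counts must be positive")
        lo, hi = self.allele_range
        if lo < 1 or hi < lo:
            raise ValueError("allele_range must satisfy 1 <= lo <= hi")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def _draw_genotypes(
    rng: np.random.Generator, pop_freqs: np.ndarray, n: int
) -> np.ndarray:
    """HWE genotypes: (n, 2) allele codes (1-based) from one frequency vector."""
    m = pop_freqs.size
    return rng.choice(np.arange(1, m + 1), size=(n, 2), p=pop_freqs)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a genotype table under the Balding-Nichols model (see module docs)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.allele_range
    if lo < 2:
        warnings.warn("allele count below 2 requested; monomorphic loci possible")
    n_total = cfg.n_pops * cfg.n_per_pop
    calls = np.zeros((n_total, cfg.n_loci, 2), dtype=np.int64)
    bn_conc = (1.0 - cfg.fst) / cfg.fst
    for j in range(cfg.n_loci):
        m = int(rng.integers(lo, hi + 1))
        ancestral = rng.dirichlet(np.full(m, cfg.concentration))
        for p in range(cfg.n_pops):
            alpha = np.maximum(ancestral * bn_conc, 1e-9)
            pop_freq = rng.dirichlet(alpha)
            rows = slice(p * cfg.n_per_pop, (p + 1) * cfg.n_per_pop)
            calls[rows, j, :] = _draw_genotypes(rng, pop_freq, cfg.n_per_pop)
    if cfg.missing_rate > 0:
        miss = rng.random((n_total, cfg.n_loci)) < cfg.missing_rate
        calls[miss] = 0
    individuals = [f"ind{i + 1:04d}" for i in range(n_total)]
    populations = [f"pop{p + 1}" for p in range(cfg.n_pops) for _ in range(cfg.n_per_pop)]
    loci = [f"L{j + 1:02d}" for j in range(cfg.n_loci)]
    return GenotypeMatrix(individuals, populations, loci, calls)


def _signal_divergences(n_best: int, separation: float) -> np.ndarray:
    """Heterogeneous per-locus divergence profile: one strong, rest graded.

    One locus at the full separation plus near-equal weak loci around 30
    percent of it: every proper subset of the signal loci then misses the
    full-set AGD by a wide, analytically verified relative gap (worst case
    about 20 percent of the AGD for n_best = 4), so margin-based selection
    cannot shrink below the planted size.
    """
    if n_best == 1:
        return np.array([separation])
    rest = 0.3 * np.linspace(1.05, 0.95, n_best - 1)
    return separation * np.concatenate([[1.0], rest])


def make_planted_instance(
    k: int = 12,
    n_best: int = 4,
    separation: float = 0.85,
    seed: int | None = None,
    n_pops: int = 6,
    n_per_pop: int = 40,
) -> tuple[GenotypeMatrix, list[str]]:
    """Benchmark dataset with a known optimal panel (see module docstring).

    Returns ``(G, planted)`` where ``planted`` lists the ``n_best`` signal
    locus names whose panel minimizes the AGD accuracy loss at that size.
    ``separation`` in (0, 1] scales the divergence profile of the signal
    loci; population count must be even (two sides).
    """
    if not 1 <= n_best < k:
        raise ValueError("need 1 <= n_best < k")
    if n_pops % 2 or n_pops < 2:
        raise ValueError("n_pops must be even and >= 2")
    if not 0 < separation <= 1:
        raise ValueError("separation must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_total = n_pops * n_per_pop
    pop_of = np.repeat(np.arange(n_pops), n_per_pop)
    side_of = (np.arange(n_pops) >= n_pops // 2).astype(int)
    divergences = _signal_divergences(n_best, separation)

    columns: list[np.ndarray] = []
    names: list[str] = []
    pool = 8  # alleles per signal locus, half-pool of 4 per side
    half = pool // 2
    for i, d in enumerate(divergences):
        base = np.full(pool, (1.0 - d) / pool)
        col = np.zeros((n_total, 2), dtype=np.int64)
        for p in range(n_pops):
            freq = base.copy()
            lohi = slice(0, half) if side_of[p] == 0 else slice(half, pool)
            freq[lohi] += d / half
            rows = pop_of == p
            col[rows] = _draw_genotypes(rng, freq, int(rows.sum()))
        columns.append(col)
        names.append(f"SIG{i + 1:02d}")

    for i in range(k - n_best):
        # Filler: genotyped only in population 1, skewed (low PIC).
        minor = rng.uniform(0.05, 0.20)
        freq = np.array([1.0 - minor, minor])
        col = np.zeros((n_total, 2), dtype=np.int64)
        rows = pop_of == 0
        col[rows] = _draw_genotypes(rng, freq, int(rows.sum()))
        columns.append(col)
        names.append(f"JNK{i + 1:02d}")

    order = rng.permutation(k)
    calls = np.stack([columns[j] for j in order], axis=1)
    loci = [names[j] for j in order]
    individuals = [f"ind{i + 1:04d}" for i in range(n_total)]
    populations = [f"pop{p + 1}" for p in pop_of]
    planted = [name for name in loci if name.startswith("SIG")]
    return GenotypeMatrix(individuals, populations, loci, calls), planted
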