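"""Ant colony optimization over the 2 x k include/exclude marker graph.

Each locus contributes two pheromone-carrying edges — include and exclude —
and an ant's tour is a binary marker panel.  Per epoch, ``ant_n`` ants build
panels from the pheromone trails, panels are scored by AGD accuracy loss,
and the top-ranked fraction deposits pheromone proportional to solution
quality after multiplicative retention (``tau <- decay * tau``, with a small
positivity floor re-applied).  Defaults follow the published parameterization
for this problem: 50 ants, 120 epochs, pheromone weight alpha = 0.7,
retention 0.9.

Pheromones may start uniformly at random or seeded from per-locus PIC values
(include edge ``eps + PIC_j``, exclude edge ``eps + (1 - PIC_j)``), which
biases early construction toward informative loci without introducing a
separate heuristic-desirability term.

Two search modes exist: fixed panel size ``N`` (loci drawn sequentially
without replacement with probability proportional to the include trail to
the power alpha) and free construction (independent include/exclude choice
per locus).  Margin-based selection reduces ``N`` stepwise from ``k - 1``
and keeps the smallest panel whose loss stays within the margin.  A
brute-force enumerator over all panels serves as the small-``k`` oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .distance import MarkerPanel, PanelEvaluator
from .diversity import locus_stats_table
from .genotypes import GenotypeMatrix

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "SelectionResult",
    "init_pheromones",
    "construct_solution",
    "update_pheromones",
    "aco_select_fixed_n",
    "aco_select_margin",
    "exhaustive_optimum",
]

PHEROMONE_EPS = 0.01


@dataclass(frozen=True)
class ACOConfig:
    """Tunable ant colony parameters (defaults: the published values).

    ``stagnation`` re-initializes the trails after that many epochs without
    a global-best improvement, restarting the search instead of spending the
    remaining epochs on a converged colony (set >= ``epochs`` to disable).
    """

    ant_n: int = 50
    epochs: int = 120
    alpha: float = 0.7
    decay: float = 0.9
    elite_fraction: float = 0.2
    stagnation: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ant_n < 1 or self.epochs < 1:
            raise ValueError("ant_n and epochs must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.decay < 1:
            raise ValueError("decay (retention) must lie in (0, 1)")
        if not 0 < self.elite_fraction <= 1:
            raise ValueError("elite_fraction must lie in (0, 1]")
        if self.stagnation < 1:
            raise ValueError("stagnation must be >= 1")


@dataclass
class PheromoneState:
    """Strictly positive include/exclude trails, one pair per locus."""

    tau_include: np.ndarray
    tau_exclude: np.ndarray

    def __post_init__(self) -> None:
        self.tau_include = np.asarray(self.tau_include, dtype=float)
        self.tau_exclude = np.asarray(self.tau_exclude, dtype=float)
        for tau in (self.tau_include, self.tau_exclude):
            if not np.isfinite(tau).all() or (tau <= 0).any():
                raise ValueError("pheromones must be finite and strictly positive")

    def copy(self) -> "PheromoneState":
        return PheromoneState(self.tau_include.copy(), self.tau_exclude.copy())


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``trace`` records the global-best loss after each epoch (non-increasing);
    ``best_first_epoch`` is the 1-based epoch at which the final best loss was
    first reached (0 for deterministic single-shot schemes).
    """

    panel: MarkerPanel
    loss: float
    trace: np.ndarray
    epochs: int
    scheme: str
    seed: int | None
    best_first_epoch: int = 0
    params: dict = field(default_factory=dict)


def init_pheromones(
    k: int,
    mode: str = "random",
    pic_values: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PheromoneState:
    """Initial pheromone trails for ``k`` loci.

    ``random``: both edges ~ Uniform(eps, 1).  ``pic``: include edge
    ``eps + PIC_j``, exclude edge ``eps + (1 - PIC_j)``, so informative loci
    start with a stronger include trail.
    """
    if mode == "random":
        rng = np.random.default_rng(rng)
        return PheromoneState(
            rng.uniform(PHEROMONE_EPS, 1.0, size=k),
            rng.uniform(PHEROMONE_EPS, 1.0, size=k),
        )
    if mode == "pic":
        if pic_values is None:
            raise ValueError("pic mode requires one PIC value per locus")
        p = np.asarray(pic_values, dtype=float)
        if p.shape != (k,) or np.isnan(p).any():
            raise ValueError("pic mode requires one PIC value per locus")
        return PheromoneState(PHEROMONE_EPS + p, PHEROMONE_EPS + (1.0 - p))
    raise ValueError(f"unknown init mode {mode!r}")


def _batch_construct(
    ph: PheromoneState,
    alpha: float,
    n_ants: int,
    N: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Construct ``n_ants`` panel masks at once; shape (n_ants, k)."""
    k = ph.tau_include.size
    if N is not None:
        if not 2 <= N <= k:
            raise ValueError(f"fixed panel size N={N} outside [2, {k}]")
        # Sequential draws without replacement with prob ~ tau_inc^alpha are
        # exactly the Gumbel top-N of log-weights (Efraimidis-Spirakis).
        logw = alpha * np.log(ph.tau_include)
        gumbel = rng.gumbel(size=(n_ants, k))
        order = np.argsort(-(logw[None, :] + gumbel), axis=1)[:, :N]
        masks = np.zeros((n_ants, k), dtype=bool)
        np.put_along_axis(masks, order, True, axis=1)
        return masks
    wi = ph.tau_include**alpha
    we = ph.tau_exclude**alpha
    p_inc = wi / (wi + we)
    masks = rng.random((n_ants, k)) < p_inc[None, :]
    # Panels below the 2-locus floor: bounded resampling, then a
    # deterministic top-up by pheromone rank.
    for _ in range(10):
        small = masks.sum(axis=1) < 2
        if not small.any():
            break
        masks[small] = rng.random((int(small.sum()), k)) < p_inc[None, :]
    small = np.flatnonzero(masks.sum(axis=1) < 2)
    if small.size:
        top = np.argsort(-ph.tau_include)[:2]
        masks[np.ix_(small, top)] = True
    return masks


def construct_solution(
    ph: PheromoneState,
    alpha: float = 0.7,
    N: int | None = None,
    rng: np.random.Generator | None = None,
    loci: list[str] | None = None,
) -> MarkerPanel:
    """One ant's panel from the current trails (see module docstring)."""
    rng = np.random.default_rng(rng)
    mask = _batch_construct(ph, alpha, 1, N, rng)[0]
    names = loci if loci is not None else [f"L{j + 1}" for j in range(mask.size)]
    return MarkerPanel(mask, tuple(names))


def update_pheromones(
    ph: PheromoneState,
    solutions: list[tuple[np.ndarray, float]],
    config: ACOConfig,
) -> PheromoneState:
    """Evaporate, then let the elite deposit quality-proportional pheromone.

    ``solutions`` holds (mask, loss-percent) pairs.  Every edge retains
    ``decay`` of its trail (floored at a small positive constant).  The
    solutions are ranked by loss, duplicates removed (a panel constructed by
    several ants carries no extra information), and each of the top
    ``ceil(elite_fraction * ant_n)`` distinct panels deposits

        (100 - loss) / 100 * (1 - decay) / n_elite

    on the edges of its tour — the include edge of each selected locus and
    the exclude edge of each unselected one.  The ``(1 - decay) / n_elite``
    scaling makes the update an exponential moving average, so trails stay
    on the same [eps, ~1] scale as their initialization instead of growing
    without bound and freezing the colony early.
    """
    if not solutions:
        raise ValueError("need at least one scored solution")
    new = ph.copy()
    new.tau_include = np.maximum(config.decay * new.tau_include, PHEROMONE_EPS)
    new.tau_exclude = np.maximum(config.decay * new.tau_exclude, PHEROMONE_EPS)
    n_elite = min(len(solutions), math.ceil(config.elite_fraction * config.ant_n))
    ranked = sorted(
        solutions,
        key=lambda s: (s[1], int(s[0].sum()), tuple(np.flatnonzero(s[0]))),
    )
    seen: set[tuple] = set()
    chosen: list[tuple[np.ndarray, float]] = []
    for mask, loss in ranked:
        key = tuple(np.flatnonzero(mask))
        if key not in seen:
            seen.add(key)
            chosen.append((mask, loss))
        if len(chosen) == n_elite:
            break
    scale = (1.0 - config.decay) / len(chosen)
    for mask, loss in chosen:
        delta = max(0.0, (100.0 - loss) / 100.0) * scale
        new.tau_include[mask] += delta
        new.tau_exclude[~mask] += delta
    return new


def _pic_per_locus(G: GenotypeMatrix) -> np.ndarray:
    return locus_stats_table(G)["PIC"].to_numpy()


def _better(cand: tuple[float, int, tuple], best: tuple[float, int, tuple]) -> bool:
    """Loss, then smaller panel, then lexicographic locus order."""
    return cand < best


def _run_engine(
    ev: PanelEvaluator,
    N: int | None,
    config: ACOConfig,
    init_mode: str,
    pic_values: np.ndarray | None,
    seed: int | None,
    scheme: str,
) -> SelectionResult:
    k = len(ev.loci)
    rng = np.random.default_rng(seed)
    ph = init_pheromones(k, init_mode, pic_values, rng)
    best_key: tuple | None = None
    best_mask: np.ndarray | None = None
    best_first = 0
    stagnant = 0
    trace = np.empty(config.epochs)
    for epoch in range(1, config.epochs + 1):
        masks = _batch_construct(ph, config.alpha, config.ant_n, N, rng)
        losses = ev.batch_loss(masks)
        order = np.lexsort(
            (np.arange(masks.shape[0]), masks.sum(axis=1), losses)
        )
        top = order[0]
        cand_key = (
            float(losses[top]),
            int(masks[top].sum()),
            tuple(np.flatnonzero(masks[top])),
        )
        if best_key is None or _better(cand_key, best_key):
            best_key = cand_key
            best_mask = masks[top].copy()
            best_first = epoch
            stagnant = 0
        else:
            stagnant += 1
        trace[epoch - 1] = best_key[0]
        if stagnant >= config.stagnation:
            ph = init_pheromones(k, init_mode, pic_values, rng)
            stagnant = 0
        else:
            ph = update_pheromones(
                ph, [(masks[i], float(losses[i])) for i in order], config
            )
    assert best_mask is not None and best_key is not None
    return SelectionResult(
        panel=MarkerPanel(best_mask, tuple(ev.loci)),
        loss=best_key[0],
        trace=trace,
        epochs=config.epochs,
        scheme=scheme,
        seed=seed,
        best_first_epoch=best_first,
        params={"N": N, "init": init_mode, **config.__dict__},
    )


def aco_select_fixed_n(
    G: GenotypeMatrix | PanelEvaluator,
    N: int,
    config: ACOConfig | None = None,
    init_mode: str = "random",
    seed: int | None = None,
    grouping: str = "auto",
) -> SelectionResult:
    """Best panel of exactly ``N`` loci found by the ant colony search.

    Deterministic given ``seed`` (which defaults to ``config.seed``).  With
    PIC initialization (``init_mode='pic'``) the per-locus PIC is computed
    from the pooled data.
    """
    config = config or ACOConfig()
    ev = G if isinstance(G, PanelEvaluator) else PanelEvaluator(G, grouping)
    if not 2 <= N <= len(ev.loci):
        raise ValueError(f"N={N} outside [2, {len(ev.loci)}]")
    pic_values = None
    if init_mode == "pic":
        if isinstance(G, PanelEvaluator):
            raise ValueError("pic init from an evaluator needs explicit pic_values; pass the GenotypeMatrix")
        pic_values = _pic_per_locus(G)
    if seed is None:
        seed = config.seed
    scheme = "PIC+ACO" if init_mode == "pic" else "ACO"
    return _run_engine(ev, N, config, init_mode, pic_values, seed, scheme)


def aco_select_margin(
    G: GenotypeMatrix,
    margin: float,
    config: ACOConfig | None = None,
    init_mode: str = "random",
    seed: int | None = None,
    grouping: str = "auto",
) -> SelectionResult:
    """Smallest panel whose accuracy loss stays within ``margin`` percent.

    Runs the fixed-``N`` search for ``N = k-1`` down to 2, keeping the last
    qualifying panel and stopping at the first ``N`` whose best-found loss
    exceeds the margin (the progressive-reduction schedule).  Returns the
    full set when not even ``k - 1`` loci qualify, and — with a warning —
    for the degenerate ``margin = 0``.
    """
    config = config or ACOConfig()
    ev = PanelEvaluator(G, grouping)
    k = len(ev.loci)
    scheme = "PIC+ACO" if init_mode == "pic" else "ACO"
    full = SelectionResult(
        panel=MarkerPanel.full(ev.loci),
        loss=0.0,
        trace=np.zeros(1),
        epochs=0,
        scheme=scheme,
        seed=seed,
        params={"margin": margin, "init": init_mode},
    )
    if margin <= 0:
        warnings.warn("margin <= 0 is degenerate; returning the full panel")
        return full
    pic_values = _pic_per_locus(G) if init_mode == "pic" else None
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(max(k - 2, 1))
    best = full
    for i, N in enumerate(range(k - 1, 1, -1)):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        result = _run_engine(ev, N, config, init_mode, pic_values, child_seed, scheme)
        if result.loss <= margin:
            best = result
        else:
            break
    best.params["margin"] = margin
    best.seed = seed
    return best


def exhaustive_optimum(
    G: GenotypeMatrix | PanelEvaluator,
    N: int | None = None,
    margin: float | None = None,
    grouping: str = "auto",
    max_k: int = 20,
) -> MarkerPanel:
    """True optimum panel by enumeration (test oracle; refuses k > ``max_k``).

    With ``N``: the loss-minimizing panel among all C(k, N) subsets (ties
    broken lexicographically).  With ``margin``: the smallest N (scanning
    upward from 2) whose optimal panel meets the margin, else the full set.
    """
    if (N is None) == (margin is None):
        raise ValueError("pass exactly one of N or margin")
    ev = G if isinstance(G, PanelEvaluator) else PanelEvaluator(G, grouping)
    k = len(ev.loci)
    if k > max_k:
        raise ValueError(f"exhaustive enumeration refused for k={k} > {max_k}")

    def best_at(n: int) -> tuple[np.ndarray, float]:
        combos = list(combinations(range(k), n))
        masks = np.zeros((len(combos), k), dtype=bool)
        for i, c in enumerate(combos):
            masks[i, list(c)] = True
        losses = ev.batch_loss(masks)
        i = int(np.argmin(losses))  # combinations iterate in lex order
        return masks[i], float(losses[i])

    if N is not None:
        if not 2 <= N <= k:
            raise ValueError(f"N={N} outside [2, {k}]")
        mask, _ = best_at(N)
        return MarkerPanel(mask, tuple(ev.loci))
    for n in range(2, k):
        mask, loss = best_at(n)
        if loss <= margin:
            return MarkerPanel(mask, tuple(ev.loci))
    return MarkerPanel.full(ev.loci)
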