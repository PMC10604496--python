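"""Nei genetic distance restricted to a marker panel, AGD, and the panel
cost function.

The between-group distance is the standard Nei form

.. math::

    D_{a,b} = -\\ln \\frac{\\sum_k \\sum_j p_{ajk} p_{bjk}}
        {\\sqrt{\\sum_k \\sum_j p_{ajk}^2 \\; \\sum_k \\sum_j p_{bjk}^2}}

with the locus sums taken *inside* the ratio (not a per-locus average) and
running over the panel's included loci only.  The average genetic distance
(AGD) is the mean of the finite pairwise distances, and a candidate panel's
cost is its relative AGD deviation from the full marker set, in percent::

    loss(panel) = 100 * |AGD(panel) - AGD(full)| / AGD(full)

Groups are subpopulations when the dataset has two or more population
labels; for single-population data each individual is its own group (its
allele "frequencies" lie in {0, 0.5, 1}).  Loci without observed data in
either member of a pair are excluded from that pair's sums; a pair sharing
no alleles at all gets an infinite distance, which is flagged and excluded
from the AGD rather than capped.

:class:`PanelEvaluator` pre-aggregates the per-locus cross products so that
panel losses can be scored in vectorized batches; the optimizer calls it
thousands of times per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .diversity import allele_frequencies
from .genotypes import GenotypeMatrix

__all__ = [
    "MarkerPanel",
    "DistanceMatrix",
    "PanelEvaluator",
    "nei_distance",
    "distance_matrix",
    "agd",
    "accuracy_loss",
    "resolve_grouping",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Binary inclusion vector over the loci of a dataset."""

    mask: np.ndarray
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "loci", tuple(self.loci))
        if mask.ndim != 1 or mask.size != len(self.loci):
            raise ValueError("panel mask length must equal the number of loci")

    @classmethod
    def from_names(cls, included: list[str], loci: list[str]) -> "MarkerPanel":
        missing = set(included) - set(loci)
        if missing:
            raise ValueError(f"unknown loci in panel: {sorted(missing)}")
        inc = set(included)
        return cls(np.array([name in inc for name in loci]), tuple(loci))

    @classmethod
    def full(cls, loci: list[str]) -> "MarkerPanel":
        return cls(np.ones(len(loci), dtype=bool), tuple(loci))

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @property
    def included(self) -> list[str]:
        return [name for name, m in zip(self.loci, self.mask) if m]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return self.loci == other.loci and np.array_equal(self.mask, other.mask)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise group distances under a panel.

    ``values`` is a square DataFrame; entries may be ``inf`` when a pair
    shares no alleles on the panel (flagged in ``infinite_pairs``) or ``nan``
    when no locus carries data for the pair (``undefined_pairs``).
    """

    values: pd.DataFrame
    panel: MarkerPanel
    infinite_pairs: list[tuple[str, str]] = field(default_factory=list)
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return list(self.values.index)


def resolve_grouping(G: GenotypeMatrix, grouping: str = "auto") -> str:
    """Pick the distance grouping unit.

    ``auto`` resolves to ``population`` when two or more population labels
    exist and ``individual`` otherwise (a single-population dataset still
    needs an AGD, so each individual becomes a group).
    """
    if grouping == "auto":
        return "population" if len(G.population_labels) >= 2 else "individual"
    if grouping in ("population", "individual"):
        if grouping == "population" and len(G.population_labels) < 2:
            raise ValueError(
                "fewer than 2 population labels; use grouping='individual'"
            )
        return grouping
    raise ValueError(f"unknown grouping {grouping!r}")


class PanelEvaluator:
    """Cached panel scorer for one dataset and grouping.

    Pre-computes, per group pair and locus, the allele-frequency cross
    products entering the Nei distance, so that the distance of any panel is
    three masked dot products.  ``batch_loss`` scores a stack of panels at
    once, which is what makes the ant colony search cheap.
    """

    def __init__(self, G: GenotypeMatrix, grouping: str = "auto") -> None:
        self.grouping = resolve_grouping(G, grouping)
        table = allele_frequencies(G, self.grouping)
        self.loci = list(table.loci)
        self.groups = list(table.groups)
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups for pairwise distances")
        k = len(self.loci)
        n_groups = len(self.groups)
        self.observed = table.n_obs > 0  # (n_groups, k)
        # self_sums[g, j] = sum_alleles p^2 at locus j for group g
        self.self_sums = np.zeros((n_groups, k))
        for j in range(k):
            self.self_sums[:, j] = (table.freqs[j] ** 2).sum(axis=1)
        self.pairs = list(combinations(range(n_groups), 2))
        n_pairs = len(self.pairs)
        # Per pair, zero out loci without data on either side so that masked
        # dot products implement the no-data exclusion rule.
        self.cross = np.zeros((n_pairs, k))
        self.self_a = np.zeros((n_pairs, k))
        self.self_b = np.zeros((n_pairs, k))
        self.pair_valid = np.zeros((n_pairs, k), dtype=bool)
        for p, (a, b) in enumerate(self.pairs):
            valid = self.observed[a] & self.observed[b]
            self.pair_valid[p] = valid
            for j in range(k):
                if valid[j]:
                    self.cross[p, j] = float(table.freqs[j][a] @ table.freqs[j][b])
            self.self_a[p] = np.where(valid, self.self_sums[a], 0.0)
            self.self_b[p] = np.where(valid, self.self_sums[b], 0.0)
        self._agd_full: float | None = None

    # ------------------------------------------------------------------
    def pair_distances(self, mask: np.ndarray) -> np.ndarray:
        """Nei distance per group pair under a panel mask (may hold inf/nan)."""
        return self._batch_pair_distances(np.asarray(mask, bool)[None, :])[0]

    def _batch_pair_distances(self, masks: np.ndarray) -> np.ndarray:
        m = masks.astype(float)
        num = m @ self.cross.T          # (M, n_pairs)
        da = m @ self.self_a.T
        db = m @ self.self_b.T
        counts = m @ self.pair_valid.T.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -np.log(num / np.sqrt(da * db))
        d = np.where(num <= 0, np.inf, d)       # disjoint alleles
        d = np.where(counts <= 0, np.nan, d)    # no usable locus for the pair
        # guard tiny negative round-off
        return np.where(np.isfinite(d) & (np.abs(d) < 1e-12), 0.0, d)

    def agd(self, mask: np.ndarray) -> tuple[float, int]:
        """AGD for one panel: (mean of finite pair distances, #excluded)."""
        d = self.pair_distances(mask)
        finite = np.isfinite(d)
        excluded = int((~finite).sum())
        if not finite.any():
            raise ValueError("all pairwise distances are infinite or undefined")
        return float(d[finite].mean()), excluded

    @property
    def agd_full(self) -> float:
        if self._agd_full is None:
            self._agd_full, _ = self.agd(np.ones(len(self.loci), dtype=bool))
        return self._agd_full

    def loss(self, mask: np.ndarray) -> float:
        """Accuracy loss (percent) of one panel relative to the full set."""
        return float(self.batch_loss(np.asarray(mask, bool)[None, :])[0])

    def batch_loss(self, masks: np.ndarray) -> np.ndarray:
        """Accuracy loss (percent) for a stack of panel masks, shape (M, k).

        Panels whose AGD is undefined (every pair infinite or data-free)
        score ``inf`` so the optimizer discards them naturally.
        """
        full = self.agd_full
        if full <= 0:
            raise ValueError("full-panel AGD must be positive to define the loss")
        d = self._batch_pair_distances(np.asarray(masks, dtype=bool))
        finite = np.isfinite(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sums = np.where(finite, d, 0.0).sum(axis=1)
            counts = finite.sum(axis=1)
            agds = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        loss = 100.0 * np.abs(agds - full) / full
        return np.where(np.isnan(agds), np.inf, loss)


# ----------------------------------------------------------------------
# Module-level functions (thin wrappers over the evaluator / direct forms)
# ----------------------------------------------------------------------

def nei_distance(fa: dict, fb: dict, panel: MarkerPanel | None = None) -> float:
    """Nei distance between two groups given per-locus frequency mappings.

    ``fa`` and ``fb`` map locus name -> {allele code: frequency}.  Sums run
    over the panel's included loci (all shared loci when ``panel`` is None);
    loci missing from either mapping are excluded with a warning.  Returns
    ``inf`` (flagged via the warning machinery, never capped) when the
    groups share no alleles on the panel, and 0 for identical frequencies.
    """
    loci = list(fa)
    if panel is not None:
        included = set(panel.included)
        loci = [name for name in loci if name in included]
    num = sa = sb = 0.0
    used = 0
    for name in loci:
        if name not in fb or not fa[name] or not fb[name]:
            warnings.warn(f"locus {name!r} has no data for one group; excluded")
            continue
        va, vb = fa[name], fb[name]
        used += 1
        for allele, p in va.items():
            sa += p * p
            num += p * vb.get(allele, 0.0)
        for p in vb.values():
            sb += p * p
    if used == 0:
        raise ValueError("no locus with data in both groups")
    if num <= 0:
        return float("inf")
    d = -np.log(num / np.sqrt(sa * sb))
    return float(0.0 if abs(d) < 1e-12 else d)


def distance_matrix(
    G: GenotypeMatrix, panel: MarkerPanel | None = None, grouping: str = "auto"
) -> DistanceMatrix:
    """Symmetric pairwise Nei distance matrix between groups under a panel."""
    ev = PanelEvaluator(G, grouping)
    if panel is None:
        panel = MarkerPanel.full(ev.loci)
    d = ev.pair_distances(panel.mask)
    n = len(ev.groups)
    mat = np.zeros((n, n))
    infinite, undefined = [], []
    for p, (a, b) in enumerate(ev.pairs):
        mat[a, b] = mat[b, a] = d[p]
        if np.isnan(d[p]):
            undefined.append((ev.groups[a], ev.groups[b]))
        elif np.isinf(d[p]):
            infinite.append((ev.groups[a], ev.groups[b]))
    values = pd.DataFrame(mat, index=ev.groups, columns=ev.groups)
    return DistanceMatrix(values, panel, infinite, undefined)


def agd(
    G: GenotypeMatrix, panel: MarkerPanel | None = None, grouping: str = "auto"
) -> float:
    """Average genetic distance: mean finite pairwise distance under a panel."""
    ev = PanelEvaluator(G, grouping)
    mask = panel.mask if panel is not None else np.ones(len(ev.loci), bool)
    value, _ = ev.agd(mask)
    return value


def accuracy_loss(
    G: GenotypeMatrix, panel: MarkerPanel, grouping: str = "auto"
) -> float:
    """Panel cost: percent AGD deviation from the full marker set."""
    if panel.size < 2:
        raise ValueError("panels submitted to the cost function need >= 2 loci")
    ev = PanelEvaluator(G, grouping)
    return ev.loss(panel.mask)
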