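"""The four marker-selection schemes behind one estimator interface.

Panel selection is feature selection, so each scheme is an sklearn-style
estimator: construct with hyperparameters, ``fit`` on a
:class:`~msatpanel.genotypes.GenotypeMatrix`, then read the fitted
``panel_`` / ``loss_`` / ``result_`` attributes or call ``transform`` to
subset the genotype table to the selected loci.

Schemes:

* :class:`ACOSelector` — ant colony search with random pheromone start;
* :class:`PICRankSelector` — rank loci by PIC, keep the top of the list;
* :class:`PICACOSelector` — ant colony search with PIC-seeded pheromones;
* :class:`RandomSelector` — uniform random panel (the control).

Each runs in fixed-size mode (``n`` loci exactly) or margin mode (smallest
panel within ``margin`` percent AGD accuracy loss).  ``run_scheme`` is the
functional dispatch over a :class:`SchemeSpec`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from .aco import ACOConfig, SelectionResult, aco_select_fixed_n, aco_select_margin
from .distance import MarkerPanel, PanelEvaluator
from .diversity import locus_stats_table
from .genotypes import GenotypeMatrix

__all__ = [
    "SchemeSpec",
    "BasePanelSelector",
    "ACOSelector",
    "PICACOSelector",
    "PICRankSelector",
    "RandomSelector",
    "run_scheme",
    "pic_rank_select",
    "random_select",
    "pic_aco_select",
    "SCHEMES",
]


class BasePanelSelector(BaseEstimator):
    """Shared scaffolding: validation, fitted attributes, transform.

    Subclasses implement ``_select(G) -> SelectionResult``.  After ``fit``:

    ``panel_`` : MarkerPanel — the selected loci;
    ``loss_`` : float — AGD accuracy loss of the panel, percent;
    ``result_`` : SelectionResult — full provenance (trace, seed, params);
    ``n_features_in_`` : int — number of loci seen.
    """

    def _check_request(self, k: int) -> None:
        n = getattr(self, "n", None)
        margin = getattr(self, "margin", None)
        if (n is None) == (margin is None):
            raise ValueError("set exactly one of n (fixed size) or margin (percent)")
        if n is not None and not 2 <= n <= k:
            raise ValueError(f"n={n} outside [2, {k}]")

    def fit(self, G: GenotypeMatrix, y: Any = None) -> "BasePanelSelector":
        if not isinstance(G, GenotypeMatrix):
            raise TypeError("fit expects a GenotypeMatrix")
        self._check_request(G.n_loci)
        result = self._select(G)
        self.result_ = result
        self.panel_ = result.panel
        self.loss_ = result.loss
        self.n_features_in_ = G.n_loci
        return self

    def _select(self, G: GenotypeMatrix) -> SelectionResult:  # pragma: no cover
        raise NotImplementedError

    def get_support(self) -> np.ndarray:
        """Boolean inclusion mask over the fitted loci."""
        return self.panel_.mask.copy()

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        """Restrict a genotype table to the selected loci."""
        if list(G.loci) != list(self.panel_.loci):
            raise ValueError("loci of G differ from those seen during fit")
        return G.subset_loci(self.panel_.mask)

    def fit_transform(self, G: GenotypeMatrix, y: Any = None) -> GenotypeMatrix:
        return self.fit(G).transform(G)


class ACOSelector(BasePanelSelector):
    """Ant colony panel search with randomly initialized pheromones."""

    scheme_name = "ACO"
    _init_mode = "random"

    def __init__(
        self,
        n: int | None = None,
        margin: float | None = None,
        config: ACOConfig | None = None,
        seed: int | None = None,
        grouping: str = "auto",
    ) -> None:
        self.n = n
        self.margin = margin
        self.config = config
        self.seed = seed
        self.grouping = grouping

    def _select(self, G: GenotypeMatrix) -> SelectionResult:
        config = self.config or ACOConfig()
        if self.n is not None:
            result = aco_select_fixed_n(
                G, self.n, config, self._init_mode, self.seed, self.grouping
            )
        else:
            result = aco_select_margin(
                G, self.margin, config, self._init_mode, self.seed, self.grouping
            )
        result.scheme = self.scheme_name
        return result


class PICACOSelector(ACOSelector):
    """Ant colony search seeded with per-locus PIC pheromones.

    ``force_top`` additionally pins the single highest-PIC locus into every
    constructed panel (off by default: seeding is a soft bias, and informative
    loci can still be excluded when they duplicate information carried by the
    rest of the panel).
    """

    scheme_name = "PIC+ACO"
    _init_mode = "pic"

    def __init__(
        self,
        n: int | None = None,
        margin: float | None = None,
        config: ACOConfig | None = None,
        seed: int | None = None,
        grouping: str = "auto",
        force_top: bool = False,
    ) -> None:
        super().__init__(n=n, margin=margin, config=config, seed=seed, grouping=grouping)
        self.force_top = force_top

    def _select(self, G: GenotypeMatrix) -> SelectionResult:
        result = super()._select(G)
        if self.force_top:
            pic_values = locus_stats_table(G)["PIC"].to_numpy()
            top = int(np.nanargmax(pic_values))
            if not result.panel.mask[top]:
                mask = result.panel.mask.copy()
                mask[top] = True
                if self.n is not None:
                    drop = [j for j in np.flatnonzero(mask) if j != top][-1]
                    mask[drop] = False
                ev = PanelEvaluator(G, self.grouping)
                result.panel = MarkerPanel(mask, result.panel.loci)
                result.loss = ev.loss(mask)
        return result


class PICRankSelector(BasePanelSelector):
    """Deterministic scheme: keep the loci with the highest PIC.

    Fixed-size mode takes the top ``n`` by PIC (ties by locus order); margin
    mode grows the panel from ``N = 2`` upward (cheapest first) until the
    top-``N`` panel meets the margin, falling back to the full set.
    """

    scheme_name = "PIC"

    def __init__(
        self,
        n: int | None = None,
        margin: float | None = None,
        grouping: str = "auto",
    ) -> None:
        self.n = n
        self.margin = margin
        self.grouping = grouping

    def _select(self, G: GenotypeMatrix) -> SelectionResult:
        pic_values = locus_stats_table(G)["PIC"].to_numpy()
        order = np.lexsort((np.arange(G.n_loci), -pic_values))
        ev = PanelEvaluator(G, self.grouping)

        def top_mask(n: int) -> np.ndarray:
            mask = np.zeros(G.n_loci, dtype=bool)
            mask[order[:n]] = True
            return mask

        if self.n is not None:
            mask = top_mask(self.n)
            loss = ev.loss(mask)
        else:
            if self.margin <= 0:
                warnings.warn("margin <= 0 is degenerate; returning the full panel")
                mask = np.ones(G.n_loci, dtype=bool)
                loss = 0.0
            else:
                mask = np.ones(G.n_loci, dtype=bool)
                loss = 0.0
                for n in range(2, G.n_loci):
                    cand = top_mask(n)
                    cand_loss = ev.loss(cand)
                    if cand_loss <= self.margin:
                        mask, loss = cand, cand_loss
                        break
        return SelectionResult(
            panel=MarkerPanel(mask, tuple(G.loci)),
            loss=float(loss),
            trace=np.array([loss]),
            epochs=0,
            scheme=self.scheme_name,
            seed=None,
            params={"n": self.n, "margin": self.margin},
        )


class RandomSelector(BasePanelSelector):
    """Uniform random panel of ``n`` loci — the control scheme."""

    scheme_name = "RANDOM"

    def __init__(
        self, n: int | None = None, seed: int | None = None, grouping: str = "auto"
    ) -> None:
        self.n = n
        self.margin = None
        self.seed = seed
        self.grouping = grouping

    def _select(self, G: GenotypeMatrix) -> SelectionResult:
        rng = np.random.default_rng(self.seed)
        chosen = rng.choice(G.n_loci, size=self.n, replace=False)
        mask = np.zeros(G.n_loci, dtype=bool)
        mask[chosen] = True
        ev = PanelEvaluator(G, self.grouping)
        loss = ev.loss(mask)
        return SelectionResult(
            panel=MarkerPanel(mask, tuple(G.loci)),
            loss=float(loss),
            trace=np.array([loss]),
            epochs=0,
            scheme=self.scheme_name,
            seed=self.seed,
            params={"n": self.n},
        )


SCHEMES: dict[str, type[BasePanelSelector]] = {
    "ACO": ACOSelector,
    "PIC": PICRankSelector,
    "PIC+ACO": PICACOSelector,
    "RANDOM": RandomSelector,
}


@dataclass
class SchemeSpec:
    """A named scheme plus everything needed to reproduce its run."""

    scheme: str
    n: int | None = None
    margin: float | None = None
    config: ACOConfig | None = None
    seed: int | None = None
    grouping: str = "auto"
    extra: dict = field(default_factory=dict)

    def build(self) -> BasePanelSelector:
        if self.scheme not in SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; choose from {sorted(SCHEMES)}"
            )
        cls = SCHEMES[self.scheme]
        kwargs: dict[str, Any] = {"n": self.n, "grouping": self.grouping, **self.extra}
        if self.scheme != "RANDOM":
            kwargs["margin"] = self.margin
        if self.scheme in ("ACO", "PIC+ACO"):
            kwargs["config"] = self.config
        if self.scheme in ("ACO", "PIC+ACO", "RANDOM"):
            kwargs["seed"] = self.seed
        return cls(**kwargs)


def run_scheme(spec: SchemeSpec, G: GenotypeMatrix) -> SelectionResult:
    """Dispatch a SchemeSpec; the result is labeled with scheme and params."""
    selector = spec.build()
    selector.fit(G)
    result = selector.result_
    result.params = {**result.params, **selector.get_params(deep=False)}
    result.params.pop("config", None)
    return result


# Functional wrappers -------------------------------------------------------

def pic_rank_select(
    G: GenotypeMatrix, n: int | None = None, margin: float | None = None
) -> SelectionResult:
    return PICRankSelector(n=n, margin=margin).fit(G).result_


def random_select(G: GenotypeMatrix, n: int, seed: int | None = None) -> SelectionResult:
    return RandomSelector(n=n, seed=seed).fit(G).result_


def pic_aco_select(
    G: GenotypeMatrix,
    n: int | None = None,
    margin: float | None = None,
    config: ACOConfig | None = None,
    seed: int | None = None,
) -> SelectionResult:
    return PICACOSelector(n=n, margin=margin, config=config, seed=seed).fit(G).result_
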