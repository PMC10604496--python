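"""Per-locus diversity statistics for codominant multi-allelic markers.

Computes the standard marker-informativeness indicators used both to rank
microsatellite loci and to evaluate reduced panels:

* ``Na`` — number of distinct observed alleles,
* ``Nea`` — effective number of alleles, :math:`1 / \\sum_i p_i^2`,
* ``AR`` — allele richness, here ``Na`` divided by the number of genotyped
  individuals in the dataset (the ratio convention; rarefaction-based
  richness is out of scope),
* ``Ho`` / ``He`` — observed and expected heterozygosity,
* ``PIC`` — polymorphic information content in the Botstein (1980) form
  :math:`1 - \\sum_i p_i^2 - \\sum_i \\sum_{j>i} 2 p_i^2 p_j^2`.

All frequencies are computed from observed (non-missing) genotypes only; a
genotype is missing whenever either allele code is 0, and denominators vary
by locus accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "LocusStats",
    "allele_frequencies",
    "pic",
    "nea",
    "heterozygosities",
    "allele_richness",
    "locus_stats_table",
]


@dataclass
class AlleleFrequencyTable:
    """Observed allele frequencies per (group, locus).

    Attributes
    ----------
    groups : list of str
        Group labels (populations, the pooled dataset, or individuals).
    loci : list of str
        Locus names.
    alleles : list of ndarray
        Per locus, the sorted distinct allele codes observed anywhere.
    freqs : list of ndarray
        Per locus, a ``(n_groups, m_k)`` array of frequencies; rows with no
        observed genotypes are all-zero and flagged via ``n_obs``.
    n_obs : ndarray of shape (n_groups, n_loci)
        Count of non-missing genotypes behind each frequency row.
    """

    groups: list[str]
    loci: list[str]
    alleles: list[np.ndarray]
    freqs: list[np.ndarray]
    n_obs: np.ndarray

    def frequencies(self, group: str, locus: str) -> pd.Series:
        """Frequency vector for one (group, locus), indexed by allele code."""
        g = self.groups.index(group)
        k = self.loci.index(locus)
        return pd.Series(self.freqs[k][g], index=self.alleles[k], name=locus)

    def observed(self, group: str, locus: str) -> bool:
        """Whether the group has any non-missing genotype at the locus."""
        return bool(self.n_obs[self.groups.index(group), self.loci.index(locus)] > 0)

    @property
    def empty_cells(self) -> list[tuple[str, str]]:
        """(group, locus) pairs with zero observed genotypes (flagged, kept)."""
        gs, ks = np.nonzero(self.n_obs == 0)
        return [(self.groups[g], self.loci[k]) for g, k in zip(gs, ks)]


def _group_indices(G: GenotypeMatrix, grouping: str) -> tuple[list[str], list[np.ndarray]]:
    if grouping == "pooled":
        return ["pooled"], [np.arange(G.n_individuals)]
    if grouping in ("population", "by-population"):
        labels = G.population_labels
        pops = np.asarray(G.populations)
        return labels, [np.flatnonzero(pops == lab) for lab in labels]
    if grouping in ("individual", "by-individual"):
        return list(G.individuals), [np.array([i]) for i in range(G.n_individuals)]
    raise ValueError(f"unknown grouping {grouping!r}")


def allele_frequencies(G: GenotypeMatrix, grouping: str = "population") -> AlleleFrequencyTable:
    """Observed allele frequencies under a grouping.

    Parameters
    ----------
    G : GenotypeMatrix
    grouping : {"population", "pooled", "individual"}
        ``population`` gives one frequency vector per subpopulation;
        ``pooled`` treats the dataset as one group; ``individual`` treats each
        diploid individual as a group (its "frequencies" lie in {0, 0.5, 1}).

    Only non-missing genotypes enter the counts. Groups with no observed
    genotype at a locus get an all-zero row, flagged through ``n_obs`` (and
    listed by ``empty_cells``) rather than silently dropped.
    """
    labels, index_sets = _group_indices(G, grouping)
    n_groups = len(labels)
    miss = G.missing_mask()
    alleles: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    n_obs = np.zeros((n_groups, G.n_loci), dtype=np.int64)
    for k in range(G.n_loci):
        obs_rows = ~miss[:, k]
        codes = np.unique(G.calls[obs_rows, k, :])
        codes = codes[codes > 0]
        if codes.size == 0:
            codes = np.array([], dtype=np.int64)
        alleles.append(codes)
        mat = np.zeros((n_groups, codes.size))
        for g, idx in enumerate(index_sets):
            sel = idx[obs_rows[idx]]
            n_obs[g, k] = sel.size
            if sel.size == 0 or codes.size == 0:
                continue
            counts = np.searchsorted(codes, G.calls[sel, k, :].ravel())
            binc = np.bincount(counts, minlength=codes.size)
            mat[g] = binc / (2 * sel.size)
        freqs.append(mat)
    return AlleleFrequencyTable(labels, list(G.loci), alleles, freqs, n_obs)


def _validated(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def pic(freqs) -> float:
    """Polymorphic information content of one allele-frequency vector.

    Botstein (1980) form for codominant markers:
    ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.  0 for a monomorphic
    locus; always at most the expected heterozygosity.
    """
    p = _validated(freqs)
    sq = p**2
    s2 = sq.sum()
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return float(1.0 - s2 - (s2**2 - (sq**2).sum()))


def nea(freqs) -> float:
    """Effective number of alleles ``1 / sum(p_i^2)``; in [1, Na]."""
    p = _validated(freqs)
    return float(1.0 / (p**2).sum())


def heterozygosities(
    G: GenotypeMatrix, locus: str, bias_corrected: bool = False
) -> tuple[float, float]:
    """Observed and expected heterozygosity at one locus (pooled).

    ``Ho`` is the fraction of observed genotypes carrying two distinct
    alleles; ``He = 1 - sum(p_i^2)`` on pooled frequencies.  With
    ``bias_corrected=True``, ``He`` is scaled by ``2n / (2n - 1)``
    (the small-sample correction), where ``n`` counts observed genotypes.
    """
    k = G.loci.index(locus)
    obs = ~G.missing_mask()[:, k]
    n = int(obs.sum())
    if n == 0:
        raise ValueError(f"no observed genotypes at locus {locus!r}")
    pairs = G.calls[obs, k, :]
    ho = float((pairs[:, 0] != pairs[:, 1]).mean())
    codes, counts = np.unique(pairs.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = float(1.0 - (p**2).sum())
    if bias_corrected and n > 0:
        he *= (2 * n) / (2 * n - 1)
    return ho, he


def allele_richness(G: GenotypeMatrix, locus: str) -> float:
    """Allele richness: distinct observed alleles / total individuals."""
    k = G.loci.index(locus)
    obs = ~G.missing_mask()[:, k]
    codes = np.unique(G.calls[obs, k, :])
    na = int((codes > 0).sum())
    return na / G.n_individuals


def locus_stats_table(G: GenotypeMatrix) -> pd.DataFrame:
    """One row per locus with Na, Nea, AR, PIC, Ho, He.

    Loci with no observed genotypes are kept as flagged (NaN) rows.  The
    returned frame carries a ``summary()``-style description via
    ``df.describe()`` when needed; columns are plain floats.
    """
    rows = []
    miss = G.missing_mask()
    for k, name in enumerate(G.loci):
        obs = ~miss[:, k]
        if not obs.any():
            rows.append(
                {"locus": name, "Na": np.nan, "Nea": np.nan, "AR": np.nan,
                 "PIC": np.nan, "Ho": np.nan, "He": np.nan}
            )
            continue
        pairs = G.calls[obs, k, :]
        codes, counts = np.unique(pairs.ravel(), return_counts=True)
        p = counts / counts.sum()
        ho, he = heterozygosities(G, name)
        rows.append(
            {
                "locus": name,
                "Na": float(codes.size),
                "Nea": nea(p),
                "AR": codes.size / G.n_individuals,
                "PIC": pic(p),
                "Ho": ho,
                "He": he,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


@dataclass
class LocusStats:
    """Named per-locus statistics bundle (one row of the stats table)."""

    locus: str
    Na: float
    Nea: float
    AR: float
    PIC: float
    Ho: float
    He: float
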