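"""Diploid codominant genotype tables and their on-disk formats.

The central container is :class:`GenotypeMatrix`: individuals x loci, two
integer allele codes per call, ``0`` meaning a missing allele.  Allele codes
are opaque labels (fragment sizes or arbitrary integers); nothing downstream
assumes an ordering on them.

Two dialects are supported:

* the GenAlEx codominant layout (the standard spreadsheet export used for
  microsatellite genotype tables): a three-row header followed by one row per
  individual with two columns per locus;
* a plain wide CSV with explicit ``<locus>.1`` / ``<locus>.2`` columns.

Both round-trip bit-exactly through :func:`write_genalex` /
:func:`read_genalex` and :func:`write_csv_genotypes` /
:func:`read_csv_genotypes`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genalex",
    "write_genalex",
    "read_csv_genotypes",
    "write_csv_genotypes",
]


class GenotypeParseError(ValueError):
    """Structured parse failure; the message names the offending row/cell."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    individuals : list of str
        Unique identifiers, one per row.
    populations : list of str
        Subpopulation label per individual; at least one group.
    loci : list of str
        Unique locus names (length ``k``).
    calls : ndarray of shape (n_individuals, k, 2)
        Non-negative integer allele codes; 0 encodes a missing allele.  A
        genotype is treated as missing whenever either allele is 0.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, k = len(self.individuals), len(self.loci)
        if n == 0:
            raise ValueError("GenotypeMatrix requires at least one individual")
        if k == 0:
            raise ValueError("GenotypeMatrix requires at least one locus")
        if self.calls.shape != (n, k, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({n} individuals, {k} loci, 2 alleles)"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        if len(set(self.individuals)) != n:
            raise ValueError("individual identifiers must be unique")
        if len(set(self.loci)) != k:
            raise ValueError("locus names must be unique")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, k) mask of missing genotypes (either allele 0)."""
        return (self.calls == 0).any(axis=2)

    def subset_loci(self, loci: list[str] | np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given loci (names or bool mask)."""
        if isinstance(loci, np.ndarray) and loci.dtype == bool:
            idx = np.flatnonzero(loci)
        else:
            pos = {name: i for i, name in enumerate(self.loci)}
            idx = np.array([pos[name] for name in loci], dtype=int)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


# ----------------------------------------------------------------------
# GenAlEx dialect
# ----------------------------------------------------------------------

def _parse_int(cell: str, where: str) -> int:
    try:
        return int(cell)
    except (TypeError, ValueError):
        raise GenotypeParseError(f"non-integer value {cell!r} at {where}") from None


def _sniff_rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    return [row for row in reader]


def read_genalex(path: str | Path) -> GenotypeMatrix:
    """Read a GenAlEx codominant genotype file (tab- or comma-delimited).

    Layout: row 1 declares ``k  N  P  n1 ... nP`` (loci, individuals,
    populations, per-population sizes); row 2 carries a title and population
    names; row 3 lists locus names over paired allele columns; data rows are
    ``individual, population, a1, a2, ...`` with 0 for a missing allele.

    Raises
    ------
    GenotypeParseError
        If declared counts disagree with the body or a cell is non-integer;
        the message names the offending row or cell.
    """
    rows = _sniff_rows(path)
    if len(rows) < 4:
        raise GenotypeParseError("file too short for GenAlEx layout (needs 3 header rows)")
    head = [c for c in rows[0] if c.strip() != ""]
    if len(head) < 3:
        raise GenotypeParseError("header row 1 must declare loci, individuals, populations")
    k = _parse_int(head[0], "header (locus count)")
    n = _parse_int(head[1], "header (individual count)")
    n_pops = _parse_int(head[2], "header (population count)")
    pop_sizes = [_parse_int(c, "header (population size)") for c in head[3 : 3 + n_pops]]
    if len(pop_sizes) != n_pops:
        raise GenotypeParseError(
            f"header declares {n_pops} populations but lists {len(pop_sizes)} sizes"
        )
    if sum(pop_sizes) != n:
        raise GenotypeParseError(
            f"per-population sizes {pop_sizes} sum to {sum(pop_sizes)}, "
            f"header declares {n} individuals"
        )
    locus_row = rows[2]
    loci = [c.strip() for c in locus_row[2::2] if c.strip() != ""]
    if len(loci) != k:
        raise GenotypeParseError(
            f"header declares {k} loci but locus row names {len(loci)}"
        )
    body = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(body) != n:
        raise GenotypeParseError(
            f"header declares {n} individuals but body has {len(body)} data rows"
        )
    individuals: list[str] = []
    populations: list[str] = []
    calls = np.zeros((n, k, 2), dtype=np.int64)
    for i, row in enumerate(body):
        if len(row) < 2 + 2 * k:
            raise GenotypeParseError(
                f"data row {i + 1} has {len(row)} columns, expected {2 + 2 * k}"
            )
        individuals.append(row[0].strip())
        populations.append(row[1].strip())
        for j in range(k):
            for a in (0, 1):
                cell = row[2 + 2 * j + a]
                calls[i, j, a] = _parse_int(
                    cell, f"row {i + 1}, locus {loci[j]!r}, allele {a + 1}"
                )
    return GenotypeMatrix(individuals, populations, loci, calls)


def write_genalex(G: GenotypeMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write ``G`` in the GenAlEx codominant layout (UTF-8, re-readable)."""
    labels = G.population_labels
    sizes = [sum(1 for p in G.populations if p == lab) for lab in labels]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow([G.n_loci, G.n_individuals, len(labels), *sizes])
        w.writerow(["msatpanel export", "", *labels])
        locus_row: list[str] = ["", ""]
        for name in G.loci:
            locus_row.extend([name, ""])
        w.writerow(locus_row)
        for i, ind in enumerate(G.individuals):
            row: list[object] = [ind, G.populations[i]]
            row.extend(int(a) for a in G.calls[i].ravel())
            w.writerow(row)


# ----------------------------------------------------------------------
# Plain CSV dialect
# ----------------------------------------------------------------------

def read_csv_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read the wide CSV dialect: columns ``individual, population`` then
    ``<locus>.1, <locus>.2`` per locus; 0 encodes a missing allele."""
    df = pd.read_csv(path, dtype={"individual": str, "population": str})
    for col in ("individual", "population"):
        if col not in df.columns:
            raise GenotypeParseError(f"CSV is missing required column {col!r}")
    allele_cols = [c for c in df.columns if c not in ("individual", "population")]
    if len(allele_cols) % 2 != 0:
        raise GenotypeParseError("allele columns must come in .1/.2 pairs")
    loci: list[str] = []
    for c1, c2 in zip(allele_cols[0::2], allele_cols[1::2]):
        base1, _, suf1 = c1.rpartition(".")
        base2, _, suf2 = c2.rpartition(".")
        if base1 != base2 or (suf1, suf2) != ("1", "2"):
            raise GenotypeParseError(f"columns {c1!r}, {c2!r} are not a locus pair")
        loci.append(base1)
    try:
        flat = df[allele_cols].to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise GenotypeParseError(f"non-integer allele cell: {exc}") from None
    calls = flat.reshape(len(df), len(loci), 2)
    return GenotypeMatrix(
        individuals=df["individual"].tolist(),
        populations=df["population"].tolist(),
        loci=loci,
        calls=calls,
    )


def write_csv_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the wide CSV dialect (see :func:`read_csv_genotypes`)."""
    data: dict[str, object] = {
        "individual": G.individuals,
        "population": G.populations,
    }
    for j, name in enumerate(G.loci):
        data[f"{name}.1"] = G.calls[:, j, 0]
        data[f"{name}.2"] = G.calls[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)
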