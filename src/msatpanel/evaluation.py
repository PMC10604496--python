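"""Scheme comparison and full-vs-reduced panel discrepancy reports.

``compare_schemes`` races the selection schemes across a range of panel
sizes, replicating the stochastic ones over seeded runs, and contrasts the
resulting accuracy distributions per size with Tukey's honest significant
difference test (studentized-range family correction, via statsmodels).

``panel_discrepancy`` quantifies how a reduced panel biases the per-locus
diversity statistics (Na, Nea, AR, PIC, Ho, He): for each statistic it
compares the reduced panel's per-locus values against the full set with a
two-sample t-test (Student pooled-variance by default, Welch behind a
flag), and reports the mean difference, fold change and a significance tier:

====================  =================
p > 0.05              ns
0.01 < p <= 0.05      slight
0.001 < p <= 0.01     moderate
p <= 0.001            high
====================  =================

``reduction_curve`` traces best-found loss and reduced-panel statistic
means as the panel shrinks from the full set down to two loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .aco import ACOConfig
from .distance import MarkerPanel, PanelEvaluator
from .diversity import locus_stats_table
from .genotypes import GenotypeMatrix
from .selection import SCHEMES, SchemeSpec, run_scheme

__all__ = [
    "ComparisonTable",
    "DiscrepancyReport",
    "compare_schemes",
    "panel_discrepancy",
    "reduction_curve",
    "significance_tier",
]

STATISTICS = ("Na", "Nea", "AR", "PIC", "Ho", "He")
DETERMINISTIC_SCHEMES = {"PIC"}


def significance_tier(p: float) -> str:
    """Map a p-value to its significance tier (see module docstring)."""
    if np.isnan(p):
        return "na"
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "slight"
    if p > 0.001:
        return "moderate"
    return "high"


@dataclass
class ComparisonTable:
    """Accuracy distributions per (N, scheme) plus pairwise Tukey contrasts.

    ``accuracies``: long frame with columns N, scheme, replicate, accuracy.
    ``contrasts``: one row per (N, scheme pair) with meandiff, p_value, tier.
    ``winners``: per N, the scheme with the highest mean accuracy and the
    smallest p-value among its contrasts.
    """

    accuracies: pd.DataFrame
    contrasts: pd.DataFrame
    winners: pd.DataFrame


def _tukey_contrasts(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """All pairwise Tukey HSD contrasts; exact ties degenerate to p = 1."""
    labels = sorted(set(groups))
    pairs = list(combinations(labels, 2))
    if len(labels) < 2:
        return pd.DataFrame(columns=["scheme_a", "scheme_b", "meandiff", "p_value"])
    group_vals = {lab: values[groups == lab] for lab in labels}
    sizes = np.array([group_vals[lab].size for lab in labels])
    pooled_var = sum(
        ((v - v.mean()) ** 2).sum() for v in group_vals.values()
    ) / max(1, int(sizes.sum()) - len(labels))
    if pooled_var <= 1e-24:
        rows = [
            {
                "scheme_a": a,
                "scheme_b": b,
                "meandiff": float(group_vals[b].mean() - group_vals[a].mean()),
                "p_value": 1.0
                if np.isclose(group_vals[a].mean(), group_vals[b].mean())
                else 0.0,
            }
            for a, b in pairs
        ]
        return pd.DataFrame(rows)
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return pd.DataFrame(
        {
            "scheme_a": frame["group1"],
            "scheme_b": frame["group2"],
            "meandiff": frame["meandiff"].astype(float),
            "p_value": frame["p-adj"].astype(float),
        }
    )


def compare_schemes(
    G: GenotypeMatrix,
    n_range: list[int],
    schemes: tuple[str, ...] = ("ACO", "PIC", "PIC+ACO", "RANDOM"),
    replicates: int = 20,
    seed: int | None = None,
    config: ACOConfig | None = None,
    grouping: str = "auto",
) -> ComparisonTable:
    """Race schemes over panel sizes; Tukey-contrast their accuracies per N.

    Stochastic schemes run ``replicates`` times with independent child
    seeds; deterministic ones contribute a single value per N.  Accuracy is
    ``100 - loss`` (percent).
    """
    unknown = set(schemes) - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown schemes: {sorted(unknown)}")
    if replicates < 2:
        raise ValueError("replicates must be >= 2 for stochastic schemes")
    root = np.random.SeedSequence(seed)
    rows = []
    for N in n_range:
        for scheme in schemes:
            reps = 1 if scheme in DETERMINISTIC_SCHEMES else replicates
            children = root.spawn(reps)
            for r in range(reps):
                child_seed = int(children[r].generate_state(1)[0] % (2**31))
                spec = SchemeSpec(
                    scheme=scheme, n=N, config=config, seed=child_seed,
                    grouping=grouping,
                )
                result = run_scheme(spec, G)
                rows.append(
                    {
                        "N": N,
                        "scheme": scheme,
                        "replicate": r,
                        "accuracy": 100.0 - result.loss,
                    }
                )
    acc = pd.DataFrame(rows)
    contrast_frames = []
    winner_rows = []
    for N, sub in acc.groupby("N"):
        con = _tukey_contrasts(
            sub["accuracy"].to_numpy(), sub["scheme"].to_numpy()
        )
        con.insert(0, "N", N)
        con["tier"] = con["p_value"].map(significance_tier)
        contrast_frames.append(con)
        means = sub.groupby("scheme")["accuracy"].mean()
        best = means.idxmax()
        involved = con[(con["scheme_a"] == best) | (con["scheme_b"] == best)]
        winner_rows.append(
            {
                "N": N,
                "winner": best,
                "mean_accuracy": float(means.max()),
                "min_p_vs_others": float(involved["p_value"].min())
                if len(involved)
                else np.nan,
            }
        )
    contrasts = pd.concat(contrast_frames, ignore_index=True)
    return ComparisonTable(acc, contrasts, pd.DataFrame(winner_rows))


@dataclass
class DiscrepancyReport:
    """Per-statistic bias of a reduced panel relative to the full set.

    ``table`` columns: statistic, mean_reduced, mean_full, mean_diff
    (absolute), fold (reduced / full), t_stat, p_value, tier.  For the
    degenerate panel == full set, numeric columns are NaN and tier "na",
    mirroring the dashes such report tables print.
    """

    table: pd.DataFrame
    panel: MarkerPanel

    @property
    def is_trivial(self) -> bool:
        return bool(self.table["tier"].eq("na").all())


def panel_discrepancy(
    G: GenotypeMatrix, panel: MarkerPanel, equal_var: bool = True
) -> DiscrepancyReport:
    """Compare per-locus statistics of a reduced panel against the full set.

    ``equal_var=True`` is the Student pooled-variance two-sample t-test (the
    common default of the named scipy function); ``False`` gives Welch.
    """
    if panel.size == 0:
        raise ValueError("panel must be non-empty")
    stats_table = locus_stats_table(G)
    reduced = stats_table.loc[panel.included]
    rows = []
    trivial = panel.size == len(G.loci)
    for stat in STATISTICS:
        full_vals = stats_table[stat].dropna().to_numpy()
        red_vals = reduced[stat].dropna().to_numpy()
        if trivial:
            rows.append(
                {
                    "statistic": stat,
                    "mean_reduced": np.nan,
                    "mean_full": float(full_vals.mean()),
                    "mean_diff": np.nan,
                    "fold": np.nan,
                    "t_stat": np.nan,
                    "p_value": np.nan,
                    "tier": "na",
                }
            )
            continue
        t_stat, p = sstats.ttest_ind(red_vals, full_vals, equal_var=equal_var)
        mean_r, mean_f = float(red_vals.mean()), float(full_vals.mean())
        rows.append(
            {
                "statistic": stat,
                "mean_reduced": mean_r,
                "mean_full": mean_f,
                "mean_diff": abs(mean_r - mean_f),
                "fold": mean_r / mean_f if mean_f != 0 else np.nan,
                "t_stat": float(t_stat),
                "p_value": float(p),
                "tier": significance_tier(float(p)),
            }
        )
    return DiscrepancyReport(pd.DataFrame(rows), panel)


def reduction_curve(
    G: GenotypeMatrix,
    scheme: str = "PIC+ACO",
    config: ACOConfig | None = None,
    seed: int | None = None,
    grouping: str = "auto",
) -> pd.DataFrame:
    """Best-found loss and reduced-panel stat means for N = k down to 2.

    Each panel size runs the scheme once with an independent child seed;
    rows carry N, loss, and the mean Ho, He and AR over the selected loci.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    k = G.n_loci
    stats_table = locus_stats_table(G)
    ev = PanelEvaluator(G, grouping)
    children = np.random.SeedSequence(seed).spawn(k - 1)
    rows = []
    for i, N in enumerate(range(k, 1, -1)):
        if N == k:
            panel = MarkerPanel.full(list(G.loci))
            loss = ev.loss(panel.mask)
        else:
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            spec = SchemeSpec(
                scheme=scheme, n=N, config=config, seed=child_seed, grouping=grouping
            )
            result = run_scheme(spec, G)
            panel, loss = result.panel, result.loss
        sub = stats_table.loc[panel.included]
        rows.append(
            {
                "N": N,
                "loss": float(loss),
                "Ho_mean": float(sub["Ho"].mean()),
                "He_mean": float(sub["He"].mean()),
                "AR_mean": float(sub["AR"].mean()),
                "panel": ",".join(panel.included),
            }
        )
    return pd.DataFrame(rows)
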