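"""Correlating codon-usage T-statistics with modification Z-score profiles.

The central inference layer: for each codon, the across-tissue vector of
gene-set T-statistics is correlated (Pearson) with each modification's
across-tissue Z-score profile.  A positive r for a wobble-rule codon (e.g.
AAC under queuosine) means tissues enriched for the modification also
over-use that codon in the chosen gene set.  The synonymous-pair check
correlates a C-ending codon's T vector with its U/T-ending partner's — the
expected signature of modification-driven codon selection is anticorrelation.

No p-values are attached by default: with a handful of tissues the
coefficients are the result of interest, and significance would be
underpowered anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import CodonTable

MIN_TISSUES = 3


class LinkageError(ValueError):
    """Invalid input to a codon-modification correlation."""


@dataclass(frozen=True)
class LinkageResult:
    codon: str
    modification: str
    r: float
    n_tissues: int
    metric: str = ""
    direction: str = ""


def _pairwise_r(x: pd.Series, y: pd.Series, what: str) -> tuple[float, int]:
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < MIN_TISSUES:
        raise LinkageError(
            f"{what}: only {len(joined)} matched tissues with defined values "
            f"(need >= {MIN_TISSUES})"
        )
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise LinkageError(f"{what}: zero variance across tissues")
    return float(np.corrcoef(a, b)[0, 1]), len(joined)


def codon_mod_correlation(
    tstats: pd.Series,
    zscores: pd.Series,
    *,
    codon: str = "",
    modification: str = "",
    metric: str = "",
    direction: str = "",
) -> LinkageResult:
    """Pearson r between one codon's per-tissue T values and one
    modification's per-tissue Z-scores.

    Both series are indexed by tissue; tissues with an undefined T are
    dropped pairwise.
    """
    r, n = _pairwise_r(tstats, zscores, f"{codon or 'codon'} vs {modification or 'mod'}")
    return LinkageResult(codon, modification, r, n, metric, direction)


def synonymous_pair_correlation(
    tstats_c: pd.Series, tstats_u: pd.Series, *, pair: str = ""
) -> float:
    """Pearson r across tissues between a synonymous codon pair's T vectors."""
    r, _ = _pairwise_r(tstats_c, tstats_u, pair or "synonymous pair")
    return r


def linkage_report(
    tstat_by_tissue: dict[str, pd.DataFrame],
    zscores: pd.DataFrame,
    table: CodonTable,
    *,
    metric: str = "",
    direction: str = "",
    rule_sets: dict[str, set] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every codon with every modification across tissues.

    Parameters
    ----------
    tstat_by_tissue
        tissue -> per-codon T-stat frame (as from ``gene_set_tstat``).
    zscores
        modification x tissue Z-score matrix.
    rule_sets
        modification -> set of codons; defaults to the table's wobble rule
        sets.  Rule-set rows are extracted from the full matrix.

    Returns
    -------
    (report, full_matrix)
        ``report`` — one row per (codon, modification) restricted to
        rule-set codons of modifications present in the Z matrix, in
        deterministic (modification, codon) order, with columns
        codon, amino_acid, modification, metric, direction, r, n_tissues.
        ``full_matrix`` — codons x modifications Pearson r.
    """
    missing = [t for t in tstat_by_tissue if t not in zscores.columns]
    if missing:
        raise LinkageError(f"tissues absent from Z-score matrix: {missing}")
    tissues = [t for t in zscores.columns if t in tstat_by_tissue]
    if len(tissues) < MIN_TISSUES:
        raise LinkageError(f"only {len(tissues)} shared tissues (need >= {MIN_TISSUES})")

    t_matrix = pd.DataFrame(
        {t: tstat_by_tissue[t]["T"] for t in tissues}
    )  # codons x tissues
    # corrwith per modification: pairwise-complete over tissues
    full = pd.DataFrame(index=t_matrix.index, columns=zscores.index, dtype=float)
    for mod in zscores.index:
        z = zscores.loc[mod, tissues].astype(float)
        centered_ok = z.std(ddof=0) > 0
        for codon in t_matrix.index:
            tv = t_matrix.loc[codon]
            joined = pd.concat([tv, z], axis=1).dropna()
            if len(joined) < MIN_TISSUES or not centered_ok:
                continue
            a = joined.iloc[:, 0].to_numpy(float)
            if np.std(a) == 0:
                continue
            full.loc[codon, mod] = float(
                np.corrcoef(a, joined.iloc[:, 1].to_numpy(float))[0, 1]
            )
    full.index.name = "codon"

    if rule_sets is None:
        rule_sets = {m: set(rs) for m, rs in table.rule_sets.items()}
    rows = []
    for mod in sorted(rule_sets):
        if mod not in zscores.index:
            continue
        for codon in sorted(rule_sets[mod]):
            if codon not in t_matrix.index:
                continue
            n_def = int(
                pd.concat(
                    [t_matrix.loc[codon], zscores.loc[mod, tissues]], axis=1
                )
                .dropna()
                .shape[0]
            )
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": table.codon_to_aa[codon],
                    "modification": mod,
                    "metric": metric,
                    "direction": direction,
                    "r": full.loc[codon, mod],
                    "n_tissues": n_def,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["codon", "amino_acid", "modification", "metric", "direction", "r", "n_tissues"],
    )
    return report, full
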