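"""Per-gene codon frequency metrics and gene-set T-statistics.

Two per-gene frequency metrics are computed from raw codon counts:

* **isoacceptor frequency** — the count of codon *i* divided by the summed
  counts of its synonymous family (the codons decoded by the isoacceptor
  tRNAs for that amino acid).  Undefined (NaN) when the family does not
  occur in the gene.  Only families of size 2–6 are eligible for T
  statistics; the single-codon Met and Trp families are reported but
  flagged ineligible.
* **total frequency** — the count of codon *i* divided by the total number
  of sense codons in the gene.

The gene-set statistic is a one-sample t of a selected gene set's per-codon
frequencies against the genome-average frequency mu_i:

    T_i = (xbar_i - mu_i) / (s_i / sqrt(n))

where xbar_i and s_i are the sample mean and sample SD over the set's genes
where the metric is defined, and n counts those genes.  |T| > 2 is flagged
significant (two-sided p < 0.05 for the default set size n = 200).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import CodingSequence, CodonTable, count_codons

ELIGIBLE_FAMILY_SIZES = range(2, 7)

METRIC_ISO = "isoacceptor"
METRIC_TOTAL = "total"


class MetricsError(ValueError):
    """Invalid input to a frequency/T-statistic computation."""


def count_matrix(cds_list: Sequence[CodingSequence], table: CodonTable) -> pd.DataFrame:
    """Genes x 64-codon integer count matrix (rows ordered as given)."""
    if not cds_list:
        raise MetricsError("no coding sequences supplied")
    data = {c.gene_id: count_codons(c, table) for c in cds_list}
    df = pd.DataFrame.from_dict(data, orient="index", dtype=np.int64)
    return df[list(table.codons)]


def isoacceptor_frequency(counts: pd.DataFrame | pd.Series, table: CodonTable) -> pd.DataFrame | pd.Series:
    """Within-family synonymous codon frequencies.

    Accepts one gene's counts (Series) or a genes x codons frame.  STOP
    codons are dropped.  Families absent from a gene yield NaN (undefined),
    never 0.
    """
    squeeze = isinstance(counts, pd.Series)
    df = counts.to_frame().T if squeeze else counts
    sense = list(table.sense_codons)
    df = df[sense].astype(float)
    out = pd.DataFrame(index=df.index, columns=sense, dtype=float)
    for fam in table.families.values():
        fam = list(fam)
        fam_total = df[fam].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[fam] = df[fam].div(fam_total.where(fam_total > 0), axis=0)
    return out.iloc[0] if squeeze else out


def total_frequency(counts: pd.DataFrame | pd.Series, table: CodonTable) -> pd.DataFrame | pd.Series:
    """Per-codon share of all sense codons in the gene; rows sum to 1."""
    squeeze = isinstance(counts, pd.Series)
    df = counts.to_frame().T if squeeze else counts
    sense = list(table.sense_codons)
    df = df[sense].astype(float)
    totals = df.sum(axis=1)
    if (totals == 0).any():
        bad = list(df.index[totals == 0])
        raise MetricsError(f"genes with zero sense-codon counts: {bad}")
    out = df.div(totals, axis=0)
    return out.iloc[0] if squeeze else out


def frequency_matrix(
    cds_list: Sequence[CodingSequence], table: CodonTable, metric: str
) -> pd.DataFrame:
    """Genes x sense-codons frequency matrix for the chosen metric."""
    counts = count_matrix(cds_list, table)
    if metric == METRIC_ISO:
        return isoacceptor_frequency(counts, table)
    if metric == METRIC_TOTAL:
        return total_frequency(counts, table)
    raise MetricsError(f"unknown metric {metric!r}")


def genome_baseline(freqs: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-codon genome-average mean mu, sample SD, and contributing-gene n.

    ``freqs`` is the genes x codons frequency matrix over the full gene
    universe.  Genes where a codon's metric is undefined (NaN) do not
    contribute to that codon.  Codons with fewer than two contributing genes
    are flagged (``eligible = False``) and must be excluded downstream.
    """
    if len(freqs) < 2:
        raise MetricsError("genome baseline needs at least 2 genes")
    n = freqs.notna().sum(axis=0)
    out = pd.DataFrame(
        {
            "metric": metric,
            "mu": freqs.mean(axis=0),
            "sigma": freqs.std(axis=0, ddof=1),
            "n_genes": n,
            "eligible": n >= 2,
        }
    )
    out.index.name = "codon"
    return out


def select_gene_sets(
    expr: pd.DataFrame, tissue: str, n: int = 200
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n gene ids by normalized expression in ``tissue``.

    ``expr`` is indexed by gene_id with one column per tissue, or per
    tissue_replicate (``tissue_rep``-style columns are averaged).  Ties are
    broken lexicographically by gene_id; NaN-expression genes are dropped
    with a warning; the two sets are disjoint.
    """
    if tissue in expr.columns:
        values = expr[tissue].astype(float)
    else:
        reps = [c for c in expr.columns if c == tissue or c.startswith(f"{tissue}_")]
        if not reps:
            raise MetricsError(f"tissue {tissue!r} not found in expression table")
        values = expr[reps].astype(float).mean(axis=1)
    if values.isna().any():
        dropped = int(values.isna().sum())
        warnings.warn(f"{tissue}: dropping {dropped} genes with NaN expression", stacklevel=2)
        values = values.dropna()
    if len(values) < 2 * n:
        raise MetricsError(
            f"{tissue}: need at least {2 * n} genes with finite expression, "
            f"have {len(values)}"
        )
    order = values.to_frame("x").reset_index()
    order.columns = ["gene_id", "x"]
    # one global ranking keeps the sets disjoint even under heavy ties
    desc = order.sort_values(["x", "gene_id"], ascending=[False, True])
    top = desc["gene_id"].head(n).tolist()
    bottom = desc["gene_id"].tail(n).tolist()[::-1]
    return top, bottom


def gene_set_tstat(
    freqs: pd.DataFrame,
    gene_ids: Iterable[str],
    baseline: pd.DataFrame,
    table: CodonTable,
    *,
    metric: str,
    tissue: str = "",
    direction: str = "",
) -> pd.DataFrame:
    """One-sample T of a gene set's codon frequencies against mu_i.

    Returns a per-codon frame with columns amino_acid, ending_class, xbar,
    s, n, T, p.  n is the number of set genes where the metric is defined
    for that codon; codons with s = 0 or n < 2, and codons flagged
    ineligible in the baseline, are reported with NaN T/p.
    """
    if str(baseline["metric"].iloc[0]) != metric:
        raise MetricsError(
            f"baseline metric {baseline['metric'].iloc[0]!r} != requested {metric!r}"
        )
    sub = freqs.loc[list(gene_ids)]
    xbar = sub.mean(axis=0)
    s = sub.std(axis=0, ddof=1)
    n = sub.notna().sum(axis=0)
    mu = baseline["mu"].reindex(sub.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (xbar - mu) / (s / np.sqrt(n))
    t = t.where((s > 0) & (n >= 2) & baseline["eligible"].reindex(sub.columns))
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(t), df=n - 1), index=t.index
    ).where(t.notna())
    fam_size = {
        c: len(table.family_of(c)) for c in sub.columns
    }
    out = pd.DataFrame(
        {
            "amino_acid": [table.codon_to_aa[c] for c in sub.columns],
            "ending_class": [table.third_position_class[c] for c in sub.columns],
            "family_eligible": [
                fam_size[c] in ELIGIBLE_FAMILY_SIZES for c in sub.columns
            ],
            "xbar": xbar,
            "s": s,
            "n": n,
            "T": t,
            "p": p,
        },
        index=sub.columns,
    )
    if metric == METRIC_ISO:
        # single-codon families have iso_freq fixed at 1 -> zero variance
        out.loc[~out["family_eligible"], ["T", "p"]] = np.nan
    out.index.name = "codon"
    out.attrs.update(tissue=tissue, direction=direction, metric=metric)
    return out


def significance_cutoff_p(t: float = 2.0, n: int = 200) -> float:
    """Two-sided Student-t tail probability of |T| >= t at df = n - 1."""
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def ending_bias_summary(tstats: pd.DataFrame) -> pd.Series:
    """Mean T for A/T-ending vs G/C-ending codons and their signed gap.

    Means run over defined (non-NaN) T values only.  The gap is
    ``mean(AT) - mean(GC)``; positive gaps mark an A/T-ending bias.
    """
    defined = tstats.dropna(subset=["T"])
    means = {}
    for cls in ("AT_ending", "GC_ending"):
        vals = defined.loc[defined["ending_class"] == cls, "T"]
        if vals.empty:
            warnings.warn(f"no defined T values for class {cls}", stacklevel=2)
            means[cls] = np.nan
        else:
            means[cls] = float(vals.mean())
    return pd.Series(
        {
            "mean_T_AT_ending": means["AT_ending"],
            "mean_T_GC_ending": means["GC_ending"],
            "gap": means["AT_ending"] - means["GC_ending"],
        }
    )
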