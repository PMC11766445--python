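"""Ground-truth recovery harnesses run on synthetic datasets.

These wire the analysis stages together on a generated dataset and return
the summary quantities the generative model makes predictions about: the
correlation between queuosine Z-scores and Q-codon T-statistics, the
NAC-vs-NAT synonymous-pair correlation, and the agreement between pause
log2 fold changes and true dwell-time ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genetic_code import build_codon_table
from .metrics import (
    METRIC_ISO,
    count_matrix,
    frequency_matrix,
    gene_set_tstat,
    genome_baseline,
    isoacceptor_frequency,
    select_gene_sets,
    total_frequency,
)
from .modifications import replicate_means, tissue_zscores
from .pausing import pause_scores, relative_pausing
from .simulate import NAC_CODONS, SyntheticDataset, recovery_report


def tstat_matrix(
    dataset: SyntheticDataset,
    *,
    metric: str = METRIC_ISO,
    direction: str = "top",
    n_top: int | None = None,
) -> pd.DataFrame:
    """Codons x tissues T-statistic matrix for one metric/direction."""
    table = build_codon_table()
    counts = count_matrix(dataset.cds, table)
    freqs = (
        isoacceptor_frequency(counts, table)
        if metric == METRIC_ISO
        else total_frequency(counts, table)
    )
    baseline = genome_baseline(freqs, metric)
    n = n_top if n_top is not None else dataset.config.min_gene_set
    cols = {}
    for tissue in dataset.config.tissues:
        top, bottom = select_gene_sets(dataset.expression, tissue, n)
        genes = top if direction == "top" else bottom
        ts = gene_set_tstat(
            freqs, genes, baseline, table,
            metric=metric, tissue=tissue, direction=direction,
        )
        cols[tissue] = ts["T"]
    return pd.DataFrame(cols)


def q_linkage_signal(
    dataset: SyntheticDataset,
    *,
    metric: str = METRIC_ISO,
    direction: str = "top",
    n_top: int | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Q-codon linkage summary on one dataset.

    Returns ``(r_mod, r_pair)``: ``r_mod`` — Pearson r between the Q
    Z-score profile and each Q-family codon's T vector across tissues;
    ``r_pair`` — for each C-ending codon, Pearson r between its T vector
    and its T-ending synonymous partner's.
    """
    t_mat = tstat_matrix(dataset, metric=metric, direction=direction, n_top=n_top)
    z = tissue_zscores(replicate_means(dataset.modifications))
    z_q = z.loc["Q", t_mat.columns].astype(float)
    table = build_codon_table()
    q_codons = sorted(set(table.rule_sets["Q"]))
    r_mod = pd.Series(
        {
            c: float(np.corrcoef(t_mat.loc[c], z_q)[0, 1])
            for c in q_codons
            if t_mat.loc[c].notna().all()
        },
        name="r_vs_Q_zscore",
    )
    r_pair = pd.Series(
        {
            c: float(
                np.corrcoef(t_mat.loc[c], t_mat.loc[table.rule_sets["Q"][c]])[0, 1]
            )
            for c in NAC_CODONS
        },
        name="r_NAC_vs_NAT",
    )
    return r_mod, r_pair


def pause_recovery(
    dataset: SyntheticDataset,
    *,
    reference: str = "brain",
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Pause log2FC vs true dwell log-ratio, reference tissue vs every other.

    Returns the ``recovery_report`` rows for the pause layer (one Pearson r
    per tissue pair, over the eight Q-family codons).
    """
    table = build_codon_table()
    tables = {
        t: pause_scores(
            fp, dataset.cds, table, tissue=t, min_expected=min_expected
        )
        for t, fp in dataset.footprints.items()
    }
    lfc = {
        t: relative_pausing(tables[reference], tables[t])
        for t in tables
        if t != reference
    }
    return recovery_report(dataset, pause_log2fc=lfc, reference_tissue=reference)
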