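"""tRNA-modification abundance profiles: normalization, Z-scores, correlation.

LC-MS/MS peak areas are normalized to the summed UV signal of the four
canonical nucleosides (U, C, G, A) and expressed as *area ratios*.  Per
modification, tissue-level abundances (replicate means of area ratios) are
standardized across tissues into Z-scores — the number of sample standard
deviations a tissue sits above or below the across-tissue mean.  Pearson
correlation matrices over tissues (modification Z-profiles as features) or
over modifications summarize the tissue landscape.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Mapping

import numpy as np
import pandas as pd


class ModificationError(ValueError):
    """Invalid modification-profile input."""


def load_modification_catalog() -> pd.DataFrame:
    """Bundled catalogue of small-RNA modifications.

    Columns: abbreviation, full_name, occurrence (comma-separated RNA
    classes).  Used to label outputs and to filter tRNA-borne modifications.
    """
    ref = importlib.resources.files("codonmod.data") / "modification_catalog.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def trna_modifications(catalog: pd.DataFrame | None = None) -> list[str]:
    """Abbreviations of modifications occurring in tRNA."""
    cat = load_modification_catalog() if catalog is None else catalog
    mask = cat["occurrence"].str.contains("tRNA")
    return cat.loc[mask, "abbreviation"].tolist()


def normalize_peak_areas(
    raw: pd.Series | float, canonical: Mapping[str, float] | pd.Series
) -> pd.Series | float:
    """Area ratio: raw analyte peak area / sum of canonical U,C,G,A areas.

    Scale invariant — multiplying every area by a common factor leaves the
    ratios unchanged.
    """
    canon = pd.Series(canonical, dtype=float)
    missing = {"U", "C", "G", "A"} - set(canon.index)
    if missing:
        raise ModificationError(f"missing canonical areas: {sorted(missing)}")
    denom = float(canon[["U", "C", "G", "A"]].sum())
    if denom <= 0:
        raise ModificationError("canonical UV signal sum must be positive")
    return raw / denom


def replicate_means(long: pd.DataFrame) -> pd.DataFrame:
    """modification x tissue mean area ratios from a long replicate table.

    Expects columns ``modification, tissue, replicate, area_ratio``; tissue
    column order follows first appearance in the input.
    """
    required = {"modification", "tissue", "area_ratio"}
    if not required <= set(long.columns):
        raise ModificationError(f"missing columns: {sorted(required - set(long.columns))}")
    if (long["area_ratio"] < 0).any():
        raise ModificationError("area ratios must be non-negative")
    tissues = list(dict.fromkeys(long["tissue"]))
    means = (
        long.groupby(["modification", "tissue"], sort=False)["area_ratio"]
        .mean()
        .unstack("tissue")
    )
    return means[tissues]


def tissue_zscores(means: pd.DataFrame, *, log_transform: bool = False) -> pd.DataFrame:
    """Row-wise Z-scores of a modification x tissue abundance matrix.

    Each row is centered on its across-tissue mean and scaled by its sample
    SD.  Constant rows become all-zero with a warning (kept rectangular for
    downstream heat-table exports).  ``log_transform`` applies log2 before
    standardizing (requires strictly positive values).
    """
    if means.shape[1] < 2:
        raise ModificationError("Z-scores need at least 2 tissues")
    values = means.astype(float)
    if log_transform:
        if (values <= 0).any().any():
            raise ModificationError("log transform requires positive abundances")
        values = np.log2(values)
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant abundance rows set to Z=0: {list(values.index[constant])}",
            stacklevel=2,
        )
    z = values.sub(mu, axis=0).div(sd.where(~constant), axis=0)
    return z.fillna(0.0) if constant.any() else z


def pearson_matrix(matrix: pd.DataFrame, axis: str = "tissues") -> pd.DataFrame:
    """Pairwise Pearson correlation matrix.

    ``axis="tissues"`` correlates columns (each tissue's profile over
    modifications); ``axis="modifications"`` correlates rows.  Pairwise
    complete observations, minimum 3 per pair; zero-variance vectors yield
    NaN against all partners, with the unit diagonal restored.
    """
    if axis == "tissues":
        df = matrix
    elif axis == "modifications":
        df = matrix.T
    else:
        raise ModificationError(f"unknown axis {axis!r}")
    r = df.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    return r
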