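"""A-site occupancy (pause) scores from ribosome footprints.

A ribosome-protected fragment's A-site — the codon being decoded — is
located by a fixed per-length 5' offset (15 nt for 27–30 nt fragments,
16 for 31–33, 17 for 34–35; standard ribosome geometry, configurable).
Footprints whose A-site lands out of frame or outside the CDS are dropped.

The per-codon pause score is observed/expected A-site occupancy:

    observed_c = assignable footprints whose A-site codon is c
    expected_c = sum over genes of (gene's assignable footprints
                 x gene's fraction of observable codons that are c)
    score_c    = observed_c / expected_c

Expected counts are codon occurrences weighted by each gene's footprint
total (a single deeply covered gene cannot dominate the composition; an
unweighted pooled-composition mode is available), and only codon positions
an A-site can reach contribute: the offset geometry makes the first ~5 and
last few codons of every CDS unobservable, so they are excluded from the
composition — the initiator and STOP codons in particular never receive a
score.  Scores above 1 mark
slow, dwelled-upon codons.  Between two tissues the comparison is
log2(score_A / score_B); **negative log2FC means faster decoding (less
dwelling) in tissue A**.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import CodingSequence, CodonTable

logger = logging.getLogger(__name__)

#: 5' offset of the A-site by fragment length.
DEFAULT_OFFSETS: dict[int, int] = {
    **{n: 15 for n in range(27, 31)},
    **{n: 16 for n in range(31, 34)},
    **{n: 17 for n in range(34, 36)},
}


class PausingError(ValueError):
    """Invalid footprint/pause-table input."""


@dataclass(frozen=True)
class FootprintRecord:
    """One ribosome-protected fragment on a CDS (0-based 5' start)."""

    gene_id: str
    start: int
    length: int


def assign_asite(
    start: int,
    length: int,
    cds_length: int,
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> int | None:
    """Codon index of the footprint's A-site, or None if unassignable.

    Unassignable: fragment length absent from the offset table, A-site
    nucleotide out of frame (not a multiple of 3 on the CDS), or the
    footprint/A-site outside the CDS.
    """
    if start < 0 or start + length > cds_length:
        return None
    offset = offsets.get(length)
    if offset is None:
        return None
    nt = start + offset
    if nt % 3 != 0 or nt >= cds_length:
        return None
    return nt // 3


def read_footprints(path) -> pd.DataFrame:
    """Footprint TSV with columns gene_id, start, length."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "start", "length"}
    if not required <= set(df.columns):
        raise PausingError(f"missing columns: {sorted(required - set(df.columns))}")
    return df


def pause_scores(
    footprints: pd.DataFrame,
    cds_list: Sequence[CodingSequence],
    table: CodonTable,
    *,
    tissue: str = "",
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
    min_expected: float = 5.0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-codon observed/expected A-site occupancy for one tissue.

    Returns a 64-codon frame with columns observed, expected, score;
    codons with ``expected < min_expected`` have NaN score.  The frame's
    ``attrs`` record tissue, assignable and dropped footprint counts.
    """
    cds_by_id = {c.gene_id: c for c in cds_list}
    unknown = sorted(set(footprints["gene_id"]) - set(cds_by_id))
    if unknown:
        raise PausingError(f"footprints reference unknown gene_ids: {unknown[:10]}")

    codons = list(table.codons)
    codon_pos = {c: i for i, c in enumerate(codons)}
    # observable codon-index window implied by the offset table: an A-site
    # needs 3i >= min offset and room for the shortest fragment tail
    min_offset = min(offsets.values())
    min_tail = min(length - off for length, off in offsets.items())
    i_min = -(-min_offset // 3)
    # per-gene codon composition over observable positions only
    comp: dict[str, np.ndarray] = {}
    seq_codons: dict[str, list[str]] = {}
    for gid, cds in cds_by_id.items():
        cl = list(cds.codons())
        seq_codons[gid] = cl
        i_max = (len(cds.sequence) - min_tail) // 3
        vec = np.zeros(64, dtype=np.int64)
        for c in cl[i_min : i_max + 1]:
            vec[codon_pos[c]] += 1
        comp[gid] = vec

    observed = np.zeros(64, dtype=np.int64)
    per_gene_assigned: dict[str, int] = {}
    dropped = 0
    starts = footprints["start"].to_numpy(int)
    lengths = footprints["length"].to_numpy(int)
    gene_ids = footprints["gene_id"].to_numpy(object)
    for gid, start, length in zip(gene_ids, starts, lengths):
        idx = assign_asite(int(start), int(length), len(cds_by_id[gid].sequence), offsets)
        if idx is None:
            dropped += 1
            continue
        observed[codon_pos[seq_codons[gid][idx]]] += 1
        per_gene_assigned[gid] = per_gene_assigned.get(gid, 0) + 1

    assignable = int(observed.sum())
    if assignable == 0:
        raise PausingError("no assignable footprints")
    if dropped:
        logger.info("%s: dropped %d unassignable footprints", tissue or "pause", dropped)

    if weighted:
        expected = np.zeros(64, dtype=float)
        for gid, n_fp in per_gene_assigned.items():
            vec = comp[gid]
            expected += n_fp * vec / vec.sum()
    else:
        pooled = np.zeros(64, dtype=np.int64)
        for gid in per_gene_assigned:
            pooled += comp[gid]
        expected = assignable * pooled / pooled.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(expected >= min_expected, observed / expected, np.nan)
    out = pd.DataFrame(
        {"observed": observed, "expected": expected, "score": score}, index=codons
    )
    out.index.name = "codon"
    out.attrs.update(
        tissue=tissue, assignable=assignable, dropped=dropped, min_expected=min_expected
    )
    return out


def relative_pausing(pause_a: pd.DataFrame, pause_b: pd.DataFrame) -> pd.Series:
    """Per-codon log2 fold change of pause scores, tissue A vs tissue B.

    Negative values = less dwelling (faster decoding) in A.  Codons with an
    undefined or non-positive score in either table are NaN.
    """
    if not pause_a.index.equals(pause_b.index):
        raise PausingError("pause tables cover different codon sets")
    ta, tb = pause_a.attrs.get("tissue"), pause_b.attrs.get("tissue")
    if ta and tb and ta == tb:
        raise PausingError(f"both pause tables labelled tissue {ta!r}")
    a, b = pause_a["score"], pause_b["score"]
    valid = (a > 0) & (b > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2(a.where(valid) / b.where(valid))
    lfc.name = f"log2FC_{ta or 'A'}_vs_{tb or 'B'}"
    return lfc


def asite_bed(
    footprints: pd.DataFrame,
    cds_list: Sequence[CodingSequence],
    offsets: Mapping[int, int] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """BED-like table of assigned A-site codon intervals (0-based, half-open)."""
    cds_by_id = {c.gene_id: c for c in cds_list}
    rows = []
    for rec in footprints.itertuples(index=False):
        idx = assign_asite(
            int(rec.start), int(rec.length), len(cds_by_id[rec.gene_id].sequence), offsets
        )
        if idx is None:
            continue
        rows.append((rec.gene_id, 3 * idx, 3 * idx + 3))
    return pd.DataFrame(rows, columns=["gene_id", "start", "end"])
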