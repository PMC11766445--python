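"""Genetic-code data structures, translation, and codon counting.

Everything downstream (frequency metrics, pausing, recoding, simulation)
consumes the :class:`CodonTable` built here.  The internal alphabet is DNA
(T); RNA input (U) is mapped to T at parse time, and codon labels may be
rendered with U for display.

The wobble-modification rule sets wired into the table are the ones relevant
to queuosine (Q) and the mcm5U cluster:

* ``Q``     — the eight NAY codons AAC/AAT (Asn), GAC/GAT (Asp),
  CAC/CAT (His), TAC/TAT (Tyr), decoded by Q-modified G34 tRNAs.
* ``manQ``  — mannosyl-Q, Asp GAC/GAT only.
* ``galQ``  — galactosyl-Q, Tyr TAC/TAT only.
* ``mcm5U`` — the five codons CAA, AAA, GAA, GGA, GCA read by
  mcm5U-modified U34 tRNAs (no swap-partner mapping beyond their families).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_BASES = "ACGT"

#: Q-modified tRNAs read both members of each NAY pair; keys and values are
#: the C-ending and T-ending partners, merged into one symmetric mapping.
Q_PAIRS: dict[str, str] = {
    "AAC": "AAT", "AAT": "AAC",
    "GAC": "GAT", "GAT": "GAC",
    "CAC": "CAT", "CAT": "CAC",
    "TAC": "TAT", "TAT": "TAC",
}

MANQ_PAIRS: dict[str, str] = {"GAC": "GAT", "GAT": "GAC"}
GALQ_PAIRS: dict[str, str] = {"TAC": "TAT", "TAT": "TAC"}
MCM5U_CODONS: tuple[str, ...] = ("CAA", "AAA", "GAA", "GGA", "GCA")


class GeneticCodeError(ValueError):
    """Invalid sequence or configuration passed to the genetic-code layer."""


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code plus the modification rule sets.

    Attributes
    ----------
    codon_to_aa
        64 trinucleotides -> one-letter amino acid or ``*`` for STOP.
    families
        amino acid -> tuple of synonymous codons, lexicographic order.
    third_position_class
        codon -> ``"AT_ending"`` or ``"GC_ending"``.
    rule_sets
        modification name -> mapping of affected codons.  For Q/manQ/galQ
        the mapping is codon -> synonymous swap partner; for mcm5U the
        mapping is codon -> codon (identity; the family carries >2 members
        so no canonical partner exists).
    alphabet
        ``"DNA"`` or ``"RNA"`` — how codon labels are rendered.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    third_position_class: Mapping[str, str]
    rule_sets: Mapping[str, Mapping[str, str]]
    alphabet: str = "DNA"
    codons: tuple[str, ...] = field(default=())

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.codons if self.codon_to_aa[c] != "*")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.codons if self.codon_to_aa[c] == "*")

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous codons of ``codon``'s amino acid (codon included)."""
        aa = self.codon_to_aa[codon]
        if aa == "*":
            raise GeneticCodeError(f"{codon} is a STOP codon; no family")
        return self.families[aa]

    def display(self, codon: str) -> str:
        """Codon label in the table's alphabet (T -> U in RNA mode)."""
        return codon.replace("T", "U") if self.alphabet == "RNA" else codon


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame CDS for one gene. Uppercase DNA, length divisible by 3."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3 or len(seq) % 3 != 0:
            raise GeneticCodeError(
                f"{self.gene_id}: CDS length {len(seq)} is not a positive "
                "multiple of 3"
            )
        if set(seq) - set(DNA_BASES):
            bad = sorted(set(seq) - set(DNA_BASES))
            raise GeneticCodeError(f"{self.gene_id}: invalid characters {bad}")

    def codons(self) -> Iterator[str]:
        seq = self.sequence
        for i in range(0, len(seq), 3):
            yield seq[i : i + 3]

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


def build_codon_table(alphabet: str = "DNA") -> CodonTable:
    """Build the standard genetic code with modification rule sets.

    Codon ordering is lexicographic over {A,C,G,T}; the ordering is stable
    across calls so every downstream table shares it.
    """
    if alphabet not in ("DNA", "RNA"):
        raise GeneticCodeError(f"unknown alphabet {alphabet!r}; use DNA or RNA")

    std = _BioCodonTable.unambiguous_dna_by_id[1]
    codons = tuple("".join(p) for p in itertools.product(DNA_BASES, repeat=3))
    codon_to_aa = {
        c: ("*" if c in std.stop_codons else std.forward_table[c]) for c in codons
    }

    families: dict[str, tuple[str, ...]] = {}
    for codon in codons:  # codons already lexicographic
        aa = codon_to_aa[codon]
        if aa == "*":
            continue
        families[aa] = families.get(aa, ()) + (codon,)

    third = {
        c: ("AT_ending" if c[2] in "AT" else "GC_ending") for c in codons
    }

    rule_sets: dict[str, Mapping[str, str]] = {
        "Q": dict(Q_PAIRS),
        "manQ": dict(MANQ_PAIRS),
        "galQ": dict(GALQ_PAIRS),
        "mcm5U": {c: c for c in MCM5U_CODONS},
    }

    return CodonTable(
        codon_to_aa=codon_to_aa,
        families=families,
        third_position_class=third,
        rule_sets=rule_sets,
        alphabet=alphabet,
        codons=codons,
    )


def translate(cds: CodingSequence, table: CodonTable, *, strict: bool = True) -> str:
    """Translate an in-frame CDS.

    A terminal STOP is dropped.  An internal STOP raises
    :class:`GeneticCodeError` unless ``strict=False``, in which case it is
    rendered as ``*``.
    """
    aas = [table.codon_to_aa[c] for c in cds.codons()]
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas and strict:
        idx = aas.index("*")
        raise GeneticCodeError(
            f"{cds.gene_id}: internal STOP at codon index {idx}"
        )
    return "".join(aas)


def count_codons(
    cds: CodingSequence,
    table: CodonTable,
    *,
    exclude_stop: bool = False,
    exclude_initiator: bool = False,
) -> dict[str, int]:
    """Per-codon occurrence counts over all 64 codons.

    Counts sum to ``len(cds)/3`` (minus exclusions).  By default every codon
    is counted, including STOPs and the initiator; the frequency metrics
    apply their own STOP exclusion.
    """
    counts = dict.fromkeys(table.codons, 0)
    for i, codon in enumerate(cds.codons()):
        if exclude_initiator and i == 0:
            continue
        counts[codon] += 1
    if exclude_stop:
        for stop in table.stop_codons:
            counts[stop] = 0
    return counts


# ---------------------------------------------------------------------------
# FASTA I/O


def read_cds_fasta(
    path, *, strict: bool = False
) -> list[CodingSequence]:
    """Read a CDS FASTA (record id = gene_id), case-insensitive, U -> T.

    Records failing the frame/alphabet check are skipped with a warning, or
    abort the whole read when ``strict=True``.
    """
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(CodingSequence(rec.id, str(rec.seq)))
        except GeneticCodeError as exc:
            if strict:
                raise
            warnings.warn(f"skipping record {rec.id}: {exc}", stacklevel=2)
            logger.warning("skipping record %s: %s", rec.id, exc)
    return out


def write_cds_fasta(path, cds_list: Iterable[CodingSequence]) -> None:
    """Write CDS records as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.gene_id, description="")
        for c in cds_list
    ]
    SeqIO.write(records, str(path), "fasta")
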