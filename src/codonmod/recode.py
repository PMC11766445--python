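"""Synonymous recoding of queuosine-family codons and a profile-guided recoder.

Queuosine-modified tRNAs read both members of each two-codon NAY family
(Asn AAC/AAT, Asp GAC/GAT, His CAC/CAT, Tyr TAC/TAT), but decode the
C-ending member faster when the modification is abundant.  The mutator
swaps the third position of the selected families wholesale (C -> T or
T -> C) while leaving the protein untouched.

``profile_guided_recode`` generalizes this: a rule names a modification and
a synonymous family, with a codon preferred when the tissue's modification
Z-score clears a threshold and an alternative otherwise.  Families larger
than two codons (the mcm5U set) are supported through explicit preferred
codons, since "ending" is ambiguous there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genetic_code import (
    CodingSequence,
    CodonTable,
    GeneticCodeError,
    translate,
)

#: amino acids with queuosine-modified tRNAs, one-letter codes
Q_AMINO_ACIDS = ("N", "D", "H", "Y")

_DIRECTIONS = {"C_to_U": ("C", "T"), "U_to_C": ("T", "C")}


class RecodeError(ValueError):
    """Invalid recoding request."""


@dataclass(frozen=True)
class MutationReport:
    """What a recoding changed and proof it was synonymous."""

    gene_id: str
    n_codons_changed: int
    changes_by_amino_acid: Mapping[str, int]
    changed_positions: tuple[tuple[int, str, str], ...]  # (codon index, old, new)
    protein_identical: bool

    def to_rows(self) -> list[dict]:
        return [
            {
                "gene_id": self.gene_id,
                "codon_index": i,
                "old_codon": old,
                "new_codon": new,
            }
            for i, old, new in self.changed_positions
        ]


def _apply_changes(
    cds: CodingSequence,
    table: CodonTable,
    replacement: Mapping[int, str],
) -> tuple[CodingSequence, MutationReport]:
    codons = list(cds.codons())
    changes: list[tuple[int, str, str]] = []
    by_aa: dict[str, int] = {}
    for idx, new in replacement.items():
        old = codons[idx]
        if new == old:
            continue
        if table.codon_to_aa[new] != table.codon_to_aa[old]:
            raise RecodeError(
                f"{cds.gene_id}: non-synonymous change {old}->{new} at {idx}"
            )
        codons[idx] = new
        changes.append((idx, old, new))
        aa = table.codon_to_aa[old]
        by_aa[aa] = by_aa.get(aa, 0) + 1
    mutated = CodingSequence(cds.gene_id, "".join(codons))
    identical = translate(mutated, table, strict=False) == translate(
        cds, table, strict=False
    )
    if not identical:
        raise RecodeError(f"{cds.gene_id}: recoding altered the protein")
    report = MutationReport(
        gene_id=cds.gene_id,
        n_codons_changed=len(changes),
        changes_by_amino_acid=by_aa,
        changed_positions=tuple(sorted(changes)),
        protein_identical=identical,
    )
    return mutated, report


def mutate_q_codons(
    cds: CodingSequence,
    table: CodonTable,
    subset: Iterable[str] | str = "ALL",
    direction: str = "C_to_U",
) -> tuple[CodingSequence, MutationReport]:
    """Swap the third position of Q-family codons for the chosen amino acids.

    ``subset`` is a set of one-letter codes drawn from N/D/H/Y, or ``"ALL"``.
    ``direction="C_to_U"`` rewrites NAC -> NAT; ``"U_to_C"`` the reverse.
    Only third positions change, and the protein is verified unchanged.
    """
    if direction not in _DIRECTIONS:
        raise RecodeError(f"unknown direction {direction!r}; use C_to_U or U_to_C")
    src, dst = _DIRECTIONS[direction]
    if isinstance(subset, str) and subset.upper() == "ALL":
        chosen = set(Q_AMINO_ACIDS)
    else:
        chosen = {s.upper() for s in subset}
        bad = chosen - set(Q_AMINO_ACIDS)
        if bad:
            raise RecodeError(
                f"subset must be within {Q_AMINO_ACIDS}; got {sorted(bad)}"
            )
    q_rules = table.rule_sets["Q"]
    replacement: dict[int, str] = {}
    for idx, codon in enumerate(cds.codons()):
        if codon in q_rules and table.codon_to_aa[codon] in chosen and codon[2] == src:
            replacement[idx] = codon[:2] + dst
    return _apply_changes(cds, table, replacement)


@dataclass(frozen=True)
class RecodeRule:
    """One profile-guided rule: a modification steering one family.

    When the modification's Z-score is >= the threshold, every codon of the
    family becomes ``preferred``; otherwise ``alternative``.
    """

    modification: str
    amino_acid: str
    preferred: str
    alternative: str


def default_q_rules(table: CodonTable) -> tuple[RecodeRule, ...]:
    """Q rules for the four NAY families: prefer C-ending when Q is high."""
    rules = []
    for aa in Q_AMINO_ACIDS:
        fam = table.families[aa]
        c_end = next(c for c in fam if c[2] == "C")
        t_end = next(c for c in fam if c[2] == "T")
        rules.append(RecodeRule("Q", aa, c_end, t_end))
    return tuple(rules)


def profile_guided_recode(
    cds: CodingSequence,
    table: CodonTable,
    zscores: Mapping[str, float],
    rules: Sequence[RecodeRule] | None = None,
    threshold: float = 0.0,
) -> tuple[CodingSequence, MutationReport]:
    """Rewrite families to their modification-preferred codons.

    For each rule, all codons of the rule's family are rewritten to the
    preferred codon iff ``zscores[rule.modification] >= threshold``, else to
    the alternative.  Deterministic and translation-invariant.
    """
    if rules is None:
        rules = default_q_rules(table)
    target_by_codon: dict[str, str] = {}
    for rule in rules:
        fam = table.families.get(rule.amino_acid)
        if fam is None:
            raise RecodeError(f"unknown amino acid {rule.amino_acid!r}")
        if len(fam) < 2:
            raise RecodeError(
                f"rule on single-codon family {rule.amino_acid!r} is not recodable"
            )
        for codon in (rule.preferred, rule.alternative):
            if codon not in fam:
                raise RecodeError(
                    f"{codon} is not a synonymous codon for {rule.amino_acid}"
                )
        if rule.modification not in zscores:
            raise RecodeError(f"no Z-score supplied for {rule.modification!r}")
        target = (
            rule.preferred
            if zscores[rule.modification] >= threshold
            else rule.alternative
        )
        for codon in fam:
            target_by_codon[codon] = target
    replacement = {
        idx: target_by_codon[codon]
        for idx, codon in enumerate(cds.codons())
        if codon in target_by_codon
    }
    return _apply_changes(cds, table, replacement)


def gc_content(cds: CodingSequence) -> float:
    seq = cds.sequence
    return (seq.count("G") + seq.count("C")) / len(seq)
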