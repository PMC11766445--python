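"""Synonymous recoding of queuosine-family codons.

Swaps NAC <-> NAT third positions for chosen amino-acid subsets without
touching the protein, and shows the modification-profile-guided recoder
picking codon endings from a tissue's Z-scores.
"""

from codonmod import (
    CodingSequence,
    build_codon_table,
    mutate_q_codons,
    profile_guided_recode,
    translate,
)

table = build_codon_table("DNA")
cds = CodingSequence(
    "demo", "ATG" + "AAC" "GAC" "CAC" "TAC" + "GGCGAGCTG" + "AACTAC" + "TAA"
)
print(f"input   : {cds.sequence}  protein {translate(table=table, cds=cds)}")

mutated, report = mutate_q_codons(cds, table, "ALL", "C_to_U")
print(f"C->U all: {mutated.sequence}  ({report.n_codons_changed} codons changed, "
      f"protein identical: {report.protein_identical})")

tyr_only, rep_tyr = mutate_q_codons(cds, table, {"Y"}, "C_to_U")
print(f"Tyr only: {tyr_only.sequence}  ({rep_tyr.n_codons_changed} changed)")

# profile-guided: a liver-like tissue with depleted queuosine prefers NAT
recoded, rep = profile_guided_recode(cds, table, {"Q": -1.2}, threshold=0.0)
print(f"Z_Q=-1.2: {recoded.sequence}  ({rep.n_codons_changed} changed)")
print("\nwith queuosine depleted the recoder chooses T-ending Q codons; with")
print("Z_Q above threshold it would restore the C-ending forms.")
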