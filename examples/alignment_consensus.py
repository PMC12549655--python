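"""Derive a conservative consensus from a pairwise protein alignment.

Columns: identical residues pass through; same-class substitutions keep
the query residue; cross-class substitutions become "X"; a single gap
keeps the present residue; double gaps stay "-".
"""

from gmimmune.consensus import (AlignedPair, alignment_metrics,
                                classify_column, derive_consensus)

pair = AlignedPair(query_id="insect_protein", subject_id="human_ortholog",
                   query_seq="MKTLR-DEAVSG",
                   subject_seq="MRTIKCDDAVTG")

cons = derive_consensus(pair)
print("query:    ", pair.query_seq)
print("subject:  ", pair.subject_seq)
print("outcome:  ", "".join(o[0] for o in cons.outcomes),
      "(i=identical c=conservative n=nonconservative s=single gap)")
print("consensus:", cons.sequence)

metrics = alignment_metrics(pair, query_full_length=22)
print(f"\nidentity {metrics['identity_pct']:.1f}% over "
      f"{metrics['aligned_columns']} columns, "
      f"query coverage {metrics['coverage_pct']:.1f}%")
print("\nK/R and L/I keep the query residue (same charge / hydrophobicity); "
      "R/K vs C-class or charge swaps become X; the gap column keeps C.")
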