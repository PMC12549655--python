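"""Rule-based conservative consensus from a pairwise protein alignment.

The alignment is parsed column by column: identical residues enter the
consensus directly; conservative substitutions (same physicochemical class)
retain the query residue; non-conservative substitutions are annotated "X";
a single-gap column retains the residue that is present; a double-gap
column emits "-".  Identity and query-coverage metrics follow the usual
pairwise-alignment conventions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError

# Column outcome labels.
IDENTICAL = "identical"
CONSERVATIVE = "conservative"
NONCONSERVATIVE = "nonconservative"
SINGLE_GAP = "single_gap"
DOUBLE_GAP = "double_gap"

#: Physicochemical classes of the 20 standard residues.  His is grouped
#: with the positively charged residues; Cys/Gly/Pro form the "special"
#: class.  Overridable via :func:`load_residue_classes`.
DEFAULT_RESIDUE_CLASSES: Dict[str, str] = {
    **{r: "hydrophobic" for r in "AVLIMFW"},
    **{r: "positive" for r in "KRH"},
    **{r: "negative" for r in "DE"},
    **{r: "polar_uncharged" for r in "STNQY"},
    **{r: "special" for r in "CGP"},
}

#: Ambiguity/non-standard codes accepted in input; they count as a
#: non-conservative partner unless the column is identical.
AMBIGUOUS_RESIDUES = frozenset("BZXUJO")

GAP = "-"
_LEGAL = set(DEFAULT_RESIDUE_CLASSES) | AMBIGUOUS_RESIDUES | {GAP}


@dataclass
class AlignedPair:
    """Two equal-length gapped protein sequences (query first)."""

    query_id: str
    subject_id: str
    query_seq: str
    subject_seq: str

    def __post_init__(self):
        self.query_seq = self.query_seq.upper()
        self.subject_seq = self.subject_seq.upper()
        if len(self.query_seq) != len(self.subject_seq):
            raise AlignmentFormatError(
                f"aligned lengths differ: {len(self.query_seq)} vs "
                f"{len(self.subject_seq)}")
        for name, seq in (("query", self.query_seq), ("subject", self.subject_seq)):
            illegal = sorted(set(seq) - _LEGAL)
            if illegal:
                raise AlignmentFormatError(
                    f"illegal characters in {name} sequence: {illegal}")

    def __len__(self) -> int:
        return len(self.query_seq)

    def columns(self):
        return zip(self.query_seq, self.subject_seq)


@dataclass
class ConsensusSequence:
    id: str
    sequence: str
    outcomes: List[str]

    def __post_init__(self):
        if len(self.sequence) != len(self.outcomes):
            raise ValueError("sequence/outcome length mismatch")


def load_residue_classes(path) -> Dict[str, str]:
    """Load a residue -> class map from YAML and validate it covers the 20
    standard residues exactly once each."""
    raw = yaml.safe_load(Path(path).read_text())
    classes = {str(r).upper(): str(c) for r, c in raw.items()}
    missing = sorted(set(DEFAULT_RESIDUE_CLASSES) - set(classes))
    if missing:
        raise ValueError(f"class map missing residues: {missing}")
    extra = sorted(set(classes) - set(DEFAULT_RESIDUE_CLASSES))
    if extra:
        raise ValueError(f"class map has non-standard residues: {extra}")
    return classes


def read_aligned_pair(path) -> AlignedPair:
    """Read an aligned FASTA of exactly two equal-length gapped records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise AlignmentFormatError(
            f"expected exactly 2 records in {path}, found {len(records)}")
    q, s = records
    return AlignedPair(query_id=q.id, subject_id=s.id,
                       query_seq=str(q.seq), subject_seq=str(s.seq))


def classify_column(q: str, s: str,
                    classes: Optional[Dict[str, str]] = None) -> str:
    """Outcome label of one alignment column."""
    classes = classes or DEFAULT_RESIDUE_CLASSES
    for symbol in (q, s):
        if symbol != GAP and symbol not in classes and symbol not in AMBIGUOUS_RESIDUES:
            raise AlignmentFormatError(f"unknown residue {symbol!r}")
    if q == GAP and s == GAP:
        return DOUBLE_GAP
    if q == GAP or s == GAP:
        return SINGLE_GAP
    if q == s:
        return IDENTICAL
    if q in classes and s in classes and classes[q] == classes[s]:
        return CONSERVATIVE
    return NONCONSERVATIVE


def derive_consensus(pair: AlignedPair,
                     classes: Optional[Dict[str, str]] = None) -> ConsensusSequence:
    """Apply the five column rules across the alignment."""
    classes = classes or DEFAULT_RESIDUE_CLASSES
    symbols: List[str] = []
    outcomes: List[str] = []
    for q, s in pair.columns():
        outcome = classify_column(q, s, classes)
        outcomes.append(outcome)
        if outcome in (IDENTICAL, CONSERVATIVE):
            symbols.append(q)
        elif outcome == NONCONSERVATIVE:
            symbols.append("X")
        elif outcome == SINGLE_GAP:
            symbols.append(s if q == GAP else q)
        else:
            symbols.append(GAP)
    return ConsensusSequence(id=f"consensus|{pair.query_id}|{pair.subject_id}",
                             sequence="".join(symbols), outcomes=outcomes)


def alignment_metrics(pair: AlignedPair,
                      query_full_length: Optional[int] = None) -> Dict[str, Optional[float]]:
    """Identity %, aligned-column count, and query coverage %.

    Identity is over columns where both sequences have a residue; coverage
    is the fraction of the full-length query present in the alignment.
    With no both-residue column, identity is undefined and reported None.
    """
    both = sum(1 for q, s in pair.columns() if q != GAP and s != GAP)
    identical = sum(1 for q, s in pair.columns() if q == s and q != GAP)
    ungapped_query = sum(1 for q in pair.query_seq if q != GAP)
    if query_full_length is not None and query_full_length < ungapped_query:
        raise ValueError("query_full_length smaller than aligned query residues")
    return {
        "identity_pct": (100.0 * identical / both) if both else None,
        "aligned_columns": len(pair),
        "coverage_pct": (100.0 * ungapped_query / query_full_length
                         if query_full_length else None),
    }


def write_consensus_fasta(consensus: ConsensusSequence, path) -> None:
    record = SeqRecord(Seq(consensus.sequence), id=consensus.id, description="")
    SeqIO.write([record], str(path), "fasta")


def write_column_table(pair: AlignedPair, consensus: ConsensusSequence, path) -> None:
    """Per-column TSV: position, query, subject, outcome, consensus symbol."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "query", "subject", "outcome", "consensus"])
        for i, ((q, s), outcome, c) in enumerate(
                zip(pair.columns(), consensus.outcomes, consensus.sequence), 1):
            writer.writerow([i, q, s, outcome, c])
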