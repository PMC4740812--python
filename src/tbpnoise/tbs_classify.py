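"""TATA-box / TATA-like classification of TBP-binding sites (TBS).

A TBS is an 8-bp promoter element scored against the canonical yeast
TATA-box consensus ``TATAWAWR`` (IUPAC: W = A/T, R = A/G).  Exact matches
are TATA-box sites, one or two mismatches make a TATA-like site, and
three or more mismatches leave the sequence unclassified ("other").
TATA-box sites are further split by the base at motif position 5
(1-based): the T5 subset carries a thymine there, the A5 subset an
adenine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CONSENSUS",
    "IUPAC",
    "TBSRecord",
    "count_mismatches",
    "classify_tbs",
    "scan_promoter",
    "classify_fasta",
]

#: Canonical yeast TATA-box consensus (8 bp).
CONSENSUS = "TATAWAWR"

#: IUPAC nucleotide codes used in consensus patterns.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

TATA_BOX = "TATA-box"
TATA_LIKE = "TATA-like"
OTHER = "other"


@dataclass(frozen=True)
class TBSRecord:
    """One gene's best TBS window and its classification."""

    gene_id: str
    sequence: str
    tbs_class: str
    subset: str  # "T5", "A5" or "none"
    mismatches: int
    offset: int | None = None  # 0-based window start within the promoter
    strand: str = "+"


def _validate_seq(seq: str, length: int | None = 8) -> str:
    seq = seq.upper()
    if length is not None and len(seq) != length:
        raise ValueError(f"expected a {length}-mer, got {len(seq)} bases")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return seq


def count_mismatches(seq: str, consensus: str = CONSENSUS) -> int:
    """Number of positions where ``seq`` violates the IUPAC consensus."""
    seq = _validate_seq(seq, length=len(consensus))
    try:
        sets = [IUPAC[c] for c in consensus.upper()]
    except KeyError as err:
        raise ValueError(f"invalid IUPAC code in consensus: {err}") from err
    return sum(base not in allowed for base, allowed in zip(seq, sets))


def classify_tbs(
    seq: str, consensus: str = CONSENSUS
) -> tuple[str, str, int]:
    """Classify an 8-mer as (tbs_class, subset, mismatches).

    Zero mismatches to the consensus is a TATA-box, one or two a
    TATA-like site, three or more "other".  The T5/A5 subset is assigned
    only for exact TATA-box matches, from the base at position 5.
    """
    mm = count_mismatches(seq, consensus)
    if mm == 0:
        subset = "T5" if seq.upper()[4] == "T" else "A5"
        return TATA_BOX, subset, mm
    if mm <= 2:
        return TATA_LIKE, "none", mm
    return OTHER, "none", mm


def scan_promoter(
    sequence: str,
    gene_id: str = "",
    consensus: str = CONSENSUS,
    both_strands: bool = False,
) -> TBSRecord:
    """Locate the best-matching TBS window in a promoter sequence.

    Slides the consensus over every window, returns the one with the
    fewest mismatches; ties go to the smallest offset (forward strand
    preferred when scanning both strands).  Offsets are 0-based on the
    forward strand.
    """
    sequence = _validate_seq(sequence, length=None)
    k = len(consensus)
    if len(sequence) < k:
        raise ValueError(
            f"promoter ({len(sequence)} bp) shorter than the {k}-bp motif"
        )
    candidates = [(sequence, "+")]
    if both_strands:
        candidates.append((str(Seq(sequence).reverse_complement()), "-"))
    best: tuple[int, int, str, str] | None = None  # (mm, offset, window, strand)
    for strand_seq, strand in candidates:
        for off in range(len(strand_seq) - k + 1):
            window = strand_seq[off : off + k]
            mm = count_mismatches(window, consensus)
            fwd_off = off if strand == "+" else len(sequence) - k - off
            if best is None or mm < best[0]:
                best = (mm, fwd_off, window, strand)
    assert best is not None
    mm, offset, window, strand = best
    tbs_class, subset, _ = classify_tbs(window, consensus)
    return TBSRecord(
        gene_id=gene_id,
        sequence=window,
        tbs_class=tbs_class,
        subset=subset,
        mismatches=mm,
        offset=offset,
        strand=strand,
    )


def classify_fasta(
    fasta_path: str | Path,
    consensus: str = CONSENSUS,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Scan every promoter in a FASTA file; one row per record.

    Columns: gene_id, offset, sequence, tbs_class, subset, mismatches,
    strand.
    """
    rows = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        rec = scan_promoter(
            str(record.seq),
            gene_id=record.id,
            consensus=consensus,
            both_strands=both_strands,
        )
        rows.append(
            {
                "gene_id": rec.gene_id,
                "offset": rec.offset,
                "sequence": rec.sequence,
                "tbs_class": rec.tbs_class,
                "subset": rec.subset,
                "mismatches": rec.mismatches,
                "strand": rec.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "offset",
            "sequence",
            "tbs_class",
            "subset",
            "mismatches",
            "strand",
        ],
    )
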