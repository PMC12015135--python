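"""Built-in star alignment fallback.

Conservation scoring normally consumes a pre-computed family alignment
(Clustal or aligned FASTA). This module provides a minimal star
alignment — global pairwise alignment of every member to a chosen
reference under BLOSUM62, merged on reference coordinates — so small
workflows and tests can run without an external aligner. It is off by
default in the pipeline and is not a substitute for a proper progressive
aligner on divergent families.
"""

from __future__ import annotations

from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .io import aligned_family_from_rows
from .model import GAP, AlignedFamily


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def star_align(
    sequences: dict[str, str],
    family_name: str = "family",
    reference: Optional[str] = None,
) -> AlignedFamily:
    """Star-align ``sequences`` around a reference member.

    The reference defaults to the longest sequence. Each member is
    globally aligned to the reference; insertions relative to the
    reference are merged by taking, per reference gap slot, the maximum
    insertion length over members.
    """
    if len(sequences) < 2:
        raise ValueError("star alignment needs at least two sequences")
    if reference is None:
        reference = max(sequences, key=lambda k: (len(sequences[k]), k))
    ref_seq = sequences[reference]
    Lr = len(ref_seq)
    aligner = _make_aligner()

    # Per member: chars matched to each reference position (or '-') and
    # insertion strings in each of the Lr+1 between-reference slots.
    matched: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    for kid, seq in sequences.items():
        if kid == reference:
            matched[kid] = list(ref_seq)
            inserts[kid] = [""] * (Lr + 1)
            continue
        aln = aligner.align(ref_seq, seq)[0]
        ref_row, mem_row = str(aln[0]), str(aln[1])
        m = [GAP] * Lr
        ins = [""] * (Lr + 1)
        ri = 0  # reference positions consumed
        for rc, mc in zip(ref_row, mem_row):
            if rc == GAP:
                if mc != GAP:
                    ins[ri] += mc
            else:
                if mc != GAP:
                    m[ri] = mc
                ri += 1
        matched[kid] = m
        inserts[kid] = ins

    slot_width = [max(len(inserts[k][i]) for k in sequences) for i in range(Lr + 1)]
    aligned: dict[str, str] = {}
    for kid in sequences:
        parts: list[str] = []
        for i in range(Lr):
            parts.append(inserts[kid][i].ljust(slot_width[i], GAP))
            parts.append(matched[kid][i])
        parts.append(inserts[kid][Lr].ljust(slot_width[Lr], GAP))
        aligned[kid] = "".join(parts)
    return aligned_family_from_rows(family_name, aligned)
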