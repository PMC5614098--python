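"""Acceptance of cluster-level domain matches and their transfer to member
sequences via the subalignment E-value.

Domain matches (Pfam/SCOP/PDB-style, produced by any external homology
search) are accepted greedily in order of increasing E-value, rejecting
matches that overlap already-annotated regions of the same database by 10%
or more of their own span. An accepted cluster annotation is transferred to
a member only when the member's subalignment to the consensus over the
annotated span is itself significant:

    E_subali = E_domain + K * L_consensus * exp(-lambda * s_subali) < 0.01

where s_subali is the BLOSUM62 score of the member-vs-consensus
subalignment read off the cluster MSA, and K, lambda are Karlin-Altschul
constants for gapped BLOSUM62 statistics. The exponent decreases with
alignment quality, so strong subalignments contribute a vanishing term and
E_subali approaches E_domain from above; a ``literal_formula`` switch with
the opposite sign is provided for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

from .align import KARLIN_K, KARLIN_LAMBDA, SubstitutionMatrix, blosum62
from .core_io import DomainAnnotation, ProteinSequence
from .msa import ConsensusRecord, Msa


@dataclass(frozen=True)
class TransferParams:
    """Constants of the acceptance and transfer rules."""

    K: float = KARLIN_K
    lam: float = KARLIN_LAMBDA
    evalue_cutoff: float = 0.01
    max_overlap_frac: float = 0.10
    literal_formula: bool = False

    def __post_init__(self) -> None:
        if min(self.K, self.lam, self.evalue_cutoff, self.max_overlap_frac) <= 0:
            raise ValueError("all transfer parameters must be positive")
        if self.max_overlap_frac >= 1:
            raise ValueError("max_overlap_frac must be < 1")


def _overlap(start: int, end: int, intervals: List[tuple]) -> int:
    """Total residues of [start, end] covered by a set of intervals."""
    covered = 0
    for s, e in intervals:
        lo = max(start, s)
        hi = min(end, e)
        if lo <= hi:
            covered += hi - lo + 1
    return covered


def _merge_interval(intervals: List[tuple], start: int, end: int) -> List[tuple]:
    merged = sorted(intervals + [(start, end)])
    out = [merged[0]]
    for s, e in merged[1:]:
        if s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def accept_annotations(
    matches: Sequence[DomainAnnotation],
    params: TransferParams | None = None,
) -> List[DomainAnnotation]:
    """Greedy per-database acceptance of domain matches on one query.

    Matches are processed in order of increasing E-value (ties: longer
    aligned span, then target ID) and accepted iff the E-value is below the
    cutoff and the match overlaps already-accepted regions by less than
    ``max_overlap_frac`` of its own query span. All matches must share one
    query and one database.
    """
    params = params or TransferParams()
    if not matches:
        return []
    queries = {m.query_id for m in matches}
    if len(queries) > 1:
        raise ValueError(f"mixed query IDs: {sorted(queries)}")
    databases = {m.database for m in matches}
    if len(databases) > 1:
        raise ValueError(
            f"mixed databases {sorted(databases)}; accept per database to "
            "avoid multiple annotations of a region"
        )
    for m in matches:
        m.validate()
    ordered = sorted(matches, key=lambda m: (m.evalue, -m.q_span_len, m.target_id))
    accepted: List[DomainAnnotation] = []
    covered: List[tuple] = []
    for m in ordered:
        if not m.evalue < params.evalue_cutoff:
            continue
        overlap = _overlap(m.q_start, m.q_end, covered)
        if overlap / m.q_span_len < params.max_overlap_frac:
            accepted.append(m)
            covered = _merge_interval(covered, m.q_start, m.q_end)
    return accepted


def subalignment_evalue(
    e_domain: float,
    s_subali: float,
    length_consensus: int,
    params: TransferParams | None = None,
) -> float:
    """E-value of a member/consensus subalignment under a domain match.

    Strictly decreasing in ``s_subali`` and increasing in ``e_domain`` and
    ``length_consensus``; always >= ``e_domain``.
    """
    params = params or TransferParams()
    if length_consensus < 1:
        raise ValueError("length_consensus must be >= 1")
    sign = 1.0 if params.literal_formula else -1.0
    return e_domain + params.K * length_consensus * math.exp(
        sign * params.lam * s_subali
    )


def _member_coordinates(row: str):
    """Per-column member residue index (1-based) or 0, plus residue chars.

    Columns are the A3M match columns; lowercase insertions advance the
    member coordinate without occupying a column.
    """
    col_residue: List[str] = []
    col_pos: List[int] = []
    pos = 0
    for c in row:
        if c == "-":
            col_residue.append("-")
            col_pos.append(0)
        elif c.isupper():
            pos += 1
            col_residue.append(c)
            col_pos.append(pos)
        else:  # lowercase insertion
            pos += 1
    return col_residue, col_pos, pos


def transfer_annotations(
    cluster_annots: Sequence[DomainAnnotation],
    msa: Msa,
    consensus: ConsensusRecord,
    members: Sequence[ProteinSequence],
    matrix: SubstitutionMatrix | None = None,
    params: TransferParams | None = None,
) -> List[DomainAnnotation]:
    """Transfer accepted cluster annotations to member sequences.

    For each member and accepted annotation, the subalignment score is the
    sum of substitution-matrix scores between member and consensus over the
    annotated match columns where the member has a residue; the annotation
    is emitted (with query coordinates mapped through the alignment onto
    the member) iff the subalignment E-value is below the cutoff. Members
    with no residue in the span are skipped.
    """
    matrix = matrix or blosum62()
    params = params or TransferParams()
    L = len(consensus.residues)
    if L != msa.n_match_columns:
        raise ValueError("consensus length does not match the alignment")
    by_acc = {m.accession: m for m in members}
    out: List[DomainAnnotation] = []
    for ann in cluster_annots:
        if ann.q_end > L:
            raise ValueError(
                f"annotation span {ann.q_start}-{ann.q_end} outside "
                f"consensus of length {L}"
            )
    for acc, row in msa.records:
        if acc not in by_acc:
            continue
        member = by_acc[acc]
        col_residue, col_pos, n_res = _member_coordinates(row)
        if n_res != len(member.residues):
            raise ValueError(f"alignment row of {acc} does not match its sequence")
        for ann in cluster_annots:
            s = 0.0
            n = 0
            first = last = 0
            for col in range(ann.q_start - 1, ann.q_end):
                res = col_residue[col]
                if res != "-":
                    s += matrix.score(res, consensus.residues[col])
                    n += 1
                    if first == 0:
                        first = col_pos[col]
                    last = col_pos[col]
            if n == 0:
                continue
            ev = subalignment_evalue(ann.evalue, s, L, params)
            if ev < params.evalue_cutoff:
                out.append(
                    DomainAnnotation(
                        query_id=acc,
                        target_id=ann.target_id,
                        database=ann.database,
                        q_start=first,
                        q_end=last,
                        q_len=len(member.residues),
                        t_start=ann.t_start,
                        t_end=ann.t_end,
                        t_len=ann.t_len,
                        evalue=ev,
                    )
                )
    return out
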