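"""Cluster MSAs, consensus sequences, profiles and diversity boosting.

A cluster's alignment is built center-star around its representative: every
member is aligned pairwise to the representative and the pairwise alignments
are merged. Representative positions define the match columns; member
residues opposite representative gaps become lowercase insertions, giving
A3M semantics directly. This replaces a general-purpose progressive aligner:
it is deterministic, and adequate because every member already satisfies
identity and coverage thresholds to its representative.

The boosting workflow enriches an alignment with local hits from iterative
profile searches against a consensus-sequence database, then filters the
result to target diversities by the BLOSUM62 score per aligned residue to
the consensus (thresholds 0.0, 0.5 and 1.1, empirically corresponding to
roughly 10%, 20% and 30% sequence identity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from . import align as _align
from .align import (
    ALPHABET,
    KARLIN_K,
    KARLIN_LAMBDA,
    STANDARD_AA,
    SubstitutionMatrix,
    blosum62,
    encode,
)

if TYPE_CHECKING:  # pragma: no cover
    from .core_io import ProteinSequence


@dataclass
class Msa:
    """An alignment with A3M semantics.

    Each record is ``(accession, row)`` where uppercase letters and ``-``
    occupy match columns and lowercase letters are insertions relative to
    the first record. The first record is the cluster representative (or the
    consensus, for boosted alignments) and is always ungapped.
    """

    records: list  # list[tuple[str, str]]

    @property
    def n_match_columns(self) -> int:
        first = self.records[0][1]
        return sum(1 for c in first if c.isupper() or c == "-")

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.records]

    def match_column_residues(self, row: str) -> str:
        """The row restricted to match columns ('-' for deletions)."""
        return "".join(c for c in row if c.isupper() or c == "-")


@dataclass
class ConsensusRecord:
    """Per-cluster consensus sequence plus its summary header."""

    residues: str
    cluster_id: str | None = None
    representative: str | None = None
    size: int = 1
    header: str = ""

    @property
    def accession(self) -> str:
        return self.cluster_id or (self.representative or "consensus")


@dataclass
class Pssm:
    """Position-specific scores over the 20 standard residues."""

    n_cols: int
    scores: np.ndarray  # (n_cols, 21) float64, indexed like align.ALPHABET
    consensus: str

    def __post_init__(self) -> None:
        if self.n_cols != len(self.consensus):
            raise ValueError("consensus length must equal n_cols")


@dataclass
class BoostParams:
    """Iterative-search and diversity-filter settings."""

    n_iterations: int = 4
    filter_min_score_per_res: float = 0.0
    search_evalue_cutoff: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _a3m_row(member: "ProteinSequence", anchor_residues: str, result) -> str:
    """Render a member's pairwise alignment to the anchor as an A3M row.

    Anchor positions outside the local alignment become deletions ('-');
    member residues outside it, and residues opposite anchor gaps, become
    lowercase insertions, so member coordinates are fully recoverable from
    the row.
    """
    parts: list[str] = []
    # member residues before the aligned span are leading insertions
    parts.append(member.residues[: result.q_start - 1].lower())
    parts.append("-" * (result.t_start - 1))
    qi = result.q_start - 1  # 0-based cursors
    for op in result.ops:
        if op == 0:  # aligned column
            parts.append(member.residues[qi])
            qi += 1
        elif op == 1:  # gap in anchor: insertion
            parts.append(member.residues[qi].lower())
            qi += 1
        else:  # gap in member: deletion
            parts.append("-")
    parts.append(member.residues[result.q_end :].lower())
    parts.append("-" * (len(anchor_residues) - result.t_end))
    return "".join(parts)


def build_msa(
    members: Sequence["ProteinSequence"],
    representative: str,
    matrix: SubstitutionMatrix | None = None,
) -> Msa:
    """Center-star A3M alignment of a cluster around its representative.

    The representative row is its plain sequence, so ``n_match_columns``
    always equals the representative length.
    """
    if not members:
        raise ValueError("cannot build an MSA from an empty member list")
    matrix = matrix or blosum62()
    by_acc = {m.accession: m for m in members}
    if representative not in by_acc:
        raise ValueError(f"representative {representative} not among members")
    rep = by_acc[representative]
    records: list[tuple[str, str]] = [(rep.accession, rep.residues)]
    for m in members:
        if m.accession == representative:
            continue
        result = _align.align_pair(m, rep, matrix)
        if result.n_aligned_cols == 0:
            # no local similarity at all: keep the member as pure insertion
            records.append(
                (m.accession, m.residues.lower() + "-" * len(rep.residues))
            )
        else:
            records.append((m.accession, _a3m_row(m, rep.residues, result)))
    return Msa(records=records)


def _column_frequencies(msa: Msa) -> np.ndarray:
    """Weighted residue frequencies per match column, shape (n_cols, 21).

    Sequence weighting collapses duplicate rows: each distinct aligned row
    contributes once, so repeating a sequence cannot bias the profile.
    """
    n_cols = msa.n_match_columns
    counts = np.zeros((n_cols, len(ALPHABET)), dtype=np.float64)
    seen: set[str] = set()
    idx = {aa: i for i, aa in enumerate(ALPHABET)}
    for _, row in msa.records:
        if row in seen:
            continue
        seen.add(row)
        col = 0
        for c in row:
            if c == "-":
                col += 1
            elif c.isupper():
                counts[col, idx[c]] += 1.0
                col += 1
    return counts


def compute_consensus(
    msa: Msa,
    matrix: SubstitutionMatrix | None = None,
    pseudocount_weight: float = 1.0,
) -> ConsensusRecord:
    """Most probable residue per match column under a smoothed profile.

    Observed counts are blended with a uniform background pseudocount of
    total weight ``pseudocount_weight``; the argmax is taken over the 20
    standard residues (X never wins unless a column holds only X). Ties go
    to the residue with the higher matrix self-score, then alphabetically.
    """
    matrix = matrix or blosum62()
    counts = _column_frequencies(msa)
    bg = pseudocount_weight / 20.0
    consensus = []
    self_scores = np.array([matrix.score(a, a) for a in STANDARD_AA])
    for col in range(counts.shape[0]):
        obs = counts[col, :20]
        if obs.sum() == 0:
            consensus.append("X")
            continue
        probs = obs + bg
        best = np.flatnonzero(probs == probs.max())
        if len(best) > 1:
            ss = self_scores[best]
            best = best[ss == ss.max()]
        consensus.append(STANDARD_AA[int(best[0])])
    return ConsensusRecord(residues="".join(consensus))


_HEADER_BLACKLIST = ("hypothetical", "unknown", "uncharacterized", "putative")


def summarize_headers(
    members: Sequence["ProteinSequence"],
    cluster_id: str,
    representative: str,
) -> str:
    """Consensus-record header: id, representative, size, the top five
    non-redundant member descriptions and all member accessions.

    Descriptions from reviewed entries outrank unreviewed ones; descriptions
    containing hypothetical/unknown/uncharacterized/putative are ranked
    last; remaining ties resolve by frequency then lexicographically.
    """
    if not members:
        raise ValueError("empty member list")
    freq: dict[str, int] = {}
    reviewed: dict[str, bool] = {}
    for m in members:
        desc = m.description.strip()
        if not desc:
            continue
        freq[desc] = freq.get(desc, 0) + 1
        reviewed[desc] = reviewed.get(desc, False) or m.source == "reviewed"

    def rank(desc: str):
        blacklisted = any(w in desc.lower() for w in _HEADER_BLACKLIST)
        return (not reviewed[desc], blacklisted, -freq[desc], desc)

    top = sorted(freq, key=rank)[:5]
    accessions = [m.accession for m in members]
    return "|".join(
        [
            cluster_id,
            representative,
            f"n={len(members)}",
            ";".join(top),
            ",".join(accessions),
        ]
    )


def build_pssm(msa: Msa, matrix: SubstitutionMatrix | None = None) -> Pssm:
    """Profile scores from weighted counts with matrix pseudocounts.

    Column scores are the frequency-weighted average of substitution-matrix
    rows of the observed residues; this keeps every score finite for
    unobserved residues and reduces exactly to the sequence's own matrix
    rows for a single-sequence alignment.
    """
    matrix = matrix or blosum62()
    counts = _column_frequencies(msa)
    n_cols = counts.shape[0]
    scores = np.zeros((n_cols, len(ALPHABET)), dtype=np.float64)
    consensus = compute_consensus(msa, matrix)
    for col in range(n_cols):
        total = counts[col].sum()
        if total == 0:
            scores[col] = matrix.scores[encode("X")[0]]
            continue
        f = counts[col] / total
        scores[col] = f @ matrix.scores
    return Pssm(n_cols=n_cols, scores=scores, consensus=consensus.residues)


def _karlin_evalue(score: float, m: int, n_db_residues: int) -> float:
    return KARLIN_K * m * n_db_residues * math.exp(-KARLIN_LAMBDA * score)


def profile_search(
    pssm: Pssm,
    db: Sequence["ProteinSequence"],
    params: BoostParams | None = None,
    msa: Msa | None = None,
    matrix: SubstitutionMatrix | None = None,
):
    """Local profile-vs-sequence search, optionally iterated.

    Each database sequence is aligned to the profile by local DP; hits with
    Karlin-Altschul E-value below the cutoff are returned sorted by
    ascending E-value. When the profile's source alignment ``msa`` is given,
    the search is iterated ``params.n_iterations`` times: hits are merged
    into the alignment (aligned to its consensus), the profile is rebuilt
    and the search repeated. Previously found hits are never dropped, so the
    hit set grows monotonically.

    Returns ``(hits, msa)`` where ``hits`` maps accessions to
    ``(evalue, AlignmentResult)`` in ascending E-value order and ``msa`` is
    the (possibly enriched) alignment, or None if none was supplied.
    """
    from .core_io import ProteinSequence  # runtime import to avoid a cycle

    params = params or BoostParams()
    matrix = matrix or blosum62()
    if not db:
        raise ValueError("empty search database")
    n_db = sum(len(s.residues) for s in db)
    n_rounds = params.n_iterations if msa is not None else 1
    hits: dict[str, tuple[float, object]] = {}
    current = pssm
    for _ in range(n_rounds):
        new_hits = 0
        cons_codes = encode(current.consensus)
        for s in db:
            if s.accession in hits:
                continue
            t_codes = encode(s.residues)
            score, qs, qe, ts, te, n_id, n_cols, ops = _align._align_profile(
                current.scores, cons_codes, t_codes,
                matrix.gap_open, matrix.gap_extend,
            )
            if n_cols == 0:
                continue
            ev = _karlin_evalue(score, current.n_cols, n_db)
            if ev < params.search_evalue_cutoff:
                res = _align.AlignmentResult(
                    q_id="profile", t_id=s.accession, score=score,
                    n_identical=n_id, n_aligned_cols=n_cols,
                    q_start=qs, q_end=qe, t_start=ts, t_end=te,
                    q_len=current.n_cols, t_len=len(s.residues), ops=ops,
                )
                hits[s.accession] = (ev, res)
                new_hits += 1
        if msa is None or new_hits == 0:
            break
        # merge new hits into the alignment via the consensus anchor
        anchor = ProteinSequence(accession="__consensus__",
                                 residues=current.consensus)
        present = set(msa.accessions)
        for s in db:
            if s.accession in hits and s.accession not in present:
                result = _align.align_pair(s, anchor, matrix)
                if result.n_aligned_cols:
                    msa.records.append(
                        (s.accession, _a3m_row(s, anchor.residues, result))
                    )
        current = build_pssm(msa, matrix)
    ordered = dict(sorted(hits.items(), key=lambda kv: (kv[1][0], kv[0])))
    return ordered, msa


def diversity_filter(
    msa: Msa,
    consensus: ConsensusRecord,
    matrix: SubstitutionMatrix | None = None,
    min_score_per_res: float = 0.0,
) -> Msa:
    """Drop records scoring below ``min_score_per_res`` against the consensus.

    The score per aligned residue is averaged over match-state columns where
    the record has a residue; insertions (lowercase) are unscored. The first
    record is always kept. Filtering is idempotent and nested: a higher
    threshold keeps a subset of a lower one.
    """
    matrix = matrix or blosum62()
    if len(consensus.residues) != msa.n_match_columns:
        raise ValueError("consensus length does not match the alignment")
    kept = [msa.records[0]]
    for acc, row in msa.records[1:]:
        match_res = msa.match_column_residues(row)
        s = 0.0
        n = 0
        for c_res, m_res in zip(consensus.residues, match_res):
            if m_res != "-":
                s += matrix.score(m_res, c_res)
                n += 1
        if n > 0 and s / n >= min_score_per_res:
            kept.append((acc, row))
    return Msa(records=kept)


#: Uniboost diversity levels: filter threshold by database name.
BOOST_FILTERS = {10: 0.0, 20: 0.5, 30: 1.1}


def uniboost(
    msa: Msa,
    consensus_db: Sequence["ProteinSequence"],
    matrix: SubstitutionMatrix | None = None,
    params: BoostParams | None = None,
    filters: dict | None = None,
) -> dict:
    """Enrich a cluster alignment and emit the three diversity variants.

    Runs the iterative profile search against the consensus database, then
    applies the score-per-residue filters (default 0.0 / 0.5 / 1.1 for
    levels 10 / 20 / 30). Returns ``{level: Msa}``.
    """
    matrix = matrix or blosum62()
    params = params or BoostParams()
    filters = filters if filters is not None else BOOST_FILTERS
    pssm = build_pssm(msa, matrix)
    enriched = Msa(records=list(msa.records))
    _, enriched = profile_search(pssm, consensus_db, params, enriched, matrix)
    consensus = compute_consensus(enriched, matrix)
    return {
        level: diversity_filter(enriched, consensus, matrix, threshold)
        for level, threshold in filters.items()
    }
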