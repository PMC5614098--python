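"""Cascaded clustering: redundancy hashing, fragment absorption, greedy
incremental clustering, greedy set cover with reassignment, and incremental
updates with stable identifiers.

The cascade mirrors the three-stage workflow used to build clustered
protein databases at the 90/50/30% identity levels:

1. an exact redundancy filter that buckets sequences by a 64-bit hash of
   their reduced-alphabet string (only identical-length, full-overlap
   sequences can merge here), followed by fragment absorption;
2. CD-HIT-style greedy incremental clustering of the remaining
   representatives at 90% identity and 90% coverage of the shorter
   sequence, again followed by fragment absorption;
3. greedy set-cover clustering of the 90%-level representatives at 50% and,
   independently, 30% identity with 80% bidirectional coverage, followed by
   one reassignment pass moving every member to its most similar
   representative (by BLOSUM62 score per aligned residue).

Tie-breaking is uniform everywhere: higher score, then longer sequence,
then lexicographically smaller accession, so all results are deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Sequence

from . import align as _align
from .align import SubstitutionMatrix, blosum62, hash64, reduce_alphabet
from .core_io import ClusterRecord, ProteinSequence, assign_cluster_ids, validate_partition

logger = logging.getLogger("miniclust")

#: above this many input sequences the all-vs-all stages emit a warning
QUADRATIC_WARN_THRESHOLD = 2000


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for one clustering level.

    ``cov_mode`` selects how the length-overlap criterion is applied:
    ``"shorter"`` requires the alignment to span ``min_cov`` of the shorter
    sequence (the 90%-level greedy rule), ``"both"`` requires it of both
    sequences (the 50/30%-level set-cover rule). The fragment rule absorbs
    near-identical fragments covered over >=95% of their own length
    regardless of the main coverage criterion.
    """

    min_seq_id: float
    min_cov: float
    cov_mode: str = "both"  # "shorter" | "both"
    fragment_min_id: float = 0.9
    fragment_min_cov: float = 0.95
    level: int = 90

    def __post_init__(self) -> None:
        for v in (self.min_seq_id, self.min_cov,
                  self.fragment_min_id, self.fragment_min_cov):
            if not 0 < v <= 1:
                raise ValueError("thresholds must be in (0, 1]")
        if self.cov_mode not in ("shorter", "both"):
            raise ValueError("cov_mode must be 'shorter' or 'both'")


PARAMS_90 = ClusterParams(min_seq_id=0.9, min_cov=0.9, cov_mode="shorter", level=90)
PARAMS_50 = ClusterParams(min_seq_id=0.5, min_cov=0.8, cov_mode="both", level=50)
PARAMS_30 = ClusterParams(min_seq_id=0.3, min_cov=0.8, cov_mode="both", level=30)

LEVEL_PARAMS = {90: PARAMS_90, 50: PARAMS_50, 30: PARAMS_30}


def _coverage_ok(result, params: ClusterParams) -> bool:
    if params.cov_mode == "shorter":
        return result.shorter_cov >= params.min_cov
    return result.q_cov >= params.min_cov and result.t_cov >= params.min_cov


def meets_thresholds(result, params: ClusterParams) -> bool:
    """Acceptance criterion for a member/representative alignment."""
    return result.identity >= params.min_seq_id and _coverage_ok(result, params)


def meets_fragment_rule(result, params: ClusterParams) -> bool:
    """Fragment absorption: near-identical and covered over >=95% of the
    member's own length (the query side of the alignment)."""
    return (
        result.identity >= params.fragment_min_id
        and result.q_cov >= params.fragment_min_cov
    )


def _seq_index(seqs: Sequence[ProteinSequence]) -> Dict[str, ProteinSequence]:
    index = {s.accession: s for s in seqs}
    if len(index) != len(seqs):
        raise ValueError("duplicate accessions in sequence set")
    return index


def _canonical(clusters: List[ClusterRecord]) -> List[ClusterRecord]:
    """Sort clusters by representative and members with representative first."""
    out = []
    for c in sorted(clusters, key=lambda c: c.representative):
        members = [c.representative] + sorted(
            m for m in c.members if m != c.representative
        )
        out.append(ClusterRecord(representative=c.representative,
                                 members=members, cluster_id=c.cluster_id))
    return out


def _warn_quadratic(n: int, stage: str) -> None:
    if n > QUADRATIC_WARN_THRESHOLD:
        logger.warning(
            "%s: %d sequences; all-vs-all alignment is O(n^2) and intended "
            "for desk-scale inputs", stage, n
        )


def hash_cluster(
    seqs: Sequence[ProteinSequence], min_seq_id: float = 0.9
) -> List[ClusterRecord]:
    """Redundancy filter: cluster identical-length, full-overlap sequences.

    Sequences are bucketed by (length, 64-bit hash of the reduced-alphabet
    string); within a bucket a sequence joins the cluster whose
    representative has the highest exact column-wise identity, provided it
    reaches ``min_seq_id``. Hash collisions are harmless because candidates
    are always verified on the full alphabet.
    """
    buckets: Dict[tuple, List[ProteinSequence]] = {}
    _seq_index(seqs)
    for s in seqs:
        key = (len(s.residues), hash64(reduce_alphabet(s.residues)))
        buckets.setdefault(key, []).append(s)
    clusters: List[ClusterRecord] = []
    for key in sorted(buckets, key=lambda k: (-k[0], k[1])):
        bucket = sorted(buckets[key], key=lambda s: s.accession)
        reps: List[ProteinSequence] = []
        members: Dict[str, List[str]] = {}
        for s in bucket:
            best_rep = None
            best_id = min_seq_id
            for r in reps:
                ident = sum(
                    a == b for a, b in zip(s.residues, r.residues)
                ) / len(s.residues)
                if ident > best_id or (ident == best_id and best_rep is None):
                    if ident >= min_seq_id:
                        best_id = ident
                        best_rep = r
            if best_rep is None:
                reps.append(s)
                members[s.accession] = [s.accession]
            else:
                members[best_rep.accession].append(s.accession)
        for r in reps:
            clusters.append(
                ClusterRecord(representative=r.accession,
                              members=members[r.accession])
            )
    return _canonical(clusters)


def merge_fragments(
    clustering: Sequence[ClusterRecord],
    seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
) -> List[ClusterRecord]:
    """Absorb fragment clusters into clusters of their full-length parents.

    A cluster is absorbed when its representative aligns to another
    surviving representative (of equal or greater length) with identity
    >= ``fragment_min_id`` over >= ``fragment_min_cov`` of its own length;
    the best-scoring eligible target wins. Every other member of the
    absorbed cluster is verified against the new representative too (it
    must meet the level thresholds or the fragment rule itself), so
    absorption chains can never leave a member behind an unchecked
    representative. Clusters are processed shortest representative first so
    chains of fragments collapse into the longest parent.
    """
    matrix = matrix or blosum62()
    index = _seq_index(seqs)
    alive: Dict[str, List[str]] = {
        c.representative: list(c.members) for c in clustering
    }
    order = sorted(
        alive, key=lambda rep: (len(index[rep].residues), rep)
    )

    def members_compatible(cluster_rep: str, target: ProteinSequence) -> bool:
        for m in alive[cluster_rep]:
            if m == cluster_rep:
                continue
            r = _align.align_pair(index[m], target, matrix)
            if not (meets_thresholds(r, params) or meets_fragment_rule(r, params)):
                return False
        return True

    for rep in order:
        if rep not in alive:
            continue
        frag = index[rep]
        best = None  # (score, len, acc)
        for other in alive:
            if other == rep:
                continue
            target = index[other]
            if len(target.residues) < len(frag.residues):
                continue
            result = _align.align_pair(frag, target, matrix)
            if meets_fragment_rule(result, params) and members_compatible(
                rep, target
            ):
                key = (-result.score, -len(target.residues), other)
                if best is None or key < best[0]:
                    best = (key, other)
        if best is not None:
            target_rep = best[1]
            logger.debug("fragment cluster %s absorbed into %s", rep, target_rep)
            alive[target_rep].extend(alive.pop(rep))
    clusters = [
        ClusterRecord(representative=rep, members=members)
        for rep, members in alive.items()
    ]
    return _canonical(clusters)


def greedy_incremental_cluster(
    seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
) -> List[ClusterRecord]:
    """CD-HIT-style greedy clustering, longest sequence first.

    Each sequence joins the best-scoring existing representative that meets
    the identity and coverage thresholds, else founds a new cluster.
    Representatives are therefore never shorter than their members, and the
    partition is independent of input order.
    """
    matrix = matrix or blosum62()
    _seq_index(seqs)
    _warn_quadratic(len(seqs), "greedy_incremental_cluster")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.accession))
    reps: List[ProteinSequence] = []
    members: Dict[str, List[str]] = {}
    for s in ordered:
        best = None  # ((-score, -len, acc), rep accession)
        for r in reps:
            result = _align.align_pair(s, r, matrix)
            if meets_thresholds(result, params):
                key = (-result.score, -len(r.residues), r.accession)
                if best is None or key < best[0]:
                    best = (key, r.accession)
        if best is None:
            reps.append(s)
            members[s.accession] = [s.accession]
        else:
            members[best[1]].append(s.accession)
    clusters = [
        ClusterRecord(representative=r.accession, members=members[r.accession])
        for r in reps
    ]
    return _canonical(clusters)


def greedy_set_cover(
    adjacency: Dict[str, set],
    lengths: Dict[str, int] | None = None,
) -> List[ClusterRecord]:
    """Greedy set cover over an explicit acceptance graph.

    Repeatedly selects the uncovered vertex covering the most uncovered
    vertices (itself plus its uncovered neighbours) as a representative;
    ties go to the longer sequence, then the smaller accession. Used both
    by :func:`set_cover_cluster` and directly on synthetic graphs.
    """
    lengths = lengths or {}
    uncovered = set(adjacency)
    clusters: List[ClusterRecord] = []
    while uncovered:
        best = None
        for v in uncovered:
            gain = 1 + sum(1 for u in adjacency[v] if u in uncovered and u != v)
            key = (-gain, -lengths.get(v, 0), v)
            if best is None or key < best[0]:
                best = (key, v)
        v = best[1]
        covered_now = [v] + sorted(
            u for u in adjacency[v] if u in uncovered and u != v
        )
        uncovered.difference_update(covered_now)
        clusters.append(ClusterRecord(representative=v, members=covered_now))
    return _canonical(clusters)


def build_acceptance_graph(
    seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
) -> Dict[str, set]:
    """All-vs-all acceptance graph: an edge means the pair meets the
    identity and (bidirectional) coverage thresholds."""
    matrix = matrix or blosum62()
    _warn_quadratic(len(seqs), "build_acceptance_graph")
    adjacency: Dict[str, set] = {s.accession: set() for s in seqs}
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            result = _align.align_pair(a, b, matrix)
            if meets_thresholds(result, params):
                adjacency[a.accession].add(b.accession)
                adjacency[b.accession].add(a.accession)
    return adjacency


def set_cover_cluster(
    seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
) -> List[ClusterRecord]:
    """Greedy set-cover clustering followed by one reassignment pass."""
    matrix = matrix or blosum62()
    index = _seq_index(seqs)
    adjacency = build_acceptance_graph(seqs, params, matrix)
    lengths = {acc: len(s.residues) for acc, s in index.items()}
    clusters = greedy_set_cover(adjacency, lengths)
    return reassign_members(clusters, seqs, params, matrix)


def reassign_members(
    clustering: Sequence[ClusterRecord],
    seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
) -> List[ClusterRecord]:
    """Move every non-representative member to the representative with the
    highest score per aligned residue among those meeting the thresholds.

    Representatives never move; a member with no eligible representative
    (which cannot arise from our own clustering steps) stays put. A single
    pass is performed.
    """
    matrix = matrix or blosum62()
    index = _seq_index(seqs)
    reps = [index[c.representative] for c in clustering]
    members: Dict[str, List[str]] = {
        c.representative: [c.representative] for c in clustering
    }
    for c in clustering:
        for m in c.members:
            if m == c.representative:
                continue
            seq = index[m]
            best = None  # ((-spr, -len, acc), rep)
            for r in reps:
                result = _align.align_pair(seq, r, matrix)
                if meets_thresholds(result, params) or (
                    r.accession == c.representative
                    and meets_fragment_rule(result, params)
                ):
                    key = (-result.score_per_res, -len(r.residues), r.accession)
                    if best is None or key < best[0]:
                        best = (key, r.accession)
            target = best[1] if best is not None else c.representative
            if target != c.representative:
                logger.debug("reassigned %s: %s -> %s", m, c.representative, target)
            members[target].append(m)
    clusters = [
        ClusterRecord(representative=rep, members=mem)
        for rep, mem in members.items()
    ]
    return _canonical(clusters)


def _expand(
    coarse: Sequence[ClusterRecord], fine: Sequence[ClusterRecord]
) -> List[ClusterRecord]:
    """Expand a clustering of fine-level representatives to all sequences."""
    fine_members = {c.representative: list(c.members) for c in fine}
    out = []
    for c in coarse:
        members: List[str] = []
        for m in c.members:
            members.extend(fine_members[m])
        out.append(ClusterRecord(representative=c.representative, members=members))
    return _canonical(out)


def cascade(
    seqs: Sequence[ProteinSequence],
    release: str = "2501",
    matrix: SubstitutionMatrix | None = None,
):
    """The full three-step clustering workflow.

    Returns ``(uniclust90, uniclust50, uniclust30)``: three partitions of
    the same accession set, with 50/30-level clusters being unions of whole
    90-level clusters (membership is expanded through the finer levels).
    """
    matrix = matrix or blosum62()
    index = _seq_index(seqs)

    step1 = hash_cluster(seqs, min_seq_id=PARAMS_90.min_seq_id)
    step1 = merge_fragments(step1, seqs, PARAMS_90, matrix)
    reps1 = [index[c.representative] for c in step1]
    logger.info("redundancy filter: %d -> %d", len(seqs), len(reps1))

    step2 = greedy_incremental_cluster(reps1, PARAMS_90, matrix)
    step2 = merge_fragments(step2, reps1, PARAMS_90, matrix)
    uniclust90 = _expand(step2, step1)
    reps90 = [index[c.representative] for c in uniclust90]
    logger.info("greedy incremental: %d -> %d", len(reps1), len(reps90))

    u50 = set_cover_cluster(reps90, PARAMS_50, matrix)
    u30 = set_cover_cluster(reps90, PARAMS_30, matrix)
    uniclust50 = _expand(u50, uniclust90)
    uniclust30 = _expand(u30, uniclust90)
    logger.info(
        "set cover: %d -> %d (50%%) / %d (30%%)",
        len(reps90), len(uniclust50), len(uniclust30),
    )

    accs = [s.accession for s in seqs]
    for clusters in (uniclust90, uniclust50, uniclust30):
        validate_partition(clusters, accs)
    assign_cluster_ids(uniclust90, 90, release)
    assign_cluster_ids(uniclust50, 50, release)
    assign_cluster_ids(uniclust30, 30, release)
    return uniclust90, uniclust50, uniclust30


def update_clustering(
    old: Sequence[ClusterRecord],
    old_seqs: Sequence[ProteinSequence],
    new_seqs: Sequence[ProteinSequence],
    params: ClusterParams,
    matrix: SubstitutionMatrix | None = None,
    release: str | None = None,
) -> List[ClusterRecord]:
    """Incrementally update a clustering to a new sequence set.

    Deprecated members are dropped (a cluster whose representative vanished
    promotes its longest remaining member but keeps its identifier); new
    sequences are compared against surviving representatives only — linear
    in the number of new sequences, never all-vs-all over old members — and
    leftover new sequences are clustered among themselves by set cover and
    receive fresh identifiers. Unchanged clusters keep identical identifier,
    representative and members.
    """
    matrix = matrix or blosum62()
    old_index = _seq_index(old_seqs)
    new_index = _seq_index(new_seqs)
    for acc, s in new_index.items():
        if acc in old_index and old_index[acc].residues != s.residues:
            raise ValueError(
                f"accession {acc} changed sequence; accessions are immutable"
            )

    level = params.level
    max_num = 0
    release_tag = release
    survivors: List[ClusterRecord] = []
    for c in old:
        if c.cluster_id:
            m = re.match(r"uc(\d+)-(\d{4})-(\d+)$", c.cluster_id)
            if m:
                max_num = max(max_num, int(m.group(3)))
                if release_tag is None:
                    release_tag = m.group(2)
        members = [m for m in c.members if m in new_index]
        if not members:
            logger.debug("cluster %s removed (all members deprecated)", c.cluster_id)
            continue
        if c.representative in new_index:
            rep = c.representative
        else:
            rep = min(members, key=lambda a: (-len(new_index[a].residues), a))
            logger.debug("cluster %s: representative %s -> %s",
                         c.cluster_id, c.representative, rep)
        members = [rep] + sorted(m for m in members if m != rep)
        survivors.append(ClusterRecord(representative=rep, members=members,
                                       cluster_id=c.cluster_id))

    old_accs = {m for c in old for m in c.members}
    added = [s for acc, s in sorted(new_index.items()) if acc not in old_accs]
    rep_seqs = [new_index[c.representative] for c in survivors]
    leftovers: List[ProteinSequence] = []
    joined: Dict[str, List[str]] = {c.representative: [] for c in survivors}
    for s in added:
        best = None
        for r in rep_seqs:
            result = _align.align_pair(s, r, matrix)
            if meets_thresholds(result, params) or meets_fragment_rule(result, params):
                key = (-result.score, -len(r.residues), r.accession)
                if best is None or key < best[0]:
                    best = (key, r.accession)
        if best is None:
            leftovers.append(s)
        else:
            joined[best[1]].append(s.accession)

    updated: List[ClusterRecord] = []
    for c in survivors:
        extra = joined[c.representative]
        if extra:
            members = [c.representative] + sorted(
                [m for m in c.members if m != c.representative] + extra
            )
            updated.append(ClusterRecord(representative=c.representative,
                                         members=members, cluster_id=c.cluster_id))
        else:
            updated.append(c)

    if leftovers:
        fresh = set_cover_cluster(leftovers, params, matrix)
        tag = release_tag or "0000"
        for c in fresh:
            max_num += 1
            c.cluster_id = f"uc{level}-{tag}-{max_num}"
        updated.extend(fresh)

    validate_partition(updated, new_index)
    return updated
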