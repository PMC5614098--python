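"""Synthetic data: homologous families at controlled divergence, fragments,
annotation corpora with toy ontologies, and fabricated domain matches.

Every generator is a pure function of its seed, so fixtures are
reproducible and nothing needs to be downloaded or shipped. Families are
grown from independent uniform-random founder sequences; unrelated founders
of realistic length share well under 30% identity over any
coverage-satisfying alignment, so planted partitions are recoverable by the
clustering cascade and scoreable with the adjusted Rand index.

The first member of each family is the unmutated founder. It is the natural
representative (longest member, lexicographically first accession), and it
makes the member-to-representative identity equal the requested
within-family identity exactly — mutating every member independently would
square the identity between members and misstate the intended divergence
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .align import STANDARD_AA, blosum62
from .core_io import DomainAnnotation, ProteinSequence
from .evaluate import Ontology, probabilities_from_corpus
from .msa import ConsensusRecord


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a planted family fixture."""

    n_families: int = 3
    members_per_family: int = 5
    seq_len: int = 200
    within_identity: float = 0.95
    fragment_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_identity <= 1:
            raise ValueError("within_identity must be in (0, 1]")
        if min(self.n_families, self.members_per_family, self.seq_len) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.fragment_prob <= 1:
            raise ValueError("fragment_prob must be in [0, 1]")


def _substitution_table() -> np.ndarray:
    """P(new | original) proportional to BLOSUM62 exchangeability, zero on
    the diagonal; shape (20, 20)."""
    m = blosum62().scores[:20, :20]
    weights = np.exp2(m / 2.0)
    np.fill_diagonal(weights, 0.0)
    return weights / weights.sum(axis=1, keepdims=True)


_SUB_TABLE: np.ndarray | None = None


def mutate_sequence(
    seq: str, target_identity: float, rng: np.random.Generator
) -> str:
    """Substitute residues so the realised exact-column identity equals
    ``round(len * target_identity) / len``.

    Positions are chosen without replacement; replacement residues are
    drawn proportionally to BLOSUM62 exchangeabilities (never the original
    residue), mimicking accepted point substitutions between homologs.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    global _SUB_TABLE
    if _SUB_TABLE is None:
        _SUB_TABLE = _substitution_table()
    L = len(seq)
    n_keep = round(L * target_identity)
    n_mut = L - n_keep
    if n_mut == 0:
        return seq
    positions = rng.choice(L, size=n_mut, replace=False)
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    out = list(seq)
    for pos in positions:
        orig = aa_index.get(out[pos], aa_index["A"])
        out[pos] = STANDARD_AA[rng.choice(20, p=_SUB_TABLE[orig])]
    return "".join(out)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-random sequence over the 20 standard residues."""
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))


def generate_families(spec: FamilySpec):
    """Planted homologous families with optional fragments.

    Returns ``(sequences, partition)`` where ``partition`` maps accession to
    family index. Member 0 of each family is the unmutated founder; other
    members are mutated to ``within_identity`` and, with probability
    ``fragment_prob``, truncated to a uniform 30-60% prefix or suffix
    (exercising the fragment-absorption rule exactly: truncation keeps
    identity, and coverage of the fragment's own length is 1).
    """
    rng = np.random.default_rng(spec.seed)
    seqs: List[ProteinSequence] = []
    partition: Dict[str, int] = {}
    for f in range(spec.n_families):
        founder = random_sequence(spec.seq_len, rng)
        for m in range(spec.members_per_family):
            acc = f"F{f:02d}M{m:02d}"
            residues = founder if m == 0 else mutate_sequence(
                founder, spec.within_identity, rng
            )
            if m > 0 and rng.random() < spec.fragment_prob:
                frac = rng.uniform(0.3, 0.6)
                n = max(1, round(frac * len(residues)))
                residues = residues[:n] if rng.random() < 0.5 else residues[-n:]
            seqs.append(
                ProteinSequence(
                    accession=acc,
                    residues=residues,
                    description=f"family {f} protein",
                    source="reviewed" if m == 0 else "unreviewed",
                )
            )
            partition[acc] = f
    return seqs, partition


def generate_hierarchical_families(
    n_superfamilies: int = 3,
    subfamilies_per: int = 2,
    members_per_family: int = 4,
    seq_len: int = 200,
    within_identity: float = 0.95,
    subfamily_identity: float = 0.70,
    seed: int = 0,
):
    """Two-level families: subfamily founders diverge to ``subfamily_identity``
    from a shared superfamily ancestor.

    Pairwise identity between sibling subfamily founders is then roughly
    ``subfamily_identity ** 2`` (~0.5 at the default), so 30%-level
    clustering merges sibling subfamilies while 90%-level clustering keeps
    them apart. Returns ``(sequences, subfamily_partition,
    superfamily_partition)``.
    """
    rng = np.random.default_rng(seed)
    seqs: List[ProteinSequence] = []
    sub_part: Dict[str, int] = {}
    super_part: Dict[str, int] = {}
    sub_id = 0
    for sf in range(n_superfamilies):
        ancestor = random_sequence(seq_len, rng)
        for sub in range(subfamilies_per):
            founder = mutate_sequence(ancestor, subfamily_identity, rng)
            for m in range(members_per_family):
                acc = f"S{sf:02d}U{sub:02d}M{m:02d}"
                residues = founder if m == 0 else mutate_sequence(
                    founder, within_identity, rng
                )
                seqs.append(
                    ProteinSequence(
                        accession=acc, residues=residues,
                        description=f"superfamily {sf} subfamily {sub} protein",
                    )
                )
                sub_part[acc] = sub_id
                super_part[acc] = sf
            sub_id += 1
    return seqs, sub_part, super_part


_NAME_STEMS = (
    "kinase", "transporter", "dehydrogenase", "ligase", "reductase",
    "synthase", "hydrolase", "isomerase", "permease", "phosphatase",
)


def generate_ontology(
    depth: int = 3,
    branching: int = 3,
    n_proteins: int = 15,
    noise: float = 0.0,
    seed: int = 0,
    accessions: Sequence[str] | None = None,
    family_of: Dict[str, int] | None = None,
):
    """A toy GO-like corpus: balanced term tree plus per-protein annotations.

    The tree has ``branching ** d`` terms at depth ``d`` with probabilities
    decreasing geometrically (``branching ** -d``; the root has p = 1).
    Proteins in the same planted family share a leaf term, a keyword set
    and a protein name; each is independently perturbed with probability
    ``noise`` (sibling-leaf swap, keyword drop+add, name typo). Families
    default to contiguous blocks of five proteins.

    Returns ``(ontology, go_annotations, keywords, names)`` keyed by
    accession.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    if accessions is None:
        accessions = [f"P{i:04d}" for i in range(n_proteins)]
    if family_of is None:
        family_of = {acc: i // 5 for i, acc in enumerate(accessions)}

    parents: Dict[str, set] = {"T:root": set()}
    p: Dict[str, float] = {"T:root": 1.0}
    level = ["T:root"]
    counter = 0
    leaves: List[str] = []
    for d in range(1, depth + 1):
        nxt = []
        for parent in level:
            for _ in range(branching):
                term = f"T:{counter:05d}"
                counter += 1
                parents[term] = {parent}
                p[term] = float(branching) ** (-d)
                nxt.append(term)
        level = nxt
    leaves = level
    ont = Ontology(parents=parents, p=p)

    families = sorted(set(family_of.values()))
    fam_leaf = {f: leaves[i % len(leaves)] for i, f in enumerate(families)}
    kw_pool = [f"KW{i:03d}" for i in range(3 * len(families) + 10)]
    fam_keywords = {
        f: {kw_pool[3 * i], kw_pool[3 * i + 1], kw_pool[3 * i + 2]}
        for i, f in enumerate(families)
    }
    fam_name = {
        f: f"{_NAME_STEMS[i % len(_NAME_STEMS)]} {i // len(_NAME_STEMS) + 1}"
        for i, f in enumerate(families)
    }

    def sibling(leaf: str) -> str:
        parent = next(iter(parents[leaf]))
        siblings = [t for t in leaves if parents[t] == {parent} and t != leaf]
        pool = siblings or [t for t in leaves if t != leaf]
        return pool[rng.integers(0, len(pool))]

    go_annotations: Dict[str, set] = {}
    keywords: Dict[str, set] = {}
    names: Dict[str, str] = {}
    for acc in accessions:
        f = family_of[acc]
        leaf = fam_leaf[f]
        if noise > 0 and rng.random() < noise:
            leaf = sibling(leaf)
        kws = set(fam_keywords[f])
        if noise > 0 and rng.random() < noise:
            dropped = sorted(kws)[rng.integers(0, len(kws))]
            kws.discard(dropped)
            kws.add(kw_pool[rng.integers(0, len(kw_pool))])
        name = fam_name[f]
        if noise > 0 and rng.random() < noise:
            i = int(rng.integers(0, len(name)))
            name = name[:i] + "x" + name[i + 1 :]
        go_annotations[acc] = {leaf}
        keywords[acc] = kws
        names[acc] = name

    ont = probabilities_from_corpus(parents, go_annotations)
    return ont, go_annotations, keywords, names


def annotate_sequences(
    seqs: Sequence[ProteinSequence],
    go_annotations: Dict[str, set],
    keywords: Dict[str, set],
    names: Dict[str, str],
) -> None:
    """Attach a generated annotation corpus to sequence records in place."""
    for s in seqs:
        if s.accession in go_annotations:
            s.go_terms = set(go_annotations[s.accession])
            s.keywords = set(keywords[s.accession])
            s.name = names[s.accession]


def generate_domain_matches(
    consensus: ConsensusRecord,
    n: int,
    evalue_range: tuple = (1e-30, 1.0),
    seed: int = 0,
    database: str = "pfam",
) -> List[DomainAnnotation]:
    """Fabricated domain matches on a consensus sequence.

    Spans are non-degenerate (>= 10 residues where possible) and E-values
    log-uniform over ``evalue_range``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(consensus.residues)
    lo, hi = np.log10(evalue_range[0]), np.log10(evalue_range[1])
    out: List[DomainAnnotation] = []
    for i in range(n):
        span = int(rng.integers(min(10, L), L + 1))
        start = int(rng.integers(1, L - span + 2))
        t_len = int(rng.integers(span, 2 * span + 1))
        t_start = int(rng.integers(1, t_len - span + 2))
        out.append(
            DomainAnnotation(
                query_id=consensus.accession,
                target_id=f"{database.upper()}{i:05d}",
                database=database,
                q_start=start,
                q_end=start + span - 1,
                q_len=L,
                t_start=t_start,
                t_end=t_start + span - 1,
                t_len=t_len,
                evalue=float(10 ** rng.uniform(lo, hi)),
            )
        )
    return out
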