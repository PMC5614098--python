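"""Cluster compactness and annotation-consistency scoring.

Three annotation types are scored between the representative and every
other cluster member:

* GO terms — a Lin-style information-content similarity,
  ``sim(a,b) = 2 log P(LCA(a,b)) / (log P(a) + log P(b))``, where ``P(a)``
  is the probability of a protein being annotated with term ``a`` (or any
  descendant) and the LCA is the common ancestor of maximal information
  content. Term-set similarity averages best-match similarities in both
  directions.
* Keywords — the Dice coefficient ``2|Kx ∩ Ky| / (|Kx| + |Ky|)``.
* Protein names — ``1 - levenshtein / max length`` after normalisation
  (case-folded, the word "protein" removed, uninformative names such as
  "uncharacterized ..." excluded).

Per cluster we report the worst (minimum) and mean score per type, plus the
average over the three types; pairs with undefined scores (missing
annotations) are skipped rather than scored zero, since a missing
annotation is not evidence of inconsistency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import edlib
import numpy as np

from . import align as _align
from .align import SubstitutionMatrix, blosum62
from .core_io import ClusterRecord, ProteinSequence

logger = logging.getLogger("miniclust")


class NamespaceError(ValueError):
    """GO terms from different namespaces compared."""


class UnknownTermError(KeyError):
    """A term is absent from the ontology."""


@dataclass
class Ontology:
    """A DAG of terms with parent links and annotation probabilities.

    ``p[t]`` is the probability that a protein is annotated with ``t`` or
    any of its descendants; it is non-decreasing from child to parent and 1
    at the root. Terms may carry a namespace; similarities are only defined
    within one namespace.
    """

    parents: Dict[str, set]
    p: Dict[str, float]
    namespace: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ancestors_cache: Dict[str, frozenset] = {}
        self._validate()

    @property
    def terms(self) -> set:
        return set(self.parents)

    def _validate(self) -> None:
        order: List[str] = []
        state: Dict[str, int] = {}

        def visit(t: str) -> None:
            stack = [(t, iter(sorted(self.parents[t])))]
            state[t] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self.parents:
                        raise UnknownTermError(parent)
                    s = state.get(parent, 0)
                    if s == 1:
                        raise ValueError("ontology contains a cycle")
                    if s == 0:
                        state[parent] = 1
                        stack.append((parent, iter(sorted(self.parents[parent]))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()

        for t in sorted(self.parents):
            if state.get(t, 0) == 0:
                visit(t)
        for t, ps in self.parents.items():
            for parent in ps:
                if self.p[parent] < self.p[t] - 1e-12:
                    raise ValueError(
                        f"p({parent}) < p({t}): probabilities must be "
                        "non-decreasing towards the root"
                    )

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term``, including the term itself."""
        if term not in self.parents:
            raise UnknownTermError(term)
        cached = self._ancestors_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        for parent in self.parents[term]:
            out |= self.ancestors(parent)
        result = frozenset(out)
        self._ancestors_cache[term] = result
        return result

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        p: Dict[str, float],
        namespace: Dict[str, str] | None = None,
    ) -> "Ontology":
        """Build from (child, parent) edges; isolated roots allowed via p."""
        parents: Dict[str, set] = {t: set() for t in p}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents=parents, p=p, namespace=namespace or {})

    @classmethod
    def from_obo(cls, path, p: Dict[str, float] | None = None) -> "Ontology":
        """Read an OBO file (is_a edges); probabilities may be supplied or
        derived later from a corpus via :func:`probabilities_from_corpus`."""
        import obonet

        graph = obonet.read_obo(path)
        parents: Dict[str, set] = {}
        namespace: Dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            parents.setdefault(node, set())
            if "namespace" in data:
                namespace[node] = data["namespace"]
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        if p is None:
            p = {t: 1.0 for t in parents}  # placeholder until corpus-derived
        return cls(parents=parents, p=p, namespace=namespace)


def probabilities_from_corpus(
    parents: Dict[str, set],
    annotations: Dict[str, set],
    namespace: Dict[str, str] | None = None,
) -> Ontology:
    """Estimate term probabilities from an annotation corpus.

    ``P(t)`` is the fraction of proteins annotated with ``t`` or any
    descendant (ancestor propagation). Terms never observed receive the
    smallest observed probability, keeping logs finite. Roots are forced
    to 1.
    """
    ont = Ontology(parents=parents, p={t: 1.0 for t in parents},
                   namespace=namespace or {})
    n = len(annotations)
    if n == 0:
        raise ValueError("empty annotation corpus")
    counts: Dict[str, int] = {t: 0 for t in parents}
    for terms in annotations.values():
        reached: set = set()
        for t in terms:
            reached |= ont.ancestors(t)
        for t in reached:
            counts[t] += 1
    floor = 1.0 / (2 * n)
    p = {t: (counts[t] / n if counts[t] else floor) for t in parents}
    for t, ps in parents.items():
        if not ps:
            p[t] = 1.0
    return Ontology(parents=parents, p=p, namespace=namespace or {})


def go_term_similarity(a: str, b: str, ont: Ontology) -> float:
    """Lin-style similarity between two ontology terms.

    The LCA is the common ancestor (terms included) with minimal
    probability, i.e. maximal information content; ties break on the term
    ID. Equals 1 for a == b with informative p, 0 when the only common
    ancestor is uninformative (the root).
    """
    if a not in ont.parents:
        raise UnknownTermError(a)
    if b not in ont.parents:
        raise UnknownTermError(b)
    ns_a, ns_b = ont.namespace.get(a), ont.namespace.get(b)
    if ns_a != ns_b:
        raise NamespaceError(f"{a} ({ns_a}) vs {b} ({ns_b})")
    common = ont.ancestors(a) & ont.ancestors(b)
    if not common:
        return 0.0
    lca = min(common, key=lambda t: (ont.p[t], t))
    denom = math.log(ont.p[a]) + math.log(ont.p[b])
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    return 2.0 * math.log(ont.p[lca]) / denom


def annotation_set_similarity(
    terms_x: set, terms_y: set, ont: Ontology
) -> float | None:
    """Best-match average similarity between two GO term sets.

    Symmetric; 1 iff the sets are equal (given informative terms); ``None``
    (undefined) when either set is empty.
    """
    if not terms_x or not terms_y:
        return None
    sims: Dict[tuple, float] = {}
    for a in terms_x:
        for b in terms_y:
            sims[(a, b)] = go_term_similarity(a, b, ont)
    total = sum(max(sims[(a, b)] for b in terms_y) for a in terms_x)
    total += sum(max(sims[(a, b)] for a in terms_x) for b in terms_y)
    return total / (len(terms_x) + len(terms_y))


#: Keyword categories excluded from the keyword score.
IGNORED_KEYWORD_CATEGORIES = {"technical term", "coding sequence diversity"}


def filter_keywords(
    keywords: set, categories: Dict[str, str] | None = None
) -> set:
    """Drop keywords belonging to ignored categories (when a category map
    is available)."""
    if not categories:
        return set(keywords)
    return {
        k for k in keywords
        if categories.get(k, "").lower() not in IGNORED_KEYWORD_CATEGORIES
    }


def keyword_similarity(kx: set, ky: set) -> float | None:
    """Dice coefficient between two (pre-filtered) keyword sets; undefined
    when both are empty."""
    if not kx and not ky:
        return None
    if not kx or not ky:
        return 0.0
    return 2.0 * len(kx & ky) / (len(kx) + len(ky))


_UNINFORMATIVE_PREFIXES = (
    "uncharacterized", "putative", "potential", "probable",
    "inactive", "likely", "unknown",
)


def normalize_name(name: str) -> str | None:
    """Normalise a recommended protein name for comparison.

    Returns ``None`` for names that are uninformative (empty, or starting
    with uncharacterized/putative/...). The word "protein" is removed, case
    is folded and whitespace collapsed.
    """
    stripped = name.strip().lower()
    if not stripped:
        return None
    if stripped.split()[0] in _UNINFORMATIVE_PREFIXES:
        return None
    words = [w for w in stripped.split() if w != "protein"]
    normalized = " ".join(words)
    return normalized or None


def name_similarity(name_x: str, name_y: str) -> float | None:
    """Normalised Levenshtein similarity between two protein names."""
    nx = normalize_name(name_x)
    ny = normalize_name(name_y)
    if nx is None or ny is None:
        return None
    if nx == ny:
        return 1.0
    dist = edlib.align(nx, ny, task="distance")["editDistance"]
    return 1.0 - dist / max(len(nx), len(ny))


def _pair_scores(rep: ProteinSequence, member: ProteinSequence, ont: Ontology | None):
    go = (
        annotation_set_similarity(rep.go_terms, member.go_terms, ont)
        if ont is not None
        else None
    )
    kw = keyword_similarity(rep.keywords, member.keywords)
    nm = name_similarity(rep.name, member.name)
    return {"go": go, "keyword": kw, "name": nm}


def cluster_consistency(
    cluster: ClusterRecord,
    seqs: Sequence[ProteinSequence],
    ont: Ontology | None = None,
) -> Dict[str, tuple | None]:
    """Worst and mean representative-vs-member score per annotation type.

    Returns ``{type: (worst, mean) | None, "average": float | None}`` where
    ``None`` marks a type with no defined pair in this cluster, and
    "average" is the cross-type mean of the defined per-type means.
    Requires cluster size >= 2.
    """
    if cluster.size < 2:
        raise ValueError("consistency is only defined for clusters of size >= 2")
    index = {s.accession: s for s in seqs}
    rep = index[cluster.representative]
    per_type: Dict[str, List[float]] = {"go": [], "keyword": [], "name": []}
    for m in cluster.members:
        if m == cluster.representative:
            continue
        scores = _pair_scores(rep, index[m], ont)
        for t, v in scores.items():
            if v is not None:
                per_type[t].append(v)
    out: Dict[str, tuple | None] = {}
    means = []
    for t, values in per_type.items():
        if values:
            out[t] = (min(values), sum(values) / len(values))
            means.append(out[t][1])
        else:
            out[t] = None
    out["average"] = sum(means) / len(means) if means else None
    return out


def consistency_report(
    clustering: Sequence[ClusterRecord],
    seqs: Sequence[ProteinSequence],
    ont: Ontology | None = None,
) -> Dict[str, Dict[str, float | None]]:
    """Database-level consistency summary over all non-singleton clusters.

    For each annotation type, the per-cluster worst and mean scores are
    averaged over clusters where the type is defined; "average" aggregates
    the cross-type per-cluster averages. Singletons are excluded.
    """
    worst: Dict[str, List[float]] = {"go": [], "keyword": [], "name": []}
    mean: Dict[str, List[float]] = {"go": [], "keyword": [], "name": []}
    averages: List[float] = []
    n_scored = 0
    for c in clustering:
        if c.size < 2:
            continue
        scores = cluster_consistency(c, seqs, ont)
        n_scored += 1
        for t in ("go", "keyword", "name"):
            if scores[t] is not None:
                worst[t].append(scores[t][0])
                mean[t].append(scores[t][1])
        if scores["average"] is not None:
            averages.append(scores["average"])
    def _avg(v):
        return sum(v) / len(v) if v else None
    report: Dict[str, Dict[str, float | None]] = {
        t: {"worst": _avg(worst[t]), "mean": _avg(mean[t])}
        for t in ("go", "keyword", "name")
    }
    report["average"] = {"mean": _avg(averages), "worst": None}
    report["n_clusters_scored"] = {"mean": float(n_scored), "worst": None}
    return report


def cluster_compactness(
    cluster: ClusterRecord,
    seqs: Sequence[ProteinSequence],
    sample_size: int = 10,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
) -> tuple:
    """Mean and worst pairwise sequence identity within a cluster.

    All pairs are aligned; clusters larger than ``sample_size`` are first
    down-sampled uniformly (seeded) as in the reference evaluation
    procedure. Requires cluster size >= 2.
    """
    if cluster.size < 2:
        raise ValueError("compactness is only defined for clusters of size >= 2")
    matrix = matrix or blosum62()
    index = {s.accession: s for s in seqs}
    members = list(cluster.members)
    if len(members) > sample_size:
        rng = np.random.default_rng(seed)
        members = [
            members[i]
            for i in sorted(rng.choice(len(members), size=sample_size,
                                       replace=False))
        ]
    identities = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            identities.append(_align.align_pair(index[a], index[b], matrix).identity)
    return (sum(identities) / len(identities), min(identities))
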