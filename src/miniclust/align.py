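"""Pairwise local alignment, reduced-alphabet encoding and hashing.

This is the similarity engine behind every clustering stage: an affine-gap
Smith-Waterman aligner with a fully deterministic traceback, plus the
five-letter alphabet reduction and the 64-bit hashing used by the
redundancy-filtering step.

Scoring follows the BLOSUM62 convention throughout: a gap of length ``k``
costs ``gap_open + k * gap_extend`` (the first gapped residue pays both
penalties). Traceback ties are resolved in the fixed priority
diagonal > up (gap in target) > left (gap in query), and within a gap the
gap is closed as early as possible, so identical inputs always yield an
identical alignment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from numba import njit

if TYPE_CHECKING:  # pragma: no cover
    from .core_io import ProteinSequence

#: Residue order used for integer encoding; the 20 standard residues plus X.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
STANDARD_AA = ALPHABET[:20]
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Karlin-Altschul constants for gapped BLOSUM62 statistics (shared by the
#: profile-search E-values and the subalignment E-value of the annotation
#: transfer). Units: lam is per raw score unit.
KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

#: Five-class physicochemical partition used by the redundancy filter:
#: tiny/small (A), cysteine (C), charged-polar/acidic (D), basic (K),
#: hydrophobic/aromatic (L). Any fixed 5-class partition works because hash
#: bucket members are always verified by exact residue comparison.
REDUCED_CLASSES = {
    "A": "ASTGP",
    "C": "C",
    "D": "DENQBZX",
    "K": "KRH",
    "L": "MILVFYW",
}
_REDUCE_TABLE = str.maketrans(
    {aa: cls for cls, members in REDUCED_CLASSES.items() for aa in members}
)

# module-level alignment call counter, used to verify the linear-time claim
# of incremental updates by instrumentation
_n_alignments = 0


def reset_alignment_counter() -> None:
    global _n_alignments
    _n_alignments = 0


def alignment_count() -> int:
    return _n_alignments


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 indices into :data:`ALPHABET`."""
    try:
        return np.array([_AA_INDEX[a] for a in residues], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-standard residue {exc} in sequence") from exc


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue substitution scores with affine gap penalties."""

    alphabet: str
    scores: np.ndarray  # (len(alphabet), len(alphabet)) float64
    gap_open: int = 11
    gap_extend: int = 1
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])

    @classmethod
    def blosum62(cls, gap_open: int = 11, gap_extend: int = 1) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        return cls._from_biopython(
            substitution_matrices.load("BLOSUM62"), gap_open, gap_extend, "BLOSUM62"
        )

    @classmethod
    def from_ncbi(
        cls, path, gap_open: int = 11, gap_extend: int = 1
    ) -> "SubstitutionMatrix":
        """Load a matrix from NCBI matrix text format (e.g. a BLOSUM file)."""
        from Bio.Align import substitution_matrices

        with open(path) as handle:
            mat = substitution_matrices.read(handle)
        return cls._from_biopython(mat, gap_open, gap_extend, str(path))

    @classmethod
    def _from_biopython(cls, mat, gap_open, gap_extend, name) -> "SubstitutionMatrix":
        n = len(ALPHABET)
        scores = np.zeros((n, n), dtype=np.float64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                scores[i, j] = mat[a, b]
        return cls(ALPHABET, scores, gap_open, gap_extend, name)


# default matrix, constructed lazily so importing the package stays cheap
_BLOSUM62: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = SubstitutionMatrix.blosum62()
    return _BLOSUM62


@dataclass
class AlignmentResult:
    """Local alignment summary between a query and a target sequence.

    ``score`` is the raw gap-penalised substitution score. ``identity`` is
    the fraction of aligned (residue-residue) columns with identical
    residues; gap columns are excluded. ``q_cov``/``t_cov`` are the aligned
    span lengths divided by the full sequence lengths. ``score_per_res`` is
    score divided by the number of aligned columns (the similarity measure
    used for member reassignment and the diversity filters).
    """

    q_id: str
    t_id: str
    score: float
    n_identical: int
    n_aligned_cols: int
    q_start: int  # 1-based inclusive span on the query (0 if no alignment)
    q_end: int
    t_start: int
    t_end: int
    q_len: int
    t_len: int
    ops: np.ndarray = field(repr=False)  # 0=match col, 1=gap in target, 2=gap in query

    @property
    def identity(self) -> float:
        return self.n_identical / self.n_aligned_cols if self.n_aligned_cols else 0.0

    @property
    def q_cov(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len if self.q_end else 0.0

    @property
    def t_cov(self) -> float:
        return (self.t_end - self.t_start + 1) / self.t_len if self.t_end else 0.0

    @property
    def score_per_res(self) -> float:
        return self.score / self.n_aligned_cols if self.n_aligned_cols else float("-inf")

    @property
    def shorter_cov(self) -> float:
        """Coverage of the shorter of the two sequences."""
        return self.q_cov if self.q_len <= self.t_len else self.t_cov


@njit(cache=True)
def _sw_kernel(profile, tcodes, gap_open, gap_ext):  # pragma: no cover - numba
    m = profile.shape[0]
    n = tcodes.shape[0]
    NEG = -1.0e30
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    best = 0.0
    bi = 0
    bj = 0
    go = float(gap_open + gap_ext)
    ge = float(gap_ext)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            h = H[i - 1, j - 1] + profile[i - 1, tcodes[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # deterministic traceback: diagonal > up > left; gaps close early
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = F (gap in target), 2 = E (gap in query)
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + profile[i - 1, tcodes[j - 1]]:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            if F[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return best, i, j, bi, bj, ops, k


def _align_profile(
    profile: np.ndarray,
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    gap_open: int,
    gap_extend: int,
):
    """Run the kernel and decode the traceback.

    ``profile`` has one score row per query position; ``q_codes`` supplies
    the query residues used only for identity counting.
    """
    global _n_alignments
    _n_alignments += 1
    score, i0, j0, bi, bj, ops_rev, k = _sw_kernel(
        profile, t_codes, gap_open, gap_extend
    )
    ops = ops_rev[:k][::-1].copy()
    if k == 0 or score <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0, np.empty(0, dtype=np.int8)
    n_cols = int(np.count_nonzero(ops == 0))
    n_id = 0
    qi, tj = i0, j0
    for op in ops:
        if op == 0:
            if q_codes[qi] == t_codes[tj]:
                n_id += 1
            qi += 1
            tj += 1
        elif op == 1:
            qi += 1
        else:
            tj += 1
    return float(score), i0 + 1, bi, j0 + 1, bj, n_id, n_cols, ops


def align_pair(
    q: "ProteinSequence", t: "ProteinSequence", matrix: SubstitutionMatrix | None = None
) -> AlignmentResult:
    """Smith-Waterman local alignment of two protein sequences.

    The alignment is computed in a canonical orientation — the sequence with
    the lexicographically smaller (residues, accession) pair acts as the DP
    query — and the result fields are swapped back afterwards. Together with
    the deterministic traceback this makes score, identity and coverages
    exactly symmetric under swapping query and target, even between
    co-optimal alignments.
    """
    matrix = matrix or blosum62()
    if not q.residues or not t.residues:
        raise ValueError("cannot align an empty sequence")
    swapped = (q.residues, q.accession) > (t.residues, t.accession)
    a, b = (t, q) if swapped else (q, t)
    a_codes = encode(a.residues)
    b_codes = encode(b.residues)
    profile = matrix.scores[a_codes.astype(np.intp)]
    score, as_, ae, bs, be, n_id, n_cols, ops = _align_profile(
        profile, a_codes, b_codes, matrix.gap_open, matrix.gap_extend
    )
    if swapped:
        as_, ae, bs, be = bs, be, as_, ae
        # op 1 = gap in target (consumes query); swap roles
        ops = np.where(ops == 1, np.int8(2), np.where(ops == 2, np.int8(1), ops))
    return AlignmentResult(
        q_id=q.accession,
        t_id=t.accession,
        score=score,
        n_identical=n_id,
        n_aligned_cols=n_cols,
        q_start=as_,
        q_end=ae,
        t_start=bs,
        t_end=be,
        q_len=len(q.residues),
        t_len=len(t.residues),
        ops=ops,
    )


def reduce_alphabet(residues: str) -> str:
    """Map a residue string onto the fixed five-letter alphabet.

    Length-preserving and many-to-one; residues in the same physicochemical
    class become indistinguishable, which is what lets near-identical
    sequences share a hash bucket.
    """
    return residues.translate(_REDUCE_TABLE)


def hash64(reduced: str) -> int:
    """Stable 64-bit digest of a (reduced) sequence string.

    Deterministic across runs and platforms; collisions are harmless because
    bucket members are verified by exact comparison before clustering.
    """
    return int.from_bytes(
        hashlib.blake2b(reduced.encode("ascii"), digest_size=8).digest(), "big"
    )
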