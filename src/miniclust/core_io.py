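"""Domain types and readers/writers for the on-disk formats.

Formats covered: FASTA with UniProt-style headers, A3M cluster alignments,
the two-column representative/member cluster TSV, and the nine-column domain
annotation TSV. Long input sequences are split into <=14 000 residue pieces
during normalization, mirroring the preprocessing of the full-scale
clustering pipeline.

Coordinates in :class:`DomainAnnotation` are 1-based inclusive (the
human-readable TSV convention); alignment code internally uses 0-based
half-open and converts at this boundary.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .msa import Msa

logger = logging.getLogger("miniclust")

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
_AMBIGUOUS = str.maketrans({c: "X" for c in "UOBZJ"})

CLUSTER_ID_RE = re.compile(r"^uc(90|50|30)-(\d{4})-(\d+)$")


class FormatError(ValueError):
    """Malformed input file."""


class DuplicateIdError(FormatError):
    """Two records share one accession."""


class AlphabetError(FormatError):
    """A record contains characters outside the amino-acid alphabet."""


@dataclass
class ProteinSequence:
    """A protein entry: accession, residues and optional annotations.

    ``source`` distinguishes reviewed (Swiss-Prot-like) from unreviewed
    (TrEMBL-like) entries; it drives the precedence rules of cluster summary
    headers. ``keywords``, ``go_terms`` and ``name`` feed the consistency
    evaluation and may be empty.
    """

    accession: str
    residues: str
    description: str = ""
    source: str = "unreviewed"  # "reviewed" | "unreviewed"
    keywords: set = field(default_factory=set)
    go_terms: set = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.source not in ("reviewed", "unreviewed"):
            raise ValueError(f"{self.accession}: bad source {self.source!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ClusterRecord:
    """One cluster: representative accession, ordered members, stable ID.

    Identifiers have the form ``uc<level>-<yymm>-<number>`` and are assigned
    per release in insertion order; intermediate clusterings may carry
    ``cluster_id=None``.
    """

    representative: str
    members: list
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative} not among members"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in cluster")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DomainAnnotation:
    """A database domain match with coordinates on query and target."""

    query_id: str
    target_id: str
    database: str  # "pfam" | "scop" | "pdb"
    q_start: int
    q_end: int
    q_len: int
    t_start: int
    t_end: int
    t_len: int
    evalue: float

    def validate(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValueError(f"bad query span in {self}")
        if not (1 <= self.t_start <= self.t_end <= self.t_len):
            raise ValueError(f"bad target span in {self}")
        if not self.evalue > 0:
            raise ValueError(f"non-positive E-value in {self}")

    @property
    def q_span_len(self) -> int:
        return self.q_end - self.q_start + 1


def normalize_residues(raw: str, accession: str = "?") -> str:
    """Uppercase and map ambiguous residue codes (U/O/B/Z/J) to X.

    Rejects '*', gaps and anything outside the amino-acid alphabet.
    """
    residues = raw.upper()
    mapped = residues.translate(_AMBIGUOUS)
    if mapped != residues:
        logger.warning("%s: ambiguous residues mapped to X", accession)
    bad = set(mapped) - VALID_RESIDUES
    if bad:
        raise AlphabetError(
            f"record {accession}: invalid characters {sorted(bad)}"
        )
    return mapped


def parse_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    The accession is the first whitespace-delimited header token; the rest of
    the header line becomes the description. Headers of the UniProt dialect
    (``sp|...`` / ``tr|...``) set the reviewed/unreviewed source flag.
    """
    from Bio import SeqIO

    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise DuplicateIdError(f"duplicate accession {accession}")
        seen.add(accession)
        description = rec.description[len(rec.id):].strip()
        source = "reviewed" if accession.startswith("sp|") else "unreviewed"
        residues = normalize_residues(str(rec.seq), accession)
        records.append(
            ProteinSequence(
                accession=accession,
                residues=residues,
                description=description,
                source=source,
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as out:
        for s in seqs:
            header = f">{s.accession}"
            if s.description:
                header += f" {s.description}"
            out.write(header + "\n")
            for i in range(0, len(s.residues), width):
                out.write(s.residues[i : i + width] + "\n")


def split_long_sequences(
    seqs: Sequence[ProteinSequence], max_len: int = 14000
) -> list[ProteinSequence]:
    """Split entries longer than ``max_len`` residues into numbered pieces.

    Pieces are near-equal (``ceil(L/max_len)`` of them) with accessions
    ``<acc>_1``, ``<acc>_2``, ...; concatenating them in order reconstructs
    the original residues. Entries of length <= ``max_len`` pass through
    unchanged.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out: list[ProteinSequence] = []
    for s in seqs:
        L = len(s.residues)
        if L <= max_len:
            out.append(s)
            continue
        n = math.ceil(L / max_len)
        base, extra = divmod(L, n)
        pos = 0
        for i in range(n):
            size = base + (1 if i < extra else 0)
            piece = s.residues[pos : pos + size]
            pos += size
            out.append(
                ProteinSequence(
                    accession=f"{s.accession}_{i + 1}",
                    residues=piece,
                    description=s.description,
                    source=s.source,
                    keywords=set(s.keywords),
                    go_terms=set(s.go_terms),
                    name=s.name,
                )
            )
        logger.info("split %s (%d aa) into %d pieces", s.accession, L, n)
    return out


def assign_cluster_ids(
    clusters: Sequence[ClusterRecord], level: int, release: str
) -> list[ClusterRecord]:
    """Assign ``uc<level>-<yymm>-<n>`` identifiers in insertion order."""
    if level not in (90, 50, 30):
        raise ValueError("level must be 90, 50 or 30")
    if not re.fullmatch(r"\d{4}", release):
        raise ValueError("release tag must match yymm (four digits)")
    for n, c in enumerate(clusters, start=1):
        c.cluster_id = f"uc{level}-{release}-{n}"
    return list(clusters)


def write_cluster_tsv(clustering: Sequence[ClusterRecord], path) -> None:
    """Write representative/member pairs, one line each, self-pair first."""
    with open(path, "w") as out:
        for c in clustering:
            out.write(f"{c.representative}\t{c.representative}\n")
            for m in c.members:
                if m != c.representative:
                    out.write(f"{c.representative}\t{m}\n")


def read_cluster_tsv(
    path, level: int | None = None, release: str | None = None
) -> list[ClusterRecord]:
    """Inverse of :func:`write_cluster_tsv`.

    Cluster IDs are regenerated deterministically from representative file
    order when ``level`` and ``release`` are given, else left unset.
    """
    members: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            rep, mem = fields
            if rep not in members:
                members[rep] = []
                order.append(rep)
            if mem not in members[rep]:
                members[rep].append(mem)
    clusters = []
    for rep in order:
        mems = members[rep]
        if rep in mems:
            mems = [rep] + [m for m in mems if m != rep]
        clusters.append(ClusterRecord(representative=rep, members=mems))
    if level is not None and release is not None:
        assign_cluster_ids(clusters, level, release)
    return clusters


def _n_match_columns(row: str) -> int:
    return sum(1 for c in row if c.isupper() or c == "-")


def parse_a3m(path) -> Msa:
    """Read an A3M alignment: uppercase/'-' are match states, lowercase are
    insertions. All records must span the same number of match columns."""
    records: list[tuple[str, str]] = []
    acc = None
    parts: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if acc is not None:
                    records.append((acc, "".join(parts)))
                acc = line[1:].split()[0] if len(line) > 1 else ""
                parts = []
            elif line:
                if acc is None:
                    raise FormatError(f"{path}: sequence before first header")
                parts.append(line)
    if acc is not None:
        records.append((acc, "".join(parts)))
    if not records:
        raise FormatError(f"{path}: no A3M records found")
    n_match = _n_match_columns(records[0][1])
    for name, row in records[1:]:
        if _n_match_columns(row) != n_match:
            raise FormatError(
                f"{path}: record {name} has {_n_match_columns(row)} match "
                f"columns, expected {n_match}"
            )
    return Msa(records=records)


def write_a3m(msa: Msa, path) -> None:
    with open(path, "w") as out:
        for acc, row in msa.records:
            out.write(f">{acc}\n{row}\n")


_DATABASES = ("pfam", "scop", "pdb")


def write_annotation_tsv(annots: Sequence[DomainAnnotation], path) -> None:
    """Write the nine-column annotation table.

    Columns: query ID, target ID, query start/end/length, target
    start/end/length, E-value. All annotations are validated before anything
    is written.
    """
    for a in annots:
        a.validate()
    with open(path, "w") as out:
        for a in annots:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        a.query_id,
                        a.target_id,
                        a.q_start,
                        a.q_end,
                        a.q_len,
                        a.t_start,
                        a.t_end,
                        a.t_len,
                        f"{a.evalue:.3g}",
                    )
                )
                + "\n"
            )


def read_annotation_tsv(path, database: str = "pfam") -> list[DomainAnnotation]:
    if database not in _DATABASES:
        raise ValueError(f"unknown database {database!r}")
    annots = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            a = DomainAnnotation(
                query_id=fields[0],
                target_id=fields[1],
                database=database,
                q_start=int(fields[2]),
                q_end=int(fields[3]),
                q_len=int(fields[4]),
                t_start=int(fields[5]),
                t_end=int(fields[6]),
                t_len=int(fields[7]),
                evalue=float(fields[8]),
            )
            a.validate()
            annots.append(a)
    return annots


def validate_partition(
    clusters: Sequence[ClusterRecord], accessions: Iterable[str] | None = None
) -> None:
    """Check the partition invariants: disjoint members, representative in
    members, and (optionally) exact coverage of a given accession set."""
    seen: set[str] = set()
    for c in clusters:
        if c.representative not in c.members:
            raise ValueError(f"{c.cluster_id}: representative not a member")
        for m in c.members:
            if m in seen:
                raise ValueError(f"accession {m} occurs in two clusters")
            seen.add(m)
    if accessions is not None:
        expected = set(accessions)
        if seen != expected:
            missing = expected - seen
            extra = seen - expected
            raise ValueError(
                f"partition mismatch: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
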