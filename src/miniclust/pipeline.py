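"""End-to-end orchestration: build a full release from a FASTA file, or
update an existing release incrementally.

A release directory contains, per level (90/50/30): the cluster TSV, seed
(representative) FASTA, consensus FASTA with summary headers, and per
cluster A3M alignments; plus Uniboost variants of the 30-level alignments,
optional transferred annotations, and a machine-readable manifest. Outputs
are written to a temporary directory and renamed into place, so a failed
run leaves no partial release.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from pathlib import Path
from typing import Dict, List, Sequence

from . import annotate as _annotate
from . import cluster as _cluster
from . import core_io, msa as _msa
from .align import SubstitutionMatrix, blosum62
from .core_io import ClusterRecord, ProteinSequence

logger = logging.getLogger("miniclust")


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide settings; thresholds themselves live in ClusterParams."""

    release_tag: str = "2501"
    levels: tuple = (90, 50, 30)
    boost_filters: tuple = (10, 20, 30)
    boost_iterations: int = 4
    search_evalue_cutoff: float = 1e-3
    evalue_cutoff: float = 0.01
    max_overlap_frac: float = 0.10
    max_seq_len: int = 14000
    seed: int = 0

    def __post_init__(self) -> None:
        import re

        if not re.fullmatch(r"\d{4}", self.release_tag):
            raise ValueError("release_tag must match yymm (four digits)")
        if not set(self.levels) <= {90, 50, 30}:
            raise ValueError("levels must be a subset of {90, 50, 30}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Plain key=value config; tuple fields are comma-separated."""
        kwargs: Dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("levels", "boost_filters"):
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key in ("boost_iterations", "max_seq_len", "seed"):
                kwargs[key] = int(value)
            elif key in ("search_evalue_cutoff", "evalue_cutoff",
                         "max_overlap_frac"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _write_level(
    out: Path,
    level: int,
    clusters: List[ClusterRecord],
    index: Dict[str, ProteinSequence],
    matrix: SubstitutionMatrix,
    reuse: Dict[str, Path] | None = None,
) -> Dict[str, object]:
    """Write TSV, seed/consensus FASTA and A3Ms for one level; return
    per-cluster alignments for reuse.

    ``reuse`` maps cluster IDs to existing A3M files of unchanged clusters,
    whose alignments are re-read instead of recomputed.
    """
    prefix = out / f"uniclust{level}"
    core_io.write_cluster_tsv(clusters, f"{prefix}_cluster_mapping.tsv")
    reps = [index[c.representative] for c in clusters]
    core_io.write_fasta(reps, f"{prefix}_seed.fasta")

    a3m_dir = out / f"uniclust{level}_a3m"
    a3m_dir.mkdir(exist_ok=True)
    alignments: Dict[str, _msa.Msa] = {}
    consensus_records: List[ProteinSequence] = []
    for c in clusters:
        members = [index[m] for m in c.members]
        if reuse and c.cluster_id in reuse:
            alignment = core_io.parse_a3m(reuse[c.cluster_id])
        else:
            alignment = _msa.build_msa(members, c.representative, matrix)
        alignments[c.cluster_id] = alignment
        core_io.write_a3m(alignment, a3m_dir / f"{c.cluster_id}.a3m")
        cons = _msa.compute_consensus(alignment, matrix)
        header = _msa.summarize_headers(members, c.cluster_id, c.representative)
        consensus_records.append(
            ProteinSequence(
                accession=c.cluster_id, residues=cons.residues,
                description=header,
            )
        )
    core_io.write_fasta(consensus_records, f"{prefix}_consensus.fasta")
    return {"alignments": alignments, "consensus": consensus_records}


def run_build(
    fasta_path,
    config: PipelineConfig | None = None,
    out_dir="release",
    annotations: Sequence[core_io.DomainAnnotation] | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> Path:
    """Build a complete release from an input FASTA file.

    Stages: parse and normalise (long-sequence split) -> clustering cascade
    -> per-cluster MSAs, consensus sequences and summary headers per level
    -> Uniboost alignments for the 30-level clusters -> optional annotation
    transfer (cluster-level matches onto members) -> manifest. Deterministic
    under a fixed config.
    """
    config = config or PipelineConfig()
    matrix = matrix or blosum62()
    out_dir = Path(out_dir)
    seqs = core_io.parse_fasta(fasta_path)
    seqs = core_io.split_long_sequences(seqs, config.max_seq_len)
    index = {s.accession: s for s in seqs}

    tmp = out_dir.with_name(out_dir.name + ".tmp")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        u90, u50, u30 = _cluster.cascade(seqs, config.release_tag, matrix)
        by_level = {90: u90, 50: u50, 30: u30}
        core_io.write_fasta(seqs, tmp / "input.fasta")
        level_data = {}
        for level in config.levels:
            level_data[level] = _write_level(
                tmp, level, by_level[level], index, matrix
            )

        if 30 in config.levels and config.boost_filters:
            consensus_db = [
                ProteinSequence(accession=r.accession, residues=r.residues)
                for r in level_data[30]["consensus"]
            ]
            boost_params = _msa.BoostParams(
                n_iterations=config.boost_iterations,
                search_evalue_cutoff=config.search_evalue_cutoff,
            )
            filters = {
                lvl: _msa.BOOST_FILTERS[lvl] for lvl in config.boost_filters
            }
            for c in by_level[30]:
                alignment = level_data[30]["alignments"][c.cluster_id]
                boosted = _msa.uniboost(
                    alignment, consensus_db, matrix, boost_params, filters
                )
                for lvl, bmsa in boosted.items():
                    bdir = tmp / f"uniboost{lvl}_a3m"
                    bdir.mkdir(exist_ok=True)
                    core_io.write_a3m(bmsa, bdir / f"{c.cluster_id}.a3m")

        if annotations:
            params = _annotate.TransferParams(
                evalue_cutoff=config.evalue_cutoff,
                max_overlap_frac=config.max_overlap_frac,
            )
            transferred = []
            by_cluster: Dict[str, List] = {}
            for a in annotations:
                by_cluster.setdefault(a.query_id, []).append(a)
            for c in by_level[30]:
                if c.cluster_id not in by_cluster:
                    continue
                alignment = level_data[30]["alignments"][c.cluster_id]
                cons = _msa.compute_consensus(alignment, matrix)
                accepted = _annotate.accept_annotations(
                    by_cluster[c.cluster_id], params
                )
                members = [index[m] for m in c.members]
                transferred.extend(
                    _annotate.transfer_annotations(
                        accepted, alignment, cons, members, matrix, params
                    )
                )
            core_io.write_annotation_tsv(
                transferred, tmp / "member_annotations.tsv"
            )

        manifest = {
            "release_tag": config.release_tag,
            "levels": list(config.levels),
            "n_sequences": len(seqs),
            "n_clusters": {
                str(level): len(by_level[level]) for level in config.levels
            },
            "seed": config.seed,
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    tmp.rename(out_dir)
    logger.info("release written to %s", out_dir)
    return out_dir


def run_update(
    old_dir,
    new_fasta,
    config: PipelineConfig | None = None,
    out_dir=None,
    matrix: SubstitutionMatrix | None = None,
) -> Path:
    """Update an existing release to a new sequence set.

    Applies the incremental clustering update per level; MSAs and consensus
    records are recomputed only for clusters whose membership changed (new
    and removed clusters included), which is logged per level.
    """
    config = config or PipelineConfig()
    matrix = matrix or blosum62()
    old_dir = Path(old_dir)
    manifest = json.loads((old_dir / "manifest.json").read_text())
    if config.release_tag <= manifest["release_tag"]:
        raise ValueError(
            f"release_tag {config.release_tag} is not newer than "
            f"{manifest['release_tag']}"
        )
    out_dir = Path(out_dir) if out_dir else old_dir.with_name(
        old_dir.name + "_" + config.release_tag
    )
    old_seqs = core_io.parse_fasta(old_dir / "input.fasta")
    new_seqs = core_io.parse_fasta(new_fasta)
    new_seqs = core_io.split_long_sequences(new_seqs, config.max_seq_len)
    index = {s.accession: s for s in new_seqs}

    tmp = out_dir.with_name(out_dir.name + ".tmp")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    try:
        core_io.write_fasta(new_seqs, tmp / "input.fasta")
        n_clusters = {}
        for level in manifest["levels"]:
            old_clusters = core_io.read_cluster_tsv(
                old_dir / f"uniclust{level}_cluster_mapping.tsv"
            )
            core_io.assign_cluster_ids(
                old_clusters, level, manifest["release_tag"]
            )
            updated = _cluster.update_clustering(
                old_clusters, old_seqs, new_seqs,
                _cluster.LEVEL_PARAMS[level], matrix,
            )
            old_members = {
                c.cluster_id: tuple(c.members) for c in old_clusters
            }
            reuse = {
                c.cluster_id: old_dir / f"uniclust{level}_a3m" / f"{c.cluster_id}.a3m"
                for c in updated
                if old_members.get(c.cluster_id) == tuple(c.members)
            }
            reuse = {k: v for k, v in reuse.items() if v.exists()}
            logger.info(
                "level %d: %d clusters, %d recomputed", level, len(updated),
                len(updated) - len(reuse),
            )
            _write_level(tmp, level, updated, index, matrix, reuse)
            n_clusters[str(level)] = len(updated)
        new_manifest = {
            "release_tag": config.release_tag,
            "levels": manifest["levels"],
            "n_sequences": len(new_seqs),
            "n_clusters": n_clusters,
            "seed": config.seed,
            "updated_from": manifest["release_tag"],
        }
        (tmp / "manifest.json").write_text(
            json.dumps(new_manifest, indent=2) + "\n"
        )
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    tmp.rename(out_dir)
    return out_dir
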