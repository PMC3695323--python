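"""Standard-format I/O: FASTA, GFF3, BED, TSV reports, pipeline config.

Internal coordinates are 0-based half-open; GFF3 is the only 1-based
surface and conversion happens here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .miner import MITECandidate
from .sequences import DNA_ALPHABET, GenomicSequence


def read_fasta(path) -> list[GenomicSequence]:
    """Read a multi-record FASTA; residues are upper-cased and validated
    (errors name the record and offset of the first illegal character)."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(residues) if c in bad)
            raise ValueError(
                f"{path.name}: record {rec.id!r} has illegal character "
                f"{residues[pos]!r} at offset {pos}")
        records.append(GenomicSequence(rec.id, residues, rec.description))
    if not records:
        raise ValueError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(sequences: list[GenomicSequence], path) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.id,
                      description=s.description or "") for s in sequences]
    SeqIO.write(recs, str(path), "fasta")


def write_named_fasta(named: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs without alphabet validation — consensus
    sequences may carry IUPAC degenerate codes."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in named]
    SeqIO.write(recs, str(path), "fasta")


def _sorted_candidates(candidates: list[MITECandidate]) -> list[MITECandidate]:
    return sorted(candidates, key=lambda c: (c.sequence_id, c.start, c.end))


def write_gff3(candidates: list[MITECandidate], path,
               source: str = "stowaway-kit") -> None:
    """GFF3 (1-based inclusive) with a version pragma; type ``MITE``."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(_sorted_candidates(candidates)):
        attrs = (f"ID=mite{i:05d};tir_len={c.tir.tir_length};"
                 f"tsd={c.tsd or 'absent'};at_content={c.at_content:.4f};"
                 f"hairpin_score={c.hairpin_score:.4f};family=NA")
        lines.append("\t".join([
            c.sequence_id, source, "MITE", str(c.start + 1), str(c.end),
            ".", c.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_spans(path) -> list[tuple[str, int, int]]:
    """Recover (sequence_id, start, end) 0-based half-open spans from GFF3."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        out.append((cols[0], int(cols[3]) - 1, int(cols[4])))
    return out


def write_bed(candidates: list[MITECandidate], path) -> None:
    """BED (0-based half-open), sorted by (seqid, start)."""
    lines = []
    for i, c in enumerate(_sorted_candidates(candidates)):
        lines.append("\t".join([c.sequence_id, str(c.start), str(c.end),
                                f"mite{i:05d}", "0", c.strand]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def candidates_to_fasta(candidates: list[MITECandidate], path) -> None:
    seqs = [GenomicSequence(f"mite{i:05d}", c.seq,
                            f"{c.sequence_id}:{c.start}-{c.end}")
            for i, c in enumerate(_sorted_candidates(candidates))]
    write_fasta(seqs, path)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class SimulateConfig:
    genome_length: int = 200_000
    at_fraction: float = 0.65
    n_families: int = 3
    copies_per_family: int = 10
    n_insertions: int = 30
    divergence: float = 0.05
    indel_rate: float = 0.002
    consensus_length: int = 274
    tir_length: int = 16
    terminal_motif: str = "CTCCCT"
    min_spacing: int = 100


@dataclass
class MineConfig:
    terminal_motif: str = "CTCCCT"
    min_tir: int = 13
    max_tir: int = 30
    max_mismatch_per_tir: int = 2
    min_len: int = 80
    max_len: int = 600
    require_tsd: bool = True


@dataclass
class ClassifyConfig:
    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_length: int = 80


@dataclass
class ScreenConfig:
    n_clones: int = 141
    clone_size_mbp: float = 0.121
    genome_size_mbp: float = 980.0
    method: str = "naive"
    ci_level: float = 0.95


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "stowaway_out"
    verbosity: str = "info"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    mine: MineConfig = field(default_factory=MineConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)


_SECTIONS = {"simulate": SimulateConfig, "mine": MineConfig,
             "classify": ClassifyConfig, "screen": ScreenConfig}


def _build(cls, data: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Strict construction: unknown keys anywhere are rejected."""
    data = dict(data or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        block = data.pop(section, None)
        if block is not None:
            if not isinstance(block, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            kwargs[section] = _build(cls, block, section)
    top_valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data, **kwargs)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def families_to_tsv(families, path) -> None:
    rows = [{"element_id": m, "family_id": f.family_id}
            for f in families for m in f.member_ids]
    pd.DataFrame(rows, columns=["element_id", "family_id"]).to_csv(
        path, sep="\t", index=False)
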