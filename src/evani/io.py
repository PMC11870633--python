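"""Readers and writers: FASTA, Newick, BED6, TSV matrices, INI configs.

All writers are atomic (write to a temp file in the target directory,
then rename), so a crashed run never leaves a half-written file that
parses as complete.  One genome is the concatenation of all records in
its FASTA file; k-mer windows and fragments never span record
boundaries upstream because callers receive the records individually.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DataError
from .matrix import DistanceMatrix, iter_pairs
from .simulate import HomologyMap, SimConfig, SimGenome

logger = logging.getLogger("evani")

__all__ = [
    "GenomeRecord",
    "read_fasta",
    "write_fasta",
    "concat_records",
    "read_newick",
    "write_newick",
    "write_bed",
    "read_bed",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_long_tsv",
    "read_long_tsv",
    "write_homology_tsv",
    "read_sim_config",
    "write_sim_config",
    "atomic_write_text",
]

_ALLOWED = set("ACGTN")


@dataclass
class GenomeRecord:
    """One FASTA record after normalization (uppercase, U->T, IUPAC->N)."""

    id: str
    description: str
    sequence: str


def atomic_write_text(path: str, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-evani-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _normalize(seq: str, record_id: str) -> str:
    up = seq.upper().replace("U", "T")
    cleaned = []
    n_other = 0
    for ch in up:
        if ch in _ALLOWED:
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_other += 1
    if n_other:
        logger.warning(
            "record %s: %d non-ACGTN characters replaced with N", record_id, n_other
        )
    return "".join(cleaned)


def read_fasta(path: str) -> list[GenomeRecord]:
    """Parse a multi-record FASTA into normalized GenomeRecords."""
    records = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), rec.id)
        if not seq:
            raise DataError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description[len(rec.id) :].strip()
        records.append(GenomeRecord(id=rec.id, description=desc, sequence=seq))
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path: str, wrap: int = 80) -> None:
    """Write records ((id, seq) pairs, GenomeRecords, or a dict) wrapped at 80 cols."""
    if isinstance(records, dict):
        records = list(records.items())
    lines = []
    for rec in records:
        if isinstance(rec, GenomeRecord):
            rid, desc, seq = rec.id, rec.description, rec.sequence
        else:
            rid, seq = rec
            desc = ""
        header = f">{rid} {desc}".rstrip()
        lines.append(header)
        for off in range(0, len(seq), wrap):
            lines.append(seq[off : off + wrap])
    atomic_write_text(path, "\n".join(lines) + "\n")


def concat_records(records: list[GenomeRecord]) -> str:
    """One genome = the concatenation of all records in its file."""
    return "".join(r.sequence for r in records)


def read_newick(path: str) -> dendropy.Tree:
    """Read a single rooted tree; missing branch lengths default to 0."""
    try:
        tree = dendropy.Tree.get(
            path=path, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise DataError(f"failed to parse Newick file {path}: {exc}") from exc
    labels = [
        leaf.taxon.label if leaf.taxon else leaf.label
        for leaf in tree.leaf_node_iter()
    ]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate leaf labels in {path}")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing > 1:  # the root edge is legitimately length-free
        logger.warning("%s: %d branch lengths missing, set to 0", path, n_missing - 1)
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    atomic_write_text(path, text)


def write_bed(genome: SimGenome, path: str) -> None:
    """Gene annotation as 6-column BED (name = family id, strand +)."""
    lines = []
    for (start, end), fam in zip(genome.genes, genome.family_ids):
        lines.append(f"{genome.leaf_id}\t{start}\t{end}\tfam{fam}\t0\t+")
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise DataError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts[:6]
            rows.append((chrom, int(start), int(end), name, int(score), strand))
    return rows


def write_homology_tsv(homology: HomologyMap, path: str) -> None:
    lines = ["leaf\tgene_index\tfamily_id\torigin"]
    for rec in homology.records:
        lines.append(f"{rec.leaf_id}\t{rec.gene_index}\t{rec.family_id}\t{rec.origin}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# distance matrices


def write_matrix_tsv(dm: DistanceMatrix, path: str) -> None:
    """Square TSV: labels as first row and first column, 12 sig digits."""
    lines = ["\t".join([""] + dm.labels)]
    for i, lab in enumerate(dm.labels):
        cells = [lab] + [f"{v:.12g}" for v in dm.values[i]]
        lines.append("\t".join(cells))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_matrix_tsv(path: str, kind: str = "distance") -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        rows = []
        row_labels = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_labels != labels:
        raise DataError(f"{path}: row labels do not match column labels")
    values = np.asarray(rows, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise DataError(f"{path}: matrix is not square")
    if not np.allclose(values, values.T, atol=1e-9):
        raise DataError(f"{path}: matrix is not symmetric")
    return DistanceMatrix(labels=labels, values=values, kind=kind)


def write_long_tsv(dm: DistanceMatrix, path: str) -> None:
    """Upper-triangle pair list; undefined entries as value 0, defined_flag 0."""
    lines = ["id1\tid2\tvalue\tkind\tdefined_flag"]
    for i, j in iter_pairs(dm.labels):
        flag = 1 if dm.defined[i, j] else 0
        value = dm.values[i, j] if flag else 0.0
        lines.append(
            f"{dm.labels[i]}\t{dm.labels[j]}\t{value:.12g}\t{dm.kind}\t{flag}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_long_tsv(path: str) -> DistanceMatrix:
    pairs = {}
    labels: list[str] = []
    kind = "distance"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for name in ("id1", "id2", "value"):
            if name not in col:
                raise DataError(f"{path}: missing column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            a, b = parts[col["id1"]], parts[col["id2"]]
            value = float(parts[col["value"]])
            flag = int(parts[col["defined_flag"]]) if "defined_flag" in col else 1
            if "kind" in col:
                kind = parts[col["kind"]]
            for lab in (a, b):
                if lab not in pairs:
                    pairs[lab] = len(labels)
                    labels.append(lab)
            pairs[(a, b)] = (value, flag)
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    defined = np.ones((n, n), dtype=bool)
    index = {lab: i for i, lab in enumerate(labels)}
    for key, entry in pairs.items():
        if not isinstance(key, tuple):
            continue
        a, b = key
        value, flag = entry
        i, j = index[a], index[b]
        values[i, j] = values[j, i] = value
        defined[i, j] = defined[j, i] = bool(flag)
    if kind == "similarity":
        np.fill_diagonal(values, values.max(initial=1.0))
    return DistanceMatrix(
        labels=labels, values=values, kind=kind, defined=defined
    )


# ---------------------------------------------------------------------------
# configuration


def read_sim_config(path: str) -> SimConfig:
    """Flat INI-style ``[simulate]`` section mapped onto SimConfig.

    Unknown keys are rejected so typos fail loudly instead of silently
    simulating the wrong scenario.
    """
    parser = configparser.ConfigParser()
    if not parser.read(path):
        raise DataError(f"cannot read config file {path}")
    if "simulate" not in parser:
        raise ConfigError(f"{path}: missing [simulate] section")
    fields = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    kwargs = {}
    for key, raw in parser["simulate"].items():
        if key not in fields:
            raise ConfigError(f"{path}: unknown simulate key {key!r}")
        is_int = fields[key] in (int, "int")
        kwargs[key] = int(raw) if is_int else float(raw)
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def write_sim_config(cfg: SimConfig, path: str) -> None:
    lines = ["[simulate]"]
    for f in dataclasses.fields(SimConfig):
        lines.append(f"{f.name} = {getattr(cfg, f.name)}")
    atomic_write_text(path, "\n".join(lines) + "\n")
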