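"""Readers and writers for every on-disk artifact the pipeline touches.

All coordinates in this package are 1-based and inclusive, matching the
convention used for domain positions ("the 14th amino acid of the domain").
TSV is the canonical tabular format: decimal point '.', no thousands
separators, row identifiers in the first column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("familyscope")

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"


@dataclass
class SequenceSet:
    """An ordered collection of named sequences of one molecule type.

    ``records`` is a list of ``(id, sequence)`` pairs; ids must be unique and
    sequences non-empty. ``moltype`` is ``"nucleotide"`` or ``"protein"``.
    """

    records: list[tuple[str, str]]
    moltype: str

    def __post_init__(self) -> None:
        if self.moltype not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for id {rid!r}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.records)

    def subset(self, ids) -> "SequenceSet":
        wanted = set(ids)
        return SequenceSet(
            [(r, s) for r, s in self.records if r in wanted], self.moltype
        )

    @staticmethod
    def merge(*sets: "SequenceSet") -> "SequenceSet":
        moltypes = {s.moltype for s in sets}
        if len(moltypes) != 1:
            raise ValueError("cannot merge sets of different moltypes")
        records = [rec for s in sets for rec in s.records]
        return SequenceSet(records, moltypes.pop())


@dataclass
class TabularMatrix:
    """A labelled numeric grid (genes x samples) with optional column groups."""

    row_ids: list[str]
    col_ids: list[str]
    values: pd.DataFrame
    col_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")
        if list(self.values.index) != self.row_ids or list(
            self.values.columns
        ) != self.col_ids:
            raise ValueError("value grid does not match id lists")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, col_groups: dict[str, str] | None = None
    ) -> "TabularMatrix":
        return cls(list(frame.index), list(frame.columns), frame, col_groups)


@dataclass(frozen=True)
class ExternalDomainHitRow:
    """One row of an externally produced (HMMER3 domtblout) domain search."""

    gene_id: str
    domain_name: str
    env_start: int  # 1-based inclusive
    env_end: int  # 1-based inclusive
    score: float  # bits
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"invalid envelope {self.env_start}..{self.env_end} "
                f"for {self.gene_id}"
            )


def read_fasta(path, moltype: str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased and line wrapping is normalized away. A
    duplicate id is a hard error; an empty file yields an empty set with a
    warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records")
    return SequenceSet(records, moltype)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    bio = [
        SeqRecord(Seq(s), id=r, description="") for r, s in seqs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_domtblout(path) -> list[ExternalDomainHitRow]:
    """Parse a whitespace-delimited HMMER3 per-domain table (domtblout).

    Comment lines start with ``#``. Envelope coordinates (columns 20-21,
    1-based inclusive) are retained. A malformed column count raises with
    the offending line number.
    """
    rows: list[ExternalDomainHitRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=23 whitespace-"
                    f"delimited columns, found {len(fields)}"
                )
            try:
                row = ExternalDomainHitRow(
                    gene_id=fields[0],
                    domain_name=fields[3],
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                    score=float(fields[13]),
                    evalue=float(fields[12]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            rows.append(row)
    return rows


def write_newick(tree, path=None) -> str:
    """Serialize a tree (anything exposing ``to_newick``) to Newick.

    Branch lengths are written for every edge and bootstrap supports as
    internal-node labels. If ``path`` is given the string is also written
    to disk.
    """
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_edgelist(edges, path) -> None:
    """Write co-expression edges as a Cytoscape-importable TSV edge list."""
    frame = pd.DataFrame(
        [
            {
                "source": e.gene_a,
                "target": e.gene_b,
                "r": f"{e.r:.6f}",
                "p": f"{e.p_value:.6g}",
                "sign": e.sign,
            }
            for e in edges
        ],
        columns=["source", "target", "r", "p", "sign"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: TabularMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def read_matrix_tsv(path, col_groups: dict[str, str] | None = None) -> TabularMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if col_groups is None:
        # columns named like "M1_1" carry their group before the last '_'
        col_groups = {
            c: c.rsplit("_", 1)[0] if "_" in c else c for c in frame.columns
        }
    return TabularMatrix.from_frame(frame, col_groups)


# --- configuration -----------------------------------------------------------

# Flat key-value schema: key -> (type, default). ``seed`` is required.
CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    "seed": (int, None),
    "outdir": (str, "familyscope_out"),
    # synthetic transcriptome counts
    "n_erf": (int, 20),
    "n_dreb": (int, 10),
    "n_ap2": (int, 6),
    "n_rav": (int, 4),
    "n_negative": (int, 10),
    "n_incomplete": (int, 5),
    "clan_mutation_rate": (float, 0.03),
    # divergent-pair simulation
    "n_pairs": (int, 5),
    "pair_omega": (float, 0.2),
    "pair_ds": (float, 0.3),
    "pair_codons": (int, 300),
    # expression block
    "expression": (bool, True),
    "expression_groups": (list, ["M1", "M2", "M3", "F1", "F2", "F3"]),
    "n_replicates": (int, 3),
    "n_expression_genes": (int, 40),
    "n_de_genes": (int, 8),
    "de_fold": (float, 4.0),
    "expr_sigma": (float, 0.1),
    "n_modules": (int, 2),
    "module_size": (int, 5),
    "module_loading": (float, 0.998),
    "n_pathway_genes": (int, 12),
    # DEG / network thresholds
    "min_fpkm": (float, 1.0),
    "fc_threshold": (float, 2.0),
    "p_threshold": (float, 0.05),
    "top_k": (int, 10),
    # phylogeny
    "bootstrap_replicates": (int, 100),
    "distance_model": (str, "poisson"),
    # qPCR block
    "qpcr": (bool, True),
    "qpcr_treatments": (list, ["ABA", "GA3"]),
    "qpcr_genes": (int, 6),
    "qpcr_fold": (float, 8.0),
}


@dataclass
class Config:
    """Validated flat pipeline configuration."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


def validate_config(raw: dict) -> Config:
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys: "
            f"{sorted(CONFIG_SCHEMA)}"
        )
    if "seed" not in raw or raw["seed"] is None:
        raise ValueError("config schema error: required key 'seed' is missing")
    merged = {k: default for k, (_, default) in CONFIG_SCHEMA.items()}
    merged.update(raw)
    for key, value in merged.items():
        expected, _ = CONFIG_SCHEMA[key]
        if value is None:
            continue
        if expected in (int, float) and isinstance(value, bool):
            raise ValueError(f"config key {key!r}: expected {expected.__name__}")
        if expected is float and isinstance(value, int):
            merged[key] = float(value)
        elif not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected.__name__}, "
                f"got {type(value).__name__}"
            )
    return Config(merged)


def read_config(path) -> Config:
    """Read and schema-check a flat YAML key-value configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a flat key-value document")
    return validate_config(raw)
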