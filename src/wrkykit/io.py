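"""Readers and writers for the external formats the pipeline touches.

All tabular inputs are plain TSV, sequences are FASTA, trees are newick.
Readers validate and reject malformed input instead of repairing it: a
duplicate FASTA id, a negative FPKM or an inverted gene interval is an
error naming the offending record, never a silent fix.

Coordinates are 1-based inclusive on input (GFF convention); the per
chromosome gene ``rank`` computed here is 0-based.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("wrkykit")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = frozenset("ACGTN")

#: closed vocabulary of family labels (three main groups, five II subgroups,
#: and UC for members the structural rules cannot place)
GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "UC")

VARIETIES = ("WF", "RF", "PF")
STAGES = ("bud", "full_bloom")


class WrkykitError(ValueError):
    """Base class for all input-validation failures."""


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SequenceRecord:
    """A named residue sequence, protein or DNA."""

    id: str
    seq: str
    moltype: str = "protein"  # {"protein", "dna"}

    def __post_init__(self) -> None:
        if not self.id:
            raise WrkykitError("sequence record with empty id")
        if not self.seq:
            raise WrkykitError(f"empty sequence for id {self.id!r}")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise WrkykitError(
                f"illegal {self.moltype} characters {sorted(bad)} in {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are upper-folded and whitespace-stripped.  Duplicate ids and
    empty sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise WrkykitError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA; round-trips ids and sequences byte-exactly."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene positions


@dataclass(frozen=True)
class GeneLocus:
    """Chromosomal position of a gene; ``rank`` is its 0-based ordinal along
    the chromosome (ascending start, ties broken by gene id)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise WrkykitError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise WrkykitError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV of gene positions (gene_id, chrom, start, end, strand) and
    assign per-chromosome ranks."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("gene table %s is empty", path)
        return []
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise WrkykitError(f"gene table {path} missing columns {missing}")
    if df.empty:
        log.warning("gene table %s has no rows", path)
        return []
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
        raise WrkykitError(f"duplicate gene ids in {path}: {dupes}")
    loci = [
        GeneLocus(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    return assign_ranks(loci)


def assign_ranks(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Return loci with 0-based per-chromosome ranks (ascending start,
    gene_id tie-break); output order follows input order."""
    ranked: dict[str, int] = {}
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom_loci in by_chrom.values():
        for i, locus in enumerate(sorted(chrom_loci, key=lambda l: (l.start, l.gene_id))):
            ranked[locus.gene_id] = i
    return [
        GeneLocus(l.gene_id, l.chrom, l.start, l.end, l.strand, ranked[l.gene_id])
        for l in loci
    ]


# ---------------------------------------------------------------------------
# homologous pairs


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair, canonicalized gene_a < gene_b."""

    gene_a: str
    gene_b: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise WrkykitError(f"self-pair {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def read_pairs(path: str | Path) -> list[HomologPair]:
    """Read a TSV of homologous pairs (gene_a, gene_b[, score])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("pair table %s is empty", path)
        return []
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise WrkykitError(f"pair table {path} missing column {col!r}")
    pairs = []
    for r in df.itertuples():
        score = float(r.score) if "score" in df.columns and pd.notna(r.score) else None
        pairs.append(HomologPair(r.gene_a, r.gene_b, score))
    return pairs


def write_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "score": p.score} for p in pairs
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionTable:
    """A dense FPKM matrix (genes x samples) with per-sample variety/stage
    metadata.

    ``values`` is a pandas DataFrame indexed by gene id; ``metadata`` is a
    DataFrame indexed by sample id with columns ``variety`` and ``stage``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            cell = self.values.stack(future_stack=True)
            bad = cell[cell.isna()].index[0]
            raise WrkykitError(f"missing FPKM value at {bad}")
        if (self.values < 0).any().any():
            cell = self.values.stack(future_stack=True)
            bad = cell[cell < 0].index[0]
            raise WrkykitError(f"negative FPKM at gene={bad[0]!r} sample={bad[1]!r}")
        absent = [s for s in self.values.columns if s not in self.metadata.index]
        if absent:
            raise WrkykitError(f"samples missing from metadata: {absent}")
        for col in ("variety", "stage"):
            if col not in self.metadata.columns:
                raise WrkykitError(f"sample metadata missing column {col!r}")
        bad_var = set(self.metadata["variety"]) - set(VARIETIES)
        if bad_var:
            raise WrkykitError(f"unknown varieties {sorted(bad_var)}")
        bad_stage = set(self.metadata["stage"]) - set(STAGES)
        if bad_stage:
            raise WrkykitError(f"unknown stages {sorted(bad_stage)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, variety: str, stage: str) -> list[str]:
        meta = self.metadata
        mask = (meta["variety"] == variety) & (meta["stage"] == stage)
        return [s for s in self.values.columns if s in meta.index[mask]]


def read_expression_table(path: str | Path, metadata_path: str | Path) -> ExpressionTable:
    """Read an FPKM matrix TSV (first column gene ids) plus a sample-metadata
    sidecar TSV (sample, variety, stage)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values = values.astype(float)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise WrkykitError(f"metadata {metadata_path} missing column 'sample'")
    meta = meta.set_index("sample")
    return ExpressionTable(values, meta)


def write_expression_table(
    table: ExpressionTable, path: str | Path, metadata_path: str | Path
) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# labeled trees


@dataclass
class LabeledTree:
    """A newick tree whose leaves carry (possibly partial) subgroup labels;
    unlabeled leaves are recorded as UC."""

    tree: dendropy.Tree
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        leaves = self.leaf_names()
        if len(set(leaves)) != len(leaves):
            raise WrkykitError("tree has duplicate leaf names")
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise WrkykitError("tree has an unnamed leaf")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise WrkykitError(f"negative branch length {edge.length}")
        leaf_set = set(leaves)
        for leaf, label in self.labels.items():
            if leaf not in leaf_set:
                raise WrkykitError(f"label for unknown leaf {leaf!r}")
            if label not in GROUP_LABELS:
                raise WrkykitError(f"unknown subgroup label {label!r} for {leaf!r}")

    def leaf_names(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter() if l.taxon]

    def label_of(self, leaf: str) -> str:
        return self.labels.get(leaf, "UC")

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf-to-leaf path-length distances."""
        pdm = self.tree.phylogenetic_distance_matrix()
        out: dict[tuple[str, str], float] = {}
        taxa = [l.taxon for l in self.tree.leaf_node_iter()]
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                d = pdm.patristic_distance(t1, t2)
                out[(t1.label, t2.label)] = d
                out[(t2.label, t1.label)] = d
        return out


def read_newick(path: str | Path, labels_path: str | Path | None = None) -> LabeledTree:
    """Read a single-tree newick file plus an optional leaf→subgroup TSV
    (columns leaf, label) covering any subset of leaves."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise WrkykitError(f"malformed newick in {path}: {exc}") from exc
    labels: dict[str, str] = {}
    if labels_path is not None:
        df = pd.read_csv(labels_path, sep="\t", dtype=str)
        for col in ("leaf", "label"):
            if col not in df.columns:
                raise WrkykitError(f"label table {labels_path} missing column {col!r}")
        labels = dict(zip(df["leaf"], df["label"]))
    return LabeledTree(tree, labels)


# ---------------------------------------------------------------------------
# run configuration / logging


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise WrkykitError(f"config {path} is not a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
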