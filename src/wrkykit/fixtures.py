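"""Packaged reference fixtures transcribed from the printed family tables:
the 57-gene azalea WRKY inventory (name, group, heptapeptides, zinc-finger
type, domain count, duplication type, Arabidopsis ortholog), the per-stage
candidate-gene lists from the flower-color screen, the curated
reassignment of the four zinc-finger-lost members, and the five-species
subgroup count reference.

Files are checksummed and invariant-checked at load time, so a silently
edited fixture fails loudly.

Note: the printed table lists the four zinc-finger-lost genes under a
main-group label; the curated reassignment map carries the labels those
four received from the phylogeny, and the classification summary applies
it to reach the published group totals.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import GROUP_LABELS, WrkykitError

_CHECKSUMS = {
    "table1.tsv": "2d7c246ef8739a56b4a5651cc429a84ed5f97dda12a059031c9156fc0cea1b0c",
    "candidate_lists.tsv": "b9683b2d62d896ec7a3b6b31f6ec65a2f69a7ee94357843b327a742fc31a1791",
    "reassignment.tsv": "12be6525f81c56eb563d5a223c6b8ed8e5a8b62698ad4bb8a806e36983367e9c",
    "table2_reference.tsv": "b1b9be1fd97214eda87a1dba66daae69ea080283db5ed1b0deab532d8153a65f",
}


@dataclass(frozen=True)
class Table1Record:
    name: str
    gene_id: str
    group: str
    orf_aa: int
    heptapeptides: tuple[str, ...]
    zf_type: str  # {"C2H2", "C2HC", "Lost"}
    domain_number: int
    gene_type: str  # duplication mode as printed
    at_ortholog: str


@dataclass
class Table1Fixture:
    records: list[Table1Record]

    def __post_init__(self) -> None:
        if len(self.records) != 57:
            raise WrkykitError(f"expected 57 family records, got {len(self.records)}")
        for r in self.records:
            if r.group not in GROUP_LABELS:
                raise WrkykitError(f"{r.name}: unknown group {r.group!r}")
            if r.domain_number not in (1, 2):
                raise WrkykitError(f"{r.name}: domain number {r.domain_number}")
            if r.zf_type not in ("C2H2", "C2HC", "Lost"):
                raise WrkykitError(f"{r.name}: zinc-finger type {r.zf_type!r}")

    def zf_lost(self) -> list[Table1Record]:
        return [r for r in self.records if r.zf_type == "Lost"]

    def groups(self, reassignment: dict[str, str] | None = None) -> dict[str, str]:
        """Per-gene group labels, optionally with the curated reassignment
        of the zinc-finger-lost members applied."""
        labels = {r.name: r.group for r in self.records}
        if reassignment:
            labels.update(reassignment)
        return labels

    def gene_type_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for r in self.records:
            tally[r.gene_type] = tally.get(r.gene_type, 0) + 1
        return tally


@dataclass
class CandidateListsFixture:
    bud_up: list[str]
    bud_down: list[str]
    bloom_up: list[str]
    bloom_down: list[str]

    def __post_init__(self) -> None:
        expected = {"bud_up": 4, "bud_down": 13, "bloom_up": 4, "bloom_down": 5}
        for attr, n in expected.items():
            genes = getattr(self, attr)
            if len(genes) != n:
                raise WrkykitError(f"{attr}: expected {n} genes, got {len(genes)}")
            if len(set(genes)) != len(genes):
                raise WrkykitError(f"{attr}: duplicate entries")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("wrkykit.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise WrkykitError(f"packaged fixture {name} checksum mismatch ({digest})")
    import io as _io

    return pd.read_csv(_io.BytesIO(raw), sep="\t", dtype=str)


def load_table1() -> Table1Fixture:
    df = _read("table1.tsv")
    records = [
        Table1Record(
            r.name,
            r.gene_id,
            r.group,
            int(r.orf_aa),
            tuple(r.heptapeptides.split(";")),
            r.zf_type,
            int(r.domain_number),
            r.gene_type,
            r.at_ortholog,
        )
        for r in df.itertuples()
    ]
    return Table1Fixture(records)


def load_candidate_lists() -> CandidateListsFixture:
    df = _read("candidate_lists.tsv")
    def sel(stage: str, direction: str) -> list[str]:
        m = (df["stage"] == stage) & (df["direction"] == direction)
        return list(df.loc[m, "gene"])
    return CandidateListsFixture(
        bud_up=sel("bud", "up"),
        bud_down=sel("bud", "down"),
        bloom_up=sel("full_bloom", "up"),
        bloom_down=sel("full_bloom", "down"),
    )


def load_reassignment_map() -> dict[str, str]:
    df = _read("reassignment.tsv")
    mapping = dict(zip(df["name"], df["label"]))
    expected = {"RsWRKY3", "RsWRKY32", "RsWRKY42", "RsWRKY55"}
    if set(mapping) != expected:
        raise WrkykitError("reassignment map keys must be the four zinc-finger-lost genes")
    return mapping


def load_table2_reference() -> pd.DataFrame:
    df = _read("table2_reference.tsv")
    cols = ["I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "total"]
    df[cols] = df[cols].astype(int)
    if not (df[cols[:-1]].sum(axis=1) == df["total"]).all():
        raise WrkykitError("species subgroup counts do not sum to totals")
    return df.set_index("species")


def load_fixtures():
    """All packaged fixtures: (table1, candidate lists, reassignment map,
    five-species reference counts)."""
    return (
        load_table1(),
        load_candidate_lists(),
        load_reassignment_map(),
        load_table2_reference(),
    )
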