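"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and seed and emits
the same FASTA/TSV dialects the readers consume, together with a truth
table sufficient to score the downstream stage without external data:

* ``gen_wrky_proteome`` — proteins with planted heptapeptide +
  zinc-finger cassettes per subgroup (two cassettes for Group I), random
  flanks rejection-sampled against accidental grammar matches, and an
  optional degraded fraction (variant heptapeptide or lost zinc finger);
* ``gen_codon_pairs`` — duplicate CDS pairs diverged from a common
  ancestor under an accept/reject scheme with nonsynonymous acceptance
  probability omega (stops rejected);
* ``gen_duplicated_genome`` — gene orders with planted WGD anchor
  chains, tandem/proximal neighbors, transposed and dispersed pairs;
* ``gen_fpkm_table`` — a three-variety x two-stage FPKM design with
  planted up/down candidates and lognormal replicate noise.

The proteome generator verifies its own truth with an independent
regular-expression check (not the scanner module): a draw whose flanks
complete a spurious zinc-finger or heptapeptide pattern is resampled.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable, GeneLocus, HomologPair, SequenceRecord, assign_ranks
from .kaks import CODON_AA, STOP_CODONS

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: filler alphabet inside cassettes: no C/H (zinc-finger letters) and no W
#: (heptapeptide start), so planted motif coordinates are unambiguous
FILLER = "ADEFGIKLMNPQRSTVY"
NUCS = "ACGT"

SUBGROUP_CLASSES = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "lost")

_SIGNATURE_EXEMPLARS = {
    "IIa": "PVKKKLQ",
    "IIb": "PVRKQVQ",
    "IId": "PARKHVE",
    "IIe": "PARKQVE",
}

_ZF_PATTERNS = (r"C.{4,5}C.{22,24}H.H", r"C.{7}C.{22,24}H.C")


def _fill(rng: np.random.Generator, n: int, alphabet: str = FILLER) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


def _cassette(rng: np.random.Generator, subgroup: str, with_zf: bool, hepta: str) -> tuple[str, dict]:
    """One heptapeptide(+zinc finger) unit; returns (sequence, local truth
    with 0-based offsets of the planted motifs)."""
    linker = _fill(rng, 5)
    parts = [hepta, linker]
    truth = {"hepta_offset": 0, "hepta": hepta, "zf_offset": None}
    if with_zf:
        truth["zf_offset"] = len(hepta) + len(linker)
        if subgroup == "III":
            # C-X7-C-X23-H-X-C
            zf = "C" + _fill(rng, 7) + "C" + _fill(rng, 23) + "H" + _fill(rng, 1) + "C"
        elif subgroup == "IIc":
            zf = "C" + _fill(rng, 4) + "C" + _fill(rng, 23) + "H" + _fill(rng, 1) + "H"
        elif subgroup in _SIGNATURE_EXEMPLARS:
            sig = _SIGNATURE_EXEMPLARS[subgroup]
            zf = (
                "C" + _fill(rng, 5) + "C" + sig + _fill(rng, 23 - len(sig))
                + "H" + _fill(rng, 1) + "H"
            )
        else:  # Group I units: plain C2H2, C-X5-C, neutral post-C2 window
            zf = "C" + _fill(rng, 5) + "C" + _fill(rng, 23) + "H" + _fill(rng, 1) + "H"
        parts.append(zf)
    return "".join(parts), truth


def _independent_motif_positions(seq: str) -> set[int]:
    """Zinc-finger grammar match starts found by plain regexes (a check
    independent of the scanner implementation)."""
    hits = set()
    for i in range(len(seq)):
        for pat in _ZF_PATTERNS:
            if re.match(pat, seq[i:]):
                hits.add(i)
    return hits


def _spurious(seq: str, zf_starts: set[int], hepta_starts: set[int]) -> bool:
    if _independent_motif_positions(seq) - zf_starts:
        return True
    exact = {m.start() for m in re.finditer("(?=WRKYGQK)", seq)}
    if exact - hepta_starts:
        return True
    # any near-canonical 7-mer (<=1 mismatch, WR prefix) outside planted sites
    # would survive assembly as a zinc-finger-lost domain
    for i in range(len(seq) - 6):
        if i in hepta_starts or not seq.startswith("WR", i):
            continue
        kmer = seq[i : i + 7]
        if sum(a != b for a, b in zip(kmer, "WRKYGQK")) <= 1:
            return True
    return False


@dataclass(frozen=True)
class ProteomeTruth:
    protein_id: str
    planted_class: str  # one of SUBGROUP_CLASSES
    degraded: str  # {"none", "variant_hepta", "zf_lost"}
    expected_label: str  # subgroup label or UC


def gen_wrky_proteome(
    n_per_subgroup: int,
    flank_len: int = 40,
    seed: int = 0,
    degraded_fraction: float = 0.0,
) -> tuple[list[SequenceRecord], list[ProteomeTruth]]:
    """Proteins with planted subgroup cassettes in random flanks.

    Classes are the seven subgroups plus a zinc-finger-``lost`` class; a
    ``degraded_fraction`` of the subgroup proteins additionally receives a
    variant heptapeptide (one substitution, expected label unchanged) or
    loses its zinc finger(s) (expected label UC).
    """
    if n_per_subgroup < 1:
        raise ValueError("n_per_subgroup must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truths: list[ProteomeTruth] = []
    for cls in SUBGROUP_CLASSES:
        for i in range(n_per_subgroup):
            pid = f"syn_{cls}_{i:03d}"
            degraded = "none"
            if cls != "lost" and degraded_fraction > 0 and rng.random() < degraded_fraction:
                degraded = "variant_hepta" if rng.random() < 0.5 else "zf_lost"
            hepta = "WRKYGQK"
            if degraded == "variant_hepta":
                # one substitution outside the WR prefix, e.g. WRKYGEK
                pos = int(rng.integers(2, 7))
                alt = rng.choice([a for a in "ADEFGIKLMNPQRSTVY" if a != hepta[pos]])
                hepta = hepta[:pos] + alt + hepta[pos + 1 :]
            with_zf = degraded != "zf_lost" and cls != "lost"

            for _attempt in range(60):
                parts: list[str] = []
                zf_starts: set[int] = set()
                hepta_starts: set[int] = set()
                pos0 = 0

                def add(s: str) -> None:
                    nonlocal pos0
                    parts.append(s)
                    pos0 += len(s)

                add(_fill(rng, flank_len, AA20))
                n_units = 2 if cls == "I" else 1
                for u in range(n_units):
                    unit, local = _cassette(rng, cls, with_zf, hepta)
                    hepta_starts.add(pos0 + local["hepta_offset"])
                    if local["zf_offset"] is not None:
                        zf_starts.add(pos0 + local["zf_offset"])
                    add(unit)
                    if u + 1 < n_units:
                        add(_fill(rng, 25, AA20))
                add(_fill(rng, flank_len, AA20))
                seq = "".join(parts)
                planted_hepta = hepta_starts if hepta == "WRKYGQK" else set(hepta_starts)
                if not _spurious(seq, zf_starts, planted_hepta):
                    break
            else:  # pragma: no cover - rejection nearly always succeeds
                raise RuntimeError(f"could not sample clean flanks for {pid}")

            expected = "UC" if (cls == "lost" or degraded == "zf_lost") else cls
            records.append(SequenceRecord(pid, seq, "protein"))
            truths.append(ProteomeTruth(pid, cls, degraded, expected))
    return records, truths


# ---------------------------------------------------------------------------
# codon pairs


@dataclass(frozen=True)
class CodonPairTruth:
    pair_id: str
    syn_events: int
    nonsyn_events: int


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    codons = []
    while len(codons) < n:
        c = "".join(rng.choice(list(NUCS), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return codons


def _evolve(rng: np.random.Generator, codons: list[str], omega: float, branch_length: float) -> tuple[list[str], int, int]:
    """Accept/reject evolution along one branch; returns (sequence,
    realized synonymous events, realized nonsynonymous events)."""
    seq = list(codons)
    n_sites = 3 * len(seq)
    n_events = rng.poisson(branch_length * n_sites)
    syn = nonsyn = 0
    for _ in range(n_events):
        ci = int(rng.integers(len(seq)))
        pos = int(rng.integers(3))
        old = seq[ci]
        alt = rng.choice([n for n in NUCS if n != old[pos]])
        new = old[:pos] + alt + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if CODON_AA[new] == CODON_AA[old]:
            seq[ci] = new
            syn += 1
        elif rng.random() < omega:
            seq[ci] = new
            nonsyn += 1
    return seq, syn, nonsyn


def gen_codon_pairs(
    n_pairs: int,
    n_codons: int,
    omega: float,
    branch_length: float,
    seed: int = 0,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], list[CodonPairTruth]]:
    """Duplicate CDS pairs diverged from a shared ancestor.

    ``branch_length`` is the expected number of attempted single-nucleotide
    changes per site per branch; synonymous proposals are always accepted,
    nonsynonymous ones with probability ``omega``, stops never.
    """
    if omega <= 0 or branch_length < 0:
        raise ValueError("omega must be > 0 and branch_length >= 0")
    rng = np.random.default_rng(seed)
    pairs = []
    truths = []
    for i in range(n_pairs):
        ancestor = _random_codons(rng, n_codons)
        a, sa, na = _evolve(rng, ancestor, omega, branch_length)
        b, sb, nb = _evolve(rng, ancestor, omega, branch_length)
        pid = f"pair{i:03d}"
        pairs.append(
            (
                SequenceRecord(f"{pid}_a", "".join(a), "dna"),
                SequenceRecord(f"{pid}_b", "".join(b), "dna"),
            )
        )
        truths.append(CodonPairTruth(pid, sa + sb, na + nb))
    return pairs, truths


# ---------------------------------------------------------------------------
# duplicated genomes


@dataclass(frozen=True)
class PlantedPair:
    pair: HomologPair
    mode: str


class _Chrom:
    """Accumulates an ordered gene list for one chromosome."""

    def __init__(self, name: str) -> None:
        self.name = name
        self.genes: list[str] = []

    def pad(self, n: int, counter: list[int]) -> None:
        for _ in range(n):
            counter[0] += 1
            self.genes.append(f"bg{counter[0]:05d}")

    def add(self, gene: str) -> int:
        self.genes.append(gene)
        return len(self.genes) - 1


def gen_duplicated_genome(
    n_per_mode: int | dict[str, int],
    n_background: int = 50,
    seed: int = 0,
    chain_len: int = 6,
) -> tuple[list[GeneLocus], list[HomologPair], list[PlantedPair]]:
    """A gene order with planted duplication modes.

    WGD pairs are embedded as anchor chains of ``chain_len`` (>= the block
    detector's default minimum of 5) between two chromosomes; tandem pairs
    are rank-adjacent; proximal pairs sit at rank gaps 2-10; transposed
    pairs join a WGD-chain gene to a distant solo locus; dispersed pairs
    join two distant non-collinear loci.  Planted same- and cross-
    chromosome structures are spaced >25 ranks apart so they cannot chain
    into spurious blocks.
    """
    if isinstance(n_per_mode, int):
        want = {m: n_per_mode for m in ("WGD", "TANDEM", "PROXIMAL", "TRANSPOSED", "DISPERSED")}
    else:
        want = {m: n_per_mode.get(m, 0) for m in ("WGD", "TANDEM", "PROXIMAL", "TRANSPOSED", "DISPERSED")}
    rng = np.random.default_rng(seed)
    counter = [0]
    chr1, chr2, chr3, chr4 = (_Chrom(f"chr{i}") for i in range(1, 5))
    planted: list[PlantedPair] = []
    gid = [0]

    def fresh(tag: str) -> str:
        gid[0] += 1
        return f"{tag}{gid[0]:04d}"

    # WGD anchor chains; a short final quota is padded up to chain_len so
    # every chain clears the block detector's minimum, and the padding
    # pairs are recorded as planted WGD too
    n_wgd = want["WGD"]
    wgd_chain_genes_a: list[str] = []
    made = 0
    while made < n_wgd:
        chr1.pad(3, counter)
        chr2.pad(3, counter)
        for _ in range(chain_len):
            ga, gb = fresh("wgdA"), fresh("wgdB")
            chr1.add(ga)
            chr2.add(gb)
            planted.append(PlantedPair(HomologPair(ga, gb), "WGD"))
            wgd_chain_genes_a.append(ga)
        made += chain_len

    # tandem and proximal on chr3, spaced >25 apart
    for _ in range(want["TANDEM"]):
        chr3.pad(30, counter)
        ga, gb = fresh("tanA"), fresh("tanB")
        chr3.add(ga)
        chr3.add(gb)
        planted.append(PlantedPair(HomologPair(ga, gb), "TANDEM"))
    for _ in range(want["PROXIMAL"]):
        chr3.pad(30, counter)
        ga = fresh("prxA")
        chr3.add(ga)
        gap = int(rng.integers(2, 11))
        chr3.pad(gap - 1, counter)
        gb = fresh("prxB")
        chr3.add(gb)
        planted.append(PlantedPair(HomologPair(ga, gb), "PROXIMAL"))

    # transposed: one side inside a WGD chain, the other a distant solo gene
    donors = list(wgd_chain_genes_a)
    if want["TRANSPOSED"] > len(donors):
        raise ValueError("not enough WGD-chain genes to seed transposed pairs")
    for i in range(want["TRANSPOSED"]):
        chr4.pad(30, counter)
        gb = fresh("trsB")
        chr4.add(gb)
        planted.append(PlantedPair(HomologPair(donors[i], gb), "TRANSPOSED"))

    # dispersed: distant loci on chr3/chr4, no collinear evidence either side
    for _ in range(want["DISPERSED"]):
        chr3.pad(30, counter)
        ga = fresh("dspA")
        chr3.add(ga)
        chr4.pad(30, counter)
        gb = fresh("dspB")
        chr4.add(gb)
        planted.append(PlantedPair(HomologPair(ga, gb), "DISPERSED"))

    # leftover background
    per = max(0, n_background) // 4
    for c in (chr1, chr2, chr3, chr4):
        c.pad(per, counter)

    loci: list[GeneLocus] = []
    for c in (chr1, chr2, chr3, chr4):
        for i, g in enumerate(c.genes):
            start = (i + 1) * 1000
            loci.append(GeneLocus(g, c.name, start, start + 500, "+"))
    loci = assign_ranks(loci)
    pairs = [p.pair for p in planted]
    return loci, pairs, planted


# ---------------------------------------------------------------------------
# FPKM tables


@dataclass(frozen=True)
class FpkmTruth:
    positive: tuple[str, ...]
    negative: tuple[str, ...]


def gen_fpkm_table(
    n_genes: int = 100,
    n_planted_pos: int = 10,
    n_planted_neg: int = 10,
    fold: float = 8.0,
    noise_sigma: float = 0.25,
    replicates: int = 3,
    seed: int = 0,
    stages: Sequence[str] = ("bud", "full_bloom"),
) -> tuple[ExpressionTable, FpkmTruth]:
    """FPKM design: three varieties (WF white baseline, RF red, PF pink) x
    two stages x ``replicates``.  Planted positives are multiplied by
    ``fold`` in both colored varieties (negatives divided), on the listed
    stages; replicate noise is lognormal(sigma)."""
    if fold < 2:
        raise ValueError("fold must be >= 2 to clear the DEG threshold")
    if n_planted_pos + n_planted_neg > n_genes:
        raise ValueError("more planted genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    pos = tuple(genes[:n_planted_pos])
    neg = tuple(genes[n_planted_pos : n_planted_pos + n_planted_neg])
    base = np.exp(rng.normal(3.0, 1.0, size=n_genes))  # median ~20 FPKM

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for variety in ("WF", "RF", "PF"):
        for stage in ("bud", "full_bloom"):
            effect = np.ones(n_genes)
            if variety in ("RF", "PF") and stage in stages:
                effect[:n_planted_pos] = fold
                effect[n_planted_pos : n_planted_pos + n_planted_neg] = 1.0 / fold
            for rep in range(1, replicates + 1):
                name = f"{variety}_{stage}_r{rep}"
                noise = (
                    np.exp(rng.normal(0.0, noise_sigma, size=n_genes))
                    if noise_sigma > 0
                    else np.ones(n_genes)
                )
                columns[name] = base * effect * noise
                meta_rows.append({"sample": name, "variety": variety, "stage": stage})
    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionTable(values, meta), FpkmTruth(pos, neg)


# ---------------------------------------------------------------------------
# labeled trees (small random fixtures for label transfer)


def gen_labeled_tree(n_leaves: int, seed: int = 0) -> str:
    """A random binary newick string with positive branch lengths."""
    rng = np.random.default_rng(seed)
    nodes = [f"t{i}" for i in range(n_leaves)]
    subtrees = [f"{n}:{rng.uniform(0.1, 2.0):.3f}" for n in nodes]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a = subtrees.pop(j)
        b = subtrees.pop(i)
        subtrees.append(f"({b},{a}):{rng.uniform(0.1, 2.0):.3f}")
    return subtrees[0].rsplit(":", 1)[0] + ";"


from .fixtures import load_fixtures  # noqa: E402  (re-exported here: the
# packaged printed-table fixtures are part of the synthetic/test data surface)
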