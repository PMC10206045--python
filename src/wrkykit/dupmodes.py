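"""Duplication-mode typing: WGD / tandem / proximal / transposed / dispersed.

Collinear (syntenic) blocks are found by greedy anchor chaining over gene
ranks: homologous pairs are grouped by chromosome pair, sorted by rank on
side A, and chained while both rank gaps stay within ``max_rank_gap`` and
the side-B direction is consistent; chains shorter than ``min_anchors``
are discarded.  This is a deliberately simplified stand-in for a full
dynamic-programming synteny tool, adequate for planted-block genomes.

Pair classification, first rule that fires:

1. the pair is an anchor of a collinear block          -> WGD
2. same chromosome, adjacent ranks (gap 1)             -> TANDEM
3. same chromosome, rank gap <= proximal_max           -> PROXIMAL
4. exactly one gene of the pair is in any block anchor -> TRANSPOSED
5. otherwise                                           -> DISPERSED

The transposed rule approximates an ancestral-locus test: the side that
sits inside a collinear block is taken as the parental copy.  Per-gene
modes collapse a gene's pair calls under the fixed priority
WGD > TANDEM > PROXIMAL > TRANSPOSED > DISPERSED.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneLocus, HomologPair, WrkykitError

MODES = ("WGD", "TANDEM", "PROXIMAL", "TRANSPOSED", "DISPERSED")
MODE_PRIORITY = {m: i for i, m in enumerate(MODES)}

DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_RANK_GAP = 25
DEFAULT_PROXIMAL_MAX = 10


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[HomologPair] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class DuplicationCall:
    pair: HomologPair
    mode: str


@dataclass(frozen=True)
class GeneModeCall:
    gene_id: str
    mode: str
    supporting: tuple[str, ...] = ()


def _rank_map(loci: Sequence[GeneLocus]) -> dict[str, tuple[str, int]]:
    return {l.gene_id: (l.chrom, l.rank) for l in loci}


def _oriented(pair: HomologPair, ranks: dict[str, tuple[str, int]]):
    """Orient a pair so (chrom, rank) of side A sorts before side B."""
    for g in (pair.gene_a, pair.gene_b):
        if g not in ranks:
            raise WrkykitError(f"pair gene {g!r} absent from gene table")
    a, b = pair.gene_a, pair.gene_b
    if ranks[a] > ranks[b]:
        a, b = b, a
    (ca, ra), (cb, rb) = ranks[a], ranks[b]
    return ca, ra, cb, rb, pair


def detect_collinear_blocks(
    pairs: Iterable[HomologPair],
    loci: Sequence[GeneLocus],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
) -> list[CollinearBlock]:
    """Greedy rank chaining of homologous pairs into collinear blocks."""
    ranks = _rank_map(loci)
    groups: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        ca, ra, cb, rb, pair = _oriented(p, ranks)
        groups.setdefault((ca, cb), []).append((ra, rb, pair))

    blocks: list[CollinearBlock] = []
    for (ca, cb), items in sorted(groups.items()):
        items.sort(key=lambda t: (t[0], t[1]))
        chain: list[tuple[int, int, HomologPair]] = []
        direction = 0  # 0 undetermined, +1 increasing, -1 decreasing on side B

        def close() -> None:
            nonlocal chain, direction
            if len(chain) >= min_anchors:
                blocks.append(CollinearBlock(ca, cb, [t[2] for t in chain]))
            chain = []
            direction = 0

        for ra, rb, pair in items:
            if not chain:
                chain.append((ra, rb, pair))
                continue
            la, lb, _ = chain[-1]
            gap_a = ra - la
            gap_b = rb - lb
            step = (gap_b > 0) - (gap_b < 0)
            ok = (
                0 < gap_a <= max_rank_gap
                and 1 <= abs(gap_b) <= max_rank_gap
                and (direction == 0 or step == direction)
            )
            if ok:
                chain.append((ra, rb, pair))
                if direction == 0:
                    direction = step
            else:
                close()
                chain.append((ra, rb, pair))
        close()
    return blocks


def classify_pair(
    pair: HomologPair,
    blocks: Sequence[CollinearBlock],
    loci: Sequence[GeneLocus],
    proximal_max: int = DEFAULT_PROXIMAL_MAX,
) -> DuplicationCall:
    """Assign one duplication mode to a homologous pair."""
    ranks = _rank_map(loci)
    for g in (pair.gene_a, pair.gene_b):
        if g not in ranks:
            raise WrkykitError(f"pair gene {g!r} absent from gene table")
    anchor_keys = {a.key for b in blocks for a in b.anchors}
    anchor_genes = {g for b in blocks for a in b.anchors for g in (a.gene_a, a.gene_b)}

    if pair.key in anchor_keys:
        return DuplicationCall(pair, "WGD")
    (ca, ra), (cb, rb) = ranks[pair.gene_a], ranks[pair.gene_b]
    if ca == cb:
        gap = abs(ra - rb)
        if gap == 1:
            return DuplicationCall(pair, "TANDEM")
        if gap <= proximal_max:
            return DuplicationCall(pair, "PROXIMAL")
    in_block = (pair.gene_a in anchor_genes) + (pair.gene_b in anchor_genes)
    if in_block == 1:
        return DuplicationCall(pair, "TRANSPOSED")
    return DuplicationCall(pair, "DISPERSED")


def classify_pairs(
    pairs: Sequence[HomologPair],
    loci: Sequence[GeneLocus],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_rank_gap: int = DEFAULT_MAX_RANK_GAP,
    proximal_max: int = DEFAULT_PROXIMAL_MAX,
) -> tuple[list[CollinearBlock], list[DuplicationCall]]:
    """Detect blocks over the pair universe, then classify every pair."""
    blocks = detect_collinear_blocks(pairs, loci, min_anchors, max_rank_gap)
    calls = [classify_pair(p, blocks, loci, proximal_max) for p in pairs]
    return blocks, calls


def assign_gene_modes(calls: Sequence[DuplicationCall]) -> list[GeneModeCall]:
    """Collapse pair calls to one mode per gene by fixed priority; genes in
    no pair are simply absent."""
    per_gene: dict[str, list[DuplicationCall]] = {}
    for call in calls:
        for g in (call.pair.gene_a, call.pair.gene_b):
            per_gene.setdefault(g, []).append(call)
    out = []
    for gene in sorted(per_gene):
        gene_calls = per_gene[gene]
        best = min(gene_calls, key=lambda c: MODE_PRIORITY[c.mode]).mode
        supporting = tuple(
            f"{c.pair.gene_a}|{c.pair.gene_b}" for c in gene_calls if c.mode == best
        )
        out.append(GeneModeCall(gene, best, supporting))
    return out


def mode_tally(calls: Sequence[DuplicationCall] | Sequence[GeneModeCall]) -> dict[str, int]:
    tally = {m: 0 for m in MODES}
    for c in calls:
        tally[c.mode] += 1
    return tally
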