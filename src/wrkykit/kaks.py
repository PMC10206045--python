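"""Codon-level Ka/Ks estimation for duplicate gene pairs (NG86 counting
with Jukes-Cantor correction) and selection-category calls.

The estimator follows the classical Nei-Gojobori (1986) scheme:

* synonymous site fraction of a codon = over its three positions, the
  fraction of the three single-nucleotide neighbors that preserve the
  amino acid (changes to stop codons count as nonsynonymous); site totals
  are averaged between the two sequences, so S + N = 3 x compared codons;
* observed synonymous/nonsynonymous differences: codons differing at 2-3
  positions average their step counts over all orderings of single
  nucleotide steps, excluding pathways that pass through a stop codon;
  a codon pair whose every pathway hits a stop is skipped (and excluded
  from the site totals) with a log line;
* proportions p = d/sites are Jukes-Cantor corrected,
  d = -(3/4) ln(1 - (4/3) p), undefined when p >= 3/4.

Ks = 0 yields an undefined ratio (never infinity); undefined ratios pass
through the selection trichotomy untouched.  The neutrality band has a
configurable half-width eps because exact Ka/Ks = 1 is measure-zero.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .io import WrkykitError

log = logging.getLogger("wrkykit")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stops mapped to '*'
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_AA.update({c: "*" for c in _TABLE.stop_codons})
STOP_CODONS = frozenset(_TABLE.stop_codons)
_NUCS = "ACGT"

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """A pair of aligned codon sequences (gaps in whole-codon units)."""

    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise WrkykitError("codon alignment rows differ in length")
        for row in (self.codons_a, self.codons_b):
            for i, codon in enumerate(row):
                if codon == GAP_CODON:
                    continue
                if len(codon) != 3 or any(n not in _NUCS for n in codon):
                    raise WrkykitError(f"bad codon {codon!r} at column {i}")
                if codon in STOP_CODONS:
                    raise WrkykitError(f"internal stop codon at column {i}")

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in zip(self.codons_a, self.codons_b)
            if a != GAP_CODON and b != GAP_CODON
        ]


@dataclass(frozen=True)
class KaKsResult:
    id_a: str
    id_b: str
    S: float  # average synonymous sites
    N: float  # average nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    Ka: float | None
    Ks: float | None
    ratio: float | None
    category: str  # {"purifying", "neutral", "positive", "undefined"}
    n_codons: int  # compared (ungapped, unskipped) codon columns


def backtranslate(
    protein_aln: tuple[tuple[str, str], tuple[str, str]],
    cds: Mapping[str, str],
) -> CodonAlignment:
    """Thread CDS codons onto a gapped protein alignment.

    ``protein_aln`` is ((id_a, gapped_protein_a), (id_b, gapped_protein_b)).
    Each CDS must translate exactly to its ungapped protein under the
    standard code (a terminal stop codon is stripped with a log line).
    """
    rows = []
    for pid, gapped in protein_aln:
        if pid not in cds:
            raise WrkykitError(f"no CDS for {pid!r}")
        dna = cds[pid].upper()
        if len(dna) % 3:
            raise WrkykitError(f"CDS length of {pid!r} not a multiple of 3")
        codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
        if codons and codons[-1] in STOP_CODONS:
            log.info("stripping terminal stop codon from %s", pid)
            codons = codons[:-1]
        protein = gapped.replace("-", "")
        if len(codons) != len(protein):
            raise WrkykitError(
                f"{pid!r}: CDS codes {len(codons)} residues, protein has {len(protein)}"
            )
        for i, (codon, aa) in enumerate(zip(codons, protein)):
            if codon in STOP_CODONS:
                raise WrkykitError(f"{pid!r}: internal stop at codon {i}")
            if CODON_AA[codon] != aa:
                raise WrkykitError(
                    f"{pid!r}: codon {codon} at position {i} codes "
                    f"{CODON_AA[codon]}, protein has {aa}"
                )
        it = iter(codons)
        rows.append([GAP_CODON if c == "-" else next(it) for c in gapped])
    (id_a, _), (id_b, _) = protein_aln
    return CodonAlignment(id_a, id_b, rows[0], rows[1])


def synonymous_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3): per position, the
    fraction of the 3 single-nucleotide neighbors coding the same residue.
    Neighbors that are stop codons count as nonsynonymous."""
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            neighbor = codon[:pos] + nuc + codon[pos + 1 :]
            if neighbor not in STOP_CODONS and CODON_AA[neighbor] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over all stop-free orderings of
    single-nucleotide steps from codon_a to codon_b; None if all pathways
    pass through a stop."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    sd_total = nd_total = 0.0
    n_valid = 0
    for order in permutations(diff):
        current = codon_a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_AA[nxt] == CODON_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            sd_total += sd
            nd_total += nd
            n_valid += 1
    if n_valid == 0:
        return None
    return sd_total / n_valid, nd_total / n_valid


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined (None) when p >= 3/4."""
    if p < 0:
        raise WrkykitError(f"negative proportion {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(aln: CodonAlignment, eps: float = 0.05) -> KaKsResult:
    """NG86 Ka/Ks for one codon-aligned pair."""
    columns = aln.ungapped_columns()
    if not columns:
        raise WrkykitError("codon alignment has no shared ungapped columns")
    S = N = Sd = Nd = 0.0
    n_used = 0
    for i, (ca, cb) in enumerate(columns):
        counts = _pathway_counts(ca, cb)
        if counts is None:
            log.info(
                "codon column %d (%s/%s): all pathways hit stops; skipped", i, ca, cb
            )
            continue
        sd, nd = counts
        s = (synonymous_fraction(ca) + synonymous_fraction(cb)) / 2.0
        S += s
        N += 3.0 - s
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise WrkykitError("no comparable codon columns after stop-pathway skips")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    ratio = Ka / Ks if (Ka is not None and Ks is not None and Ks > 0) else None
    return KaKsResult(
        aln.id_a, aln.id_b, S, N, Sd, Nd, Ka, Ks, ratio,
        selection_category(ratio, eps), n_used,
    )


def selection_category(ratio: float | None, eps: float = 0.05) -> str:
    """Trichotomy: purifying (<1), neutral (~1 within eps), positive (>1);
    an undefined ratio passes through as 'undefined'."""
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise WrkykitError(f"negative Ka/Ks ratio {ratio}")
    if abs(ratio - 1.0) <= eps:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def align_protein_pair(id_a: str, prot_a: str, id_b: str, prot_b: str):
    """Global protein alignment (BLOSUM62, affine gaps) as backtranslate
    input; convenience for pipelines whose input is unaligned pairs."""
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a, prot_b)[0]
    return ((id_a, str(aln[0])), (id_b, str(aln[1])))


def kaks_for_pairs(
    pairs, proteins: Mapping[str, str], cds: Mapping[str, str], eps: float = 0.05
) -> list[KaKsResult]:
    """Align, backtranslate and estimate Ka/Ks for a list of HomologPairs."""
    results = []
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in proteins:
                raise WrkykitError(f"no protein sequence for {g!r}")
        aln = align_protein_pair(
            p.gene_a, proteins[p.gene_a], p.gene_b, proteins[p.gene_b]
        )
        results.append(ng86_pair(backtranslate(aln, cds), eps))
    return results
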