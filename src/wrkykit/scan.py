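"""WRKY domain detection.

A WRKY domain is ~60 residues: a conserved heptapeptide (canonically
WRKYGQK) followed by a zinc finger, either C2H2 (C-X4-5-C-X22-24-H-X-H)
or C2HC (C-X7-C-X22-24-H-X-C).  The scanner works in three passes:

1. zinc fingers — every non-overlapping grammar match, scanning left to
   right, preferring the shortest spacers at equal start;
2. heptapeptides — all exact WRKYGQK occurrences, plus anchor-conditioned
   fuzzy hits (a 7-mer starting "WR" with at most 4 mismatches within the
   60 residues upstream of a zinc finger), plus truncated terminal "WR"/
   "WRK" prefixes flagged partial;
3. assembly — each zinc finger pairs with the nearest upstream
   heptapeptide within the 60-aa window; an unpaired near-canonical
   heptapeptide (≤1 mismatch) still counts as a domain that has lost its
   zinc finger.

All positions are 1-based.  The fuzzy search is anchor-conditioned on
purpose: an unanchored 4-mismatch search over a proteome floods false
positives, while real heptapeptide variants sit directly upstream of an
intact zinc finger.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .io import PROTEIN_ALPHABET, WrkykitError

CANONICAL_HEPTA = "WRKYGQK"

#: zinc-finger grammar: type -> (C-to-C spacer range, final residue)
ZF_GRAMMAR = {
    "C2H2": ((4, 5), "H"),
    "C2HC": ((7, 7), "C"),
}
#: residues between the second cysteine and the first histidine
CH_SPACER = (22, 24)
#: residues following the second cysteine kept for subgroup signatures
POST_C2_WINDOW = 12
#: maximal heptapeptide-to-zinc-finger separation (domain span)
PAIRING_WINDOW = 60
#: mismatch cap for anchor-conditioned heptapeptide variants
MAX_HEPTA_MISMATCH = 4


@dataclass(frozen=True)
class HeptapeptideHit:
    """A (possibly variant or truncated) conserved-heptapeptide occurrence."""

    start: int  # 1-based
    motif7: str
    mismatches: int
    partial: bool = False


@dataclass(frozen=True)
class ZincFingerHit:
    """A zinc-finger grammar match; c1/c2/h1/last are the 1-based positions
    of the four metal-coordinating residues."""

    zf_type: str  # {"C2H2", "C2HC"}
    c1: int
    c2: int
    h1: int
    last: int
    cc_spacer: int
    post_c2_window: str  # 12 residues after c2, '-'-padded near the end

    @property
    def end(self) -> int:
        return self.last


@dataclass(frozen=True)
class WrkyDomain:
    """A heptapeptide paired (or not) with its downstream zinc finger."""

    hepta: HeptapeptideHit
    zf: ZincFingerHit | None = None

    @property
    def complete(self) -> bool:
        return self.zf is not None and not self.hepta.partial


@dataclass
class WrkyAnnotation:
    """All WRKY domains detected in one protein."""

    protein_id: str
    domains: list[WrkyDomain] = field(default_factory=list)

    @property
    def n_complete(self) -> int:
        return sum(1 for d in self.domains if d.complete)

    @property
    def zf_lost(self) -> bool:
        return any(d.zf is None for d in self.domains)

    @property
    def is_wrky(self) -> bool:
        return bool(self.domains)


def _check_protein(seq: str) -> None:
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise WrkykitError(f"non-protein characters {sorted(bad)}")


def _zf_candidates_at(seq: str, i: int) -> list[ZincFingerHit]:
    """All grammar matches whose first cysteine is at 0-based index i."""
    if seq[i] != "C":
        return []
    out: list[ZincFingerHit] = []
    n = len(seq)
    for zf_type, ((cc_lo, cc_hi), last_res) in ZF_GRAMMAR.items():
        for cc in range(cc_lo, cc_hi + 1):
            j = i + 1 + cc  # second cysteine
            if j >= n or seq[j] != "C":
                continue
            for ch in range(CH_SPACER[0], CH_SPACER[1] + 1):
                h = j + 1 + ch
                if h + 2 >= n:
                    continue
                if seq[h] == "H" and seq[h + 2] == last_res:
                    window = seq[j + 1 : j + 1 + POST_C2_WINDOW]
                    window = window.ljust(POST_C2_WINDOW, "-")
                    out.append(
                        ZincFingerHit(
                            zf_type=zf_type,
                            c1=i + 1,
                            c2=j + 1,
                            h1=h + 1,
                            last=h + 3,
                            cc_spacer=cc,
                            post_c2_window=window,
                        )
                    )
    return out


def scan_zinc_fingers(seq: str) -> list[ZincFingerHit]:
    """Non-overlapping zinc-finger matches, leftmost first; at equal start
    the shortest C-to-C spacer wins, then the shortest overall span."""
    _check_protein(seq)
    hits: list[ZincFingerHit] = []
    i = 0
    n = len(seq)
    while i < n:
        cands = _zf_candidates_at(seq, i)
        if cands:
            best = min(cands, key=lambda z: (z.cc_spacer, z.last))
            hits.append(best)
            i = best.last  # 1-based last == 0-based index after the motif
        else:
            i += 1
    return hits


def _mismatches(kmer: str) -> int:
    return sum(1 for a, b in zip(kmer, CANONICAL_HEPTA) if a != b)


def scan_heptapeptides(seq: str, anchors: list[ZincFingerHit] | None = None) -> list[HeptapeptideHit]:
    """Heptapeptide hits: exact canonical matches everywhere, the best
    anchored variant upstream of each zinc finger, and truncated terminal
    prefixes."""
    _check_protein(seq)
    anchors = anchors or []
    by_start: dict[int, HeptapeptideHit] = {}

    pos = seq.find(CANONICAL_HEPTA)
    while pos != -1:
        by_start[pos + 1] = HeptapeptideHit(pos + 1, CANONICAL_HEPTA, 0)
        pos = seq.find(CANONICAL_HEPTA, pos + 1)

    for anchor in anchors:
        c1_idx = anchor.c1 - 1  # 0-based
        lo = max(0, c1_idx - PAIRING_WINDOW)
        best: HeptapeptideHit | None = None
        for s in range(lo, c1_idx - 6):
            kmer = seq[s : s + 7]
            if not kmer.startswith("WR"):
                continue
            mm = _mismatches(kmer)
            if mm > MAX_HEPTA_MISMATCH:
                continue
            cand = HeptapeptideHit(s + 1, kmer, mm)
            # ties on mismatch count resolve to the hit closest to the anchor
            if best is None or mm < best.mismatches or (
                mm == best.mismatches and cand.start > best.start
            ):
                best = cand
        if best is not None and best.start not in by_start:
            by_start[best.start] = best

    # truncated terminal prefix: "WR" or "WRK" with no room for a 7-mer
    for prefix in ("WRK", "WR"):
        s = len(seq) - len(prefix)
        if s >= 0 and seq[s:] == prefix and s + 1 not in by_start:
            by_start[s + 1] = HeptapeptideHit(s + 1, prefix, 0, partial=True)
            break

    return [by_start[k] for k in sorted(by_start)]


def assemble_domains(seq: str, protein_id: str = "") -> WrkyAnnotation:
    """Pair zinc fingers with upstream heptapeptides into WRKY domains.

    Each zinc finger takes the nearest unconsumed heptapeptide that starts
    before its first cysteine and within the 60-aa pairing window.  An
    unpaired non-partial heptapeptide with ≤1 mismatch is kept as a
    zinc-finger-lost domain.  An empty annotation means the protein is not
    a WRKY at all.
    """
    zfs = scan_zinc_fingers(seq)
    heptas = scan_heptapeptides(seq, zfs)
    taken: set[int] = set()
    domains: list[WrkyDomain] = []
    for zf in zfs:
        upstream = [
            h
            for h in heptas
            if h.start not in taken
            and h.start < zf.c1
            and zf.c1 - h.start <= PAIRING_WINDOW
        ]
        if upstream:
            hepta = max(upstream, key=lambda h: h.start)
            taken.add(hepta.start)
            domains.append(WrkyDomain(hepta, zf))
    for h in heptas:
        if h.start not in taken and not h.partial and h.mismatches <= 1:
            domains.append(WrkyDomain(h, None))
    domains.sort(key=lambda d: d.hepta.start)
    return WrkyAnnotation(protein_id=protein_id, domains=domains)


def annotate_proteome(records) -> list[WrkyAnnotation]:
    """Scan a list of SequenceRecords; proteins with no domain are dropped
    (the family-retention rule: at least one WRKY signature required)."""
    out = []
    for rec in records:
        ann = assemble_domains(rec.seq, rec.id)
        if ann.is_wrky:
            out.append(ann)
    return out


def annotation_rows(annotations: list[WrkyAnnotation]) -> list[dict]:
    """Flatten annotations into TSV-ready rows."""
    rows = []
    for ann in annotations:
        for i, d in enumerate(ann.domains):
            rows.append(
                {
                    "protein_id": ann.protein_id,
                    "domain_index": i,
                    "hepta_start": d.hepta.start,
                    "motif7": d.hepta.motif7,
                    "mismatches": d.hepta.mismatches,
                    "partial": d.hepta.partial,
                    "zf_type": d.zf.zf_type if d.zf else "Lost",
                    "c1": d.zf.c1 if d.zf else "",
                    "c2": d.zf.c2 if d.zf else "",
                    "spacer": d.zf.cc_spacer if d.zf else "",
                    "complete": d.complete,
                }
            )
    return rows
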