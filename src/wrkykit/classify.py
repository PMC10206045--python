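"""Group/subgroup classification of annotated WRKY proteins.

Structural decision ladder (first match wins):

1. two or more domains and any C2H2 zinc finger        -> Group I
2. any C2HC zinc finger                                -> Group III
3. no intact zinc finger on any domain                 -> UC
4. single C2H2 domain with a C-X4-C spacer             -> IIc
5. single C2H2 with C-X5-C: the 7 residues after the second cysteine are
   matched against the subgroup signatures
       IIa  P V K K K [LV] Q
       IIb  P V R K Q  V   Q
       IId  P A R K H  V   E
       IIe  P A R K [QM] V [ED]
   exact match wins; otherwise the minimum-Hamming signature within a
   configurable tolerance (default 2); otherwise UC.

Proteins left UC by structure can be resolved by label transfer on a
phylogeny: each UC leaf inherits the label of its nearest labeled leaf by
patristic distance (ties: majority label among the tied set, then the
lexically smallest label).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io import GROUP_LABELS, LabeledTree, WrkykitError
from .scan import WrkyAnnotation

#: subgroup signatures applied to the post-C2 window, anchored at the first
#: residue after the second cysteine; each position is a residue class
SUBGROUP_SIGNATURES: dict[str, tuple[frozenset[str], ...]] = {
    "IIa": tuple(map(frozenset, ("P", "V", "K", "K", "K", "LV", "Q"))),
    "IIb": tuple(map(frozenset, ("P", "V", "R", "K", "Q", "V", "Q"))),
    "IId": tuple(map(frozenset, ("P", "A", "R", "K", "H", "V", "E"))),
    "IIe": tuple(map(frozenset, ("P", "A", "R", "K", "QM", "V", "ED"))),
}

MAIN_GROUPS = {"I": ("I",), "II": ("IIa", "IIb", "IIc", "IId", "IIe"), "III": ("III",)}


@dataclass(frozen=True)
class ClassificationResult:
    protein_id: str
    label: str
    basis: str  # {"structural", "tree", "fixture"}
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise WrkykitError(f"unknown label {self.label!r}")


def signature_mismatches(window: str, subgroup: str) -> int:
    """Hamming-style distance of a post-C2 window to a subgroup signature;
    padding ('-') always mismatches."""
    pattern = SUBGROUP_SIGNATURES[subgroup]
    return sum(1 for i, allowed in enumerate(pattern) if window[i] not in allowed)


def classify_structural(
    annotation: WrkyAnnotation, max_sig_mismatch: int = 2
) -> ClassificationResult:
    """Apply the structural decision ladder to one annotated protein."""
    if not annotation.domains:
        raise WrkykitError(
            f"protein {annotation.protein_id!r} has no WRKY domain; not a WRKY"
        )
    pid = annotation.protein_id
    zfs = [d.zf for d in annotation.domains if d.zf is not None]

    if len(annotation.domains) >= 2 and any(z.zf_type == "C2H2" for z in zfs):
        return ClassificationResult(pid, "I", "structural", "two domains + C2H2")
    if any(z.zf_type == "C2HC" for z in zfs):
        return ClassificationResult(pid, "III", "structural", "C2HC zinc finger")
    if not zfs or all(d.hepta.partial for d in annotation.domains):
        return ClassificationResult(pid, "UC", "structural", "zinc finger lost/partial")

    zf = zfs[0]
    if zf.cc_spacer == 4:
        return ClassificationResult(pid, "IIc", "structural", "C-X4-C")

    window = zf.post_c2_window
    scored = sorted(
        (signature_mismatches(window, sg), sg) for sg in SUBGROUP_SIGNATURES
    )
    best_mm, best_sg = scored[0]
    if best_mm == 0:
        return ClassificationResult(
            pid, best_sg, "structural", f"signature {window[:7]}"
        )
    if best_mm <= max_sig_mismatch:
        return ClassificationResult(
            pid, best_sg, "structural", f"signature {window[:7]} ({best_mm} mm)"
        )
    return ClassificationResult(pid, "UC", "structural", f"no signature ({window[:7]})")


def classify_proteome(
    annotations: list[WrkyAnnotation], max_sig_mismatch: int = 2
) -> list[ClassificationResult]:
    return [classify_structural(a, max_sig_mismatch) for a in annotations]


def transfer_labels(
    tree: LabeledTree, structural: list[ClassificationResult]
) -> list[ClassificationResult]:
    """Resolve UC proteins by nearest-labeled-leaf patristic distance.

    Structurally classified (non-UC) results are never changed.  A UC
    protein missing from the tree is an error.
    """
    uc = [r for r in structural if r.label == "UC"]
    if not uc:
        return list(structural)
    leaf_set = set(tree.leaf_names())
    missing = [r.protein_id for r in uc if r.protein_id not in leaf_set]
    if missing:
        raise WrkykitError(f"UC proteins missing from tree: {missing}")
    labeled = [(leaf, lab) for leaf, lab in tree.labels.items() if lab != "UC"]
    if not labeled:
        raise WrkykitError("tree has no labeled leaves to transfer from")
    dist = tree.patristic_distances()

    out: list[ClassificationResult] = []
    for r in structural:
        if r.label != "UC":
            out.append(r)
            continue
        scored = [(dist[(r.protein_id, leaf)], leaf, lab) for leaf, lab in labeled]
        dmin = min(s[0] for s in scored)
        tied = [s for s in scored if s[0] == dmin]
        if len(tied) == 1:
            _, leaf, lab = tied[0]
            evidence = f"nearest leaf {leaf} (d={dmin:g})"
        else:
            counts = Counter(lab for _, _, lab in tied)
            top = max(counts.values())
            lab = min(l for l, c in counts.items() if c == top)
            evidence = f"tie at d={dmin:g}, majority/lexical -> {lab}"
        out.append(ClassificationResult(r.protein_id, lab, "tree", evidence))
    return out


def apply_reassignment(
    results: list[ClassificationResult], mapping: dict[str, str]
) -> list[ClassificationResult]:
    """Overwrite labels from an externally curated reassignment map (only
    sensible for UC members resolved elsewhere); basis becomes 'fixture'."""
    out = []
    for r in results:
        if r.protein_id in mapping:
            out.append(
                ClassificationResult(
                    r.protein_id, mapping[r.protein_id], "fixture", "curated map"
                )
            )
        else:
            out.append(r)
    return out


def summarize_groups(results: list[ClassificationResult]) -> dict[str, int]:
    """Counts per subgroup label plus main-group totals (II = IIa..IIe)."""
    counts = Counter(r.label for r in results)
    summary = {label: counts.get(label, 0) for label in GROUP_LABELS}
    for main, members in MAIN_GROUPS.items():
        summary[f"main_{main}"] = sum(counts.get(m, 0) for m in members)
    summary["total"] = len(results)
    return summary
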