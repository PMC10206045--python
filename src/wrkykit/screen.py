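"""The candidate-gene expression screen.

Differential expression between two flower-color varieties at the same
floral stage is called by fold change alone: a gene is a DEG when
|log2 FC| >= 1 (2-fold), computed on replicate-mean FPKM with a
pseudocount.  The two colored-vs-white DEG sets of a stage (red vs white
and pink vs white) are then intersected: genes up in both are candidate
positive regulators of anthocyanin pigmentation, genes down in both are
candidate suppressors.

Also here: the 2^-ddCt arithmetic used to validate RNA-seq calls by qPCR
against one or more reference genes, and hypergeometric (Fisher upper
tail) term enrichment with Bonferroni correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import STAGES, ExpressionTable, WrkykitError


@dataclass(frozen=True)
class Contrast:
    """A baseline-vs-treatment sample comparison within one stage."""

    name: str
    baseline: tuple[str, ...]
    treatment: tuple[str, ...]
    stage: str

    def __post_init__(self) -> None:
        if not self.baseline or not self.treatment:
            raise WrkykitError(f"contrast {self.name!r}: empty sample set")
        if set(self.baseline) & set(self.treatment):
            raise WrkykitError(f"contrast {self.name!r}: overlapping sample sets")
        if self.stage not in STAGES:
            raise WrkykitError(f"contrast {self.name!r}: unknown stage {self.stage!r}")


def contrast_from_table(
    table: ExpressionTable, name: str, baseline_variety: str,
    treatment_variety: str, stage: str,
) -> Contrast:
    """Build a contrast from the table's sample metadata."""
    return Contrast(
        name,
        tuple(table.samples_for(baseline_variety, stage)),
        tuple(table.samples_for(treatment_variety, stage)),
        stage,
    )


@dataclass
class DegSet:
    """Up/down DEG sets of one contrast plus all per-gene log2 fold changes."""

    contrast: str
    stage: str
    up: set[str]
    down: set[str]
    fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise WrkykitError("gene in both up and down sets")


@dataclass
class CandidateResult:
    """Per-stage intersection of the two colored-vs-white DEG sets."""

    stage: str
    positive: set[str]  # up in both contrasts: putative pigment promoters
    negative: set[str]  # down in both: putative suppressors

    @property
    def n_candidates(self) -> int:
        return len(self.positive) + len(self.negative)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study hits
    n: int  # study size
    K: int  # population hits
    N: int  # population size
    p: float
    padj: float
    significant: bool


def log2_fold_change(
    table: ExpressionTable, contrast: Contrast, pseudocount: float = 1.0
) -> dict[str, float]:
    """log2((mean treatment FPKM + pc) / (mean baseline FPKM + pc)) per gene;
    replicate means are arithmetic."""
    missing = [
        s for s in (*contrast.baseline, *contrast.treatment)
        if s not in table.values.columns
    ]
    if missing:
        raise WrkykitError(f"contrast {contrast.name!r}: samples {missing} not in table")
    base = table.values[list(contrast.baseline)].mean(axis=1)
    treat = table.values[list(contrast.treatment)].mean(axis=1)
    fc = np.log2((treat + pseudocount) / (base + pseudocount))
    return dict(fc)


def call_degs(
    fc: Mapping[str, float], contrast: str = "", stage: str = "bud",
    threshold: float = 1.0,
) -> DegSet:
    """Threshold DEG calling; boundary values are included (>=)."""
    if threshold <= 0:
        raise WrkykitError("DEG threshold must be positive")
    up = {g for g, v in fc.items() if v >= threshold}
    down = {g for g, v in fc.items() if v <= -threshold}
    return DegSet(contrast, stage, up, down, dict(fc))


def screen_candidates(deg_rf: DegSet, deg_pf: DegSet) -> CandidateResult:
    """Intersect the two colored-vs-white DEG sets of one stage."""
    if deg_rf.stage != deg_pf.stage:
        raise WrkykitError(
            f"stage mismatch: {deg_rf.stage!r} vs {deg_pf.stage!r}"
        )
    return CandidateResult(
        deg_rf.stage,
        positive=deg_rf.up & deg_pf.up,
        negative=deg_rf.down & deg_pf.down,
    )


def ddct_fold_change(
    ct_target: Mapping[str, float],
    ct_refs: Sequence[Mapping[str, float]],
    groups: Mapping[str, Sequence[str]],
    calibrator: str,
) -> dict[str, float]:
    """Relative expression by the 2^-ddCt method.

    dCt(sample) = Ct_target - mean over reference genes of Ct_ref;
    ddCt(group) = mean dCt(group) - mean dCt(calibrator);
    fold(group) = 2^-ddCt.  The calibrator group's fold is exactly 1.
    """
    if calibrator not in groups:
        raise WrkykitError(f"calibrator group {calibrator!r} not in groups")
    if not ct_refs:
        raise WrkykitError("at least one reference gene required")
    dct: dict[str, float] = {}
    for group, samples in groups.items():
        for s in samples:
            if s in dct:
                continue
            if s not in ct_target:
                raise WrkykitError(f"missing target Ct for sample {s!r}")
            refs = []
            for ref in ct_refs:
                if s not in ref:
                    raise WrkykitError(f"missing reference Ct for sample {s!r}")
                refs.append(ref[s])
            dct[s] = ct_target[s] - sum(refs) / len(refs)

    def group_mean(g: str) -> float:
        return sum(dct[s] for s in groups[g]) / len(groups[g])

    cal = group_mean(calibrator)
    return {g: 2.0 ** -(group_mean(g) - cal) for g in groups}


def fisher_enrichment(
    study: set[str],
    population: set[str],
    term_map: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of annotation terms in a study set.

    p is the hypergeometric upper tail P(X >= k) (one-sided Fisher exact);
    the Bonferroni factor is the number of terms actually tested (terms
    with at least one population gene after intersection).
    """
    outside = study - population
    if outside:
        raise WrkykitError(f"study genes outside population: {sorted(outside)}")
    N, n = len(population), len(study)
    tested = {
        term: genes & population
        for term, genes in term_map.items()
        if genes & population
    }
    m = len(tested)
    results = []
    for term in sorted(tested):
        genes = tested[term]
        K = len(genes)
        k = len(genes & study)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, p)
        padj = min(1.0, p * m)
        results.append(EnrichmentResult(term, k, n, K, N, p, padj, padj < alpha))
    results.sort(key=lambda r: (r.p, r.term))
    return results
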