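"""End-to-end orchestration: scan -> classify -> summarize; dupmodes ->
kaks; degs -> screen -> enrich, driven by a YAML run configuration.

Every stage reads and writes plain TSV so each can also be run standalone
from a previous stage's outputs; the run directory additionally gets one
versioned ``summary.json``.  All randomness flows from explicit config
seeds; reruns of an identical config produce byte-identical tables.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import dupmodes as _dup
from . import kaks as _kaks
from . import screen as _screen
from .io import (
    WrkykitError,
    read_expression_table,
    read_fasta,
    read_gene_table,
    read_newick,
    read_pairs,
)
from .scan import annotate_proteome, annotation_rows

log = logging.getLogger("wrkykit")

SUMMARY_SCHEMA_VERSION = 1

KNOWN_STAGES = ("scan", "classify", "dupmodes", "kaks", "screen", "enrich")

_PARAM_RANGES = {
    "signature_mismatch_max": (0, 7),
    "min_anchors": (2, 1000),
    "max_rank_gap": (1, 10_000),
    "proximal_max": (1, 10_000),
    "pseudocount": (0.0, 1e6),
    "deg_threshold": (1e-9, 100.0),
    "epsilon": (0.0, 1.0),
    "alpha": (0.0, 1.0),
}

_STAGE_INPUTS = {
    "scan": ("proteins",),
    "classify": ("proteins",),
    "dupmodes": ("gene_table", "pairs"),
    "kaks": ("proteins", "cds", "pairs"),
    "screen": ("expression", "expression_metadata"),
    "enrich": ("expression", "expression_metadata", "term_map"),
}


def validate_config(config: dict) -> dict:
    """Check stage names, tunable ranges and input-file existence; returns
    the config with defaults filled in."""
    stages = config.get("stages") or []
    if not stages:
        raise WrkykitError("config enables no stages")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise WrkykitError(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")
    params = dict(config.get("params") or {})
    for name, (lo, hi) in _PARAM_RANGES.items():
        if name in params and not (lo <= params[name] <= hi):
            raise WrkykitError(f"param {name}={params[name]} outside [{lo}, {hi}]")
    inputs = dict(config.get("inputs") or {})
    needed = {k for s in stages for k in _STAGE_INPUTS[s]}
    for key in sorted(needed):
        if key not in inputs:
            raise WrkykitError(f"config missing input {key!r} required by enabled stages")
    for key, path in inputs.items():
        if path and not Path(path).exists():
            raise WrkykitError(f"input {key!r}: file {path} does not exist")
    out = dict(config)
    out["params"] = params
    out["inputs"] = inputs
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns the summary
    dict (also written to ``summary.json``)."""
    config = validate_config(config)
    stages = config["stages"]
    params = config["params"]
    inputs = config["inputs"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "stages": list(stages)}

    def stage_error(stage: str, exc: Exception):
        return WrkykitError(f"stage {stage!r} failed: {exc}")

    annotations = None
    if "scan" in stages or "classify" in stages:
        try:
            proteins = read_fasta(inputs["proteins"], "protein")
            annotations = annotate_proteome(proteins)
            _write_tsv(pd.DataFrame(annotation_rows(annotations)), outdir / "domains.tsv")
            summary["scan"] = {
                "n_proteins": len(proteins),
                "n_wrky": len(annotations),
                "n_domains": sum(len(a.domains) for a in annotations),
            }
        except WrkykitError as exc:
            raise stage_error("scan", exc) from exc

    if "classify" in stages:
        try:
            results = _classify.classify_proteome(
                annotations, params.get("signature_mismatch_max", 2)
            )
            if inputs.get("tree"):
                tree = read_newick(inputs["tree"], inputs.get("tree_labels"))
                results = _classify.transfer_labels(tree, results)
            if inputs.get("reassign_map"):
                mapping = dict(
                    pd.read_csv(inputs["reassign_map"], sep="\t", dtype=str).values
                )
                results = _classify.apply_reassignment(results, mapping)
            rows = [
                {"protein_id": r.protein_id, "label": r.label, "basis": r.basis,
                 "evidence": r.evidence}
                for r in results
            ]
            _write_tsv(pd.DataFrame(rows), outdir / "classification.tsv")
            summary["classify"] = _classify.summarize_groups(results)
        except WrkykitError as exc:
            raise stage_error("classify", exc) from exc

    if "dupmodes" in stages:
        try:
            loci = read_gene_table(inputs["gene_table"])
            pairs = read_pairs(inputs["pairs"])
            blocks, calls = _dup.classify_pairs(
                pairs,
                loci,
                params.get("min_anchors", _dup.DEFAULT_MIN_ANCHORS),
                params.get("max_rank_gap", _dup.DEFAULT_MAX_RANK_GAP),
                params.get("proximal_max", _dup.DEFAULT_PROXIMAL_MAX),
            )
            gene_modes = _dup.assign_gene_modes(calls)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"block": i, "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                         "n_anchors": b.n_anchors}
                        for i, b in enumerate(blocks)
                    ]
                ),
                outdir / "blocks.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"gene_a": c.pair.gene_a, "gene_b": c.pair.gene_b, "mode": c.mode}
                        for c in calls
                    ]
                ),
                outdir / "pair_modes.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    [{"gene_id": g.gene_id, "mode": g.mode} for g in gene_modes]
                ),
                outdir / "gene_modes.tsv",
            )
            summary["dupmodes"] = {
                "n_blocks": len(blocks),
                "pair_modes": _dup.mode_tally(calls),
                "gene_modes": _dup.mode_tally(gene_modes),
            }
        except WrkykitError as exc:
            raise stage_error("dupmodes", exc) from exc

    if "kaks" in stages:
        try:
            prot = {r.id: r.seq for r in read_fasta(inputs["proteins"], "protein")}
            cds = {r.id: r.seq for r in read_fasta(inputs["cds"], "dna")}
            pairs = read_pairs(inputs["pairs"])
            results = _kaks.kaks_for_pairs(
                pairs, prot, cds, params.get("epsilon", 0.05)
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"gene_a": r.id_a, "gene_b": r.id_b, "S": r.S, "N": r.N,
                         "Sd": r.Sd, "Nd": r.Nd, "Ka": r.Ka, "Ks": r.Ks,
                         "ratio": r.ratio, "category": r.category}
                        for r in results
                    ]
                ),
                outdir / "kaks.tsv",
            )
            cats: dict[str, int] = {}
            for r in results:
                cats[r.category] = cats.get(r.category, 0) + 1
            summary["kaks"] = {"n_pairs": len(results), "categories": cats}
        except WrkykitError as exc:
            raise stage_error("kaks", exc) from exc

    if "screen" in stages or "enrich" in stages:
        try:
            table = read_expression_table(
                inputs["expression"], inputs["expression_metadata"]
            )
            candidates: dict[str, _screen.CandidateResult] = {}
            deg_rows = []
            for stage_name in ("bud", "full_bloom"):
                degs = {}
                for variety in ("RF", "PF"):
                    contrast = _screen.contrast_from_table(
                        table, f"WFvs{variety}_{stage_name}", "WF", variety, stage_name
                    )
                    fc = _screen.log2_fold_change(
                        table, contrast, params.get("pseudocount", 1.0)
                    )
                    degs[variety] = _screen.call_degs(
                        fc, contrast.name, stage_name,
                        params.get("deg_threshold", 1.0),
                    )
                    for g in sorted(degs[variety].up | degs[variety].down):
                        deg_rows.append(
                            {"contrast": contrast.name, "gene": g,
                             "log2fc": fc[g],
                             "direction": "up" if g in degs[variety].up else "down"}
                        )
                candidates[stage_name] = _screen.screen_candidates(
                    degs["RF"], degs["PF"]
                )
            _write_tsv(pd.DataFrame(deg_rows), outdir / "degs.tsv")
            cand_rows = [
                {"stage": st, "direction": d, "gene": g}
                for st, cr in candidates.items()
                for d, genes in (("up", cr.positive), ("down", cr.negative))
                for g in sorted(genes)
            ]
            _write_tsv(pd.DataFrame(cand_rows), outdir / "candidates.tsv")
            summary["screen"] = {
                st: {"positive": sorted(cr.positive), "negative": sorted(cr.negative)}
                for st, cr in candidates.items()
            }
        except WrkykitError as exc:
            raise stage_error("screen", exc) from exc

    if "enrich" in stages:
        try:
            tm = pd.read_csv(inputs["term_map"], sep="\t", dtype=str)
            term_map: dict[str, set[str]] = {}
            for r in tm.itertuples():
                term_map.setdefault(r.term_id, set()).add(r.gene_id)
            population = set(table.genes)
            study = set().union(
                *(cr.positive | cr.negative for cr in candidates.values())
            )
            results = _screen.fisher_enrichment(
                study & population, population, term_map, params.get("alpha", 0.05)
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                         "p": r.p, "padj": r.padj, "significant": r.significant}
                        for r in results
                    ]
                ),
                outdir / "enrichment.tsv",
            )
            summary["enrich"] = {
                "n_terms_tested": len(results),
                "n_significant": sum(r.significant for r in results),
            }
        except WrkykitError as exc:
            raise stage_error("enrich", exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
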