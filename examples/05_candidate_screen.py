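"""The candidate-gene screen, on synthetic FPKM and on the printed lists.

Part 1 plants 10 up- and 10 down-regulated genes (8-fold, both colored
varieties) in a noisy three-variety x two-stage FPKM table and recovers
them via the two-contrast intersection.  Part 2 replays the intersection
arithmetic on the packaged per-stage DEG lists, reproducing the
published candidate counts (17 at bud, 9 at full bloom, one shared gene).
"""
from wrkykit.fixtures import load_candidate_lists
from wrkykit.screen import DegSet, call_degs, contrast_from_table, log2_fold_change, screen_candidates
from wrkykit.simulate import gen_fpkm_table

# part 1: synthetic recovery
table, truth = gen_fpkm_table(n_genes=100, n_planted_pos=10, n_planted_neg=10, seed=3)
degs = {}
for variety in ("RF", "PF"):
    contrast = contrast_from_table(table, f"WFvs{variety}", "WF", variety, "bud")
    degs[variety] = call_degs(log2_fold_change(table, contrast), contrast.name, "bud")
result = screen_candidates(degs["RF"], degs["PF"])
print(f"synthetic bud stage: {len(result.positive)} positive, "
      f"{len(result.negative)} negative candidates")
print(f"  planted sets recovered: "
      f"{result.positive == set(truth.positive) and result.negative == set(truth.negative)}")

# part 2: the printed per-stage lists
lists = load_candidate_lists()
for stage, up, down in (
    ("bud", lists.bud_up, lists.bud_down),
    ("full_bloom", lists.bloom_up, lists.bloom_down),
):
    rf = DegSet("WFvsRF", stage, set(up), set(down))
    pf = DegSet("WFvsPF", stage, set(up), set(down))
    r = screen_candidates(rf, pf)
    print(f"{stage}: {r.n_candidates} candidates "
          f"({len(r.positive)} up + {len(r.negative)} down)")
bud = set(lists.bud_up) | set(lists.bud_down)
bloom = set(lists.bloom_up) | set(lists.bloom_down)
print(f"shared between stages: {sorted(bud & bloom)}")
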