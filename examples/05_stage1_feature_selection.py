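"""Stage 1: prioritize feature groups and prune by normalized weighted sum.

Builds a feature-domain dataset in which 6 of 63 groups carry the class
signal (each for its own stratum of trials), runs a scaled batch-of-colonies
prioritization loop, and prints the NWS heatmap and the surviving groups.
Runtime: ~10 s.
"""

from bmnabc import ClassifierSpec, ColonyConfig, Stage1Config, generate_feature_dataset, stage1_loop
from bmnabc.experiments import SCALED_PROTO, planted_group_indices
from bmnabc.stage1 import export_nws_heatmap

fm = generate_feature_dataset(seed=100, strata="group", effect_size=6.0)
planted = planted_group_indices(fm)

res = stage1_loop(
    fm,
    ClassifierSpec("knn_cosine"),
    ColonyConfig(d=fm.n_groups, n=10, max_iter=25, limit=5),
    SCALED_PROTO,
    Stage1Config(n_runs=10, reps_per_mask=20),
    seed=0,
)

final = set(res.final_active.tolist())
print(f"cycles run:        {len(res.cycles)}")
print(f"surviving groups:  {sorted(fm.groups[i].name for i in final)}")
print(f"planted recovered: {len(planted & final)}/{len(planted)}")
print()
print("NWS heatmap of the first batch (accuracy-weighted selection frequency;")
print("1.0 = chosen by every run, blank = already removed):")
print(export_nws_heatmap(res.cycles[-1].nws, fm).round(2).to_string())
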