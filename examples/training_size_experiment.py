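"""Training-size saturation experiment with McNemar comparisons.

Runs the seven configurations (3 singles + 4 hybrids) at several
training sizes with repeated seeded draws, prints the mean +/- SD OA
curve, and tallies McNemar significance categories per size group.
"""

from cropfuse import (aggregate_mcnemar, default_pool, generate_scene,
                      preset_config, run_experiment, CONFIG_NAMES)

config = preset_config("bole6", seed=5)
cube, labels, objects = generate_scene(config)
pool = default_pool(labels, seed=5)

result = run_experiment(cube, labels, objects, pool,
                        sizes=[50, 500], runs=3, seed=5)

print(f"{'config':<16}" + "".join(f"  n={s:<12}" for s in result.sizes))
for cfg in CONFIG_NAMES:
    cells = []
    for size in result.sizes:
        row = result.summary[(result.summary["config"] == cfg)
                             & (result.summary["size"] == size)]
        cells.append(f"{row['oa_mean'].iloc[0]:6.2f}+/-{row['oa_std'].iloc[0]:4.2f}")
    print(f"{cfg:<16}" + "  ".join(cells))

tallies = aggregate_mcnemar(result)
pair = tallies[(tallies["classifier_1"] == "mvote_object")
               & (tallies["classifier_2"] == "c5")]
print("\nmvote_object vs c5 (McNemar categories per size):")
print(pair[["group", "s_plus", "n", "s_minus"]].to_string(index=False))

# OA rises and its run-to-run SD shrinks as training grows; the S+ counts
# show where the object-level hybrid is significantly more accurate than
# the boosted-tree single classifier.
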