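"""Run all five unsupervised selector families on one synthetic cohort.

Generates a cohort of patients with latent comorbidity factors, encodes
it, and asks each method for its best 15 of ~80 ancestor-closed code
columns.  The depth-weighted concrete autoencoder (caeww) additionally
receives the 1/(1+depth) loss weights from the hierarchy.
"""

import numpy as np

from codesel import (
    AEFSConfig,
    CAEConfig,
    SynthConfig,
    aefs_select,
    aggregate_records,
    cae_select,
    depth_weights_for,
    encode_one_hot,
    generate_hierarchy,
    generate_records,
    laplacian_score,
    mcfs_scores,
    pfa_select,
)

cfg = SynthConfig(n_patients=300, seed=5)
hierarchy = generate_hierarchy(cfg.hierarchy_shape, 5)
raw, truth = generate_records(cfg, hierarchy)
matrix = encode_one_hot(aggregate_records(raw, cfg.window_days), hierarchy)
print(f"cohort: {matrix.n_records} aggregated records x {matrix.n_features} code columns")

n_best = 15
weights = np.asarray(depth_weights_for(hierarchy, matrix.feature_codes))
runs = {
    "ls": laplacian_score(matrix, n_best),
    "mcfs": mcfs_scores(matrix, n_best),
    "aefs": aefs_select(matrix, n_best, AEFSConfig(epochs=100), seed=5),
    "pfa": pfa_select(matrix, n_best, seed=5),
    "cae": cae_select(matrix, n_best, CAEConfig(epochs=100), seed=5),
    "caeww": cae_select(matrix, n_best, CAEConfig(epochs=100, weight_adjust=True),
                        seed=5, feature_weights=weights),
}

for name, result in runs.items():
    codes = [matrix.feature_codes[j] for j in result.selected]
    depths = [hierarchy.depth(c) for c in codes]
    print(f"{name:>6}: {len(codes):2d} codes, mean depth {np.mean(depths):.2f}, "
          f"first five: {codes[:5]}")
# The concrete autoencoder may return fewer than n_best codes (selector
# neurons can agree on a feature); the weighted variant leans toward
# shallower, more general codes.
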