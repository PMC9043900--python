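"""Train a small dual-branch late-fusion regressor on synthetic canopies.

Demonstration-sized run (fewer scenes and epochs than the full benchmark,
about a minute on one CPU): each modality branch is first trained as its
own regressor, the heads are stripped, and the fused network (concatenated
branch features -> FC head) is fine-tuned end to end with the MAPE loss.
For the full-accuracy run see scripts/acceptance.py.
"""

import numpy as np

from canopymass.benchmark import make_benchmark_datasets, train_fusion_benchmark

datasets = make_benchmark_datasets(seed=5, n_train_pool=160, n_test=40, n_val=30)
result = train_fusion_benchmark(
    seed=5, datasets=datasets, backbone="tiny", feature_dim=96,
    pretrain_epochs=8, fusion_epochs=15,
)

print(f"held-out n={result.report.n}")
print(f"  MAPE  {result.report.mape_pct:.1f}%   (mean-mass baseline {result.baseline_mape_pct:.0f}%)")
print(f"  RMSE  {result.report.rmse_g:.2f} g")
print(f"  r     {result.report.pearson_r:.3f}")
print("single-modality ablation MAPE%:", {k: round(v, 1) for k, v in result.ablation_mape_pct.items()})
print("\nper-mass-bin error (bins follow occlusion regimes):")
for b in result.report.per_bin:
    if b.n:
        print(f"  [{b.bin_range_g[0]:>4.0f}, {b.bin_range_g[1]:>4.0f}) g  n={b.n:<3d} MAPE {b.mape_pct:5.1f}%  RMSE {b.rmse_g:.2f} g")
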