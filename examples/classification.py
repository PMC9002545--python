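"""Classify immersion conditions from EEG features with the 6-6-2 MLP.

Each (subject, condition) observation is six numbers: five relative band
powers and the fractal dimension, averaged over the nine sites.  A tanh
network (initial learning rate 0.4 annealed, momentum 0.9, stratified
70/30 split) is trained per binary contrast.  Sensitivity is the true-3D
rate, specificity the true-other rate; the AUC summarises the ROC of the
output-activation difference.  Contrasts against the eyes-open baseline
separate best because they carry the largest band-power and complexity
differences.
"""

from vreeg import (
    MLPConfig,
    SyntheticStudyConfig,
    assemble_features,
    build_fd_table,
    build_power_table,
    evaluate,
    gen_study,
    preprocess,
    train_mlp,
)
from vreeg.classify import repeated_evaluation

segments = [preprocess(s) for s in gen_study(SyntheticStudyConfig(seed=1))]
power = build_power_table(segments)
fd = build_fd_table(segments)

print(f"{'contrast':10s} {'sens':>6s} {'spec':>6s} {'acc':>6s} {'AUC':>6s}   (20 splits)")
for contrast in ("3DvsEO", "3Dvs2D", "2DvsEO", "3DvsRest"):
    ds = assemble_features(power, fd, contrast)
    rep = repeated_evaluation(ds, MLPConfig(seed=1), n_splits=20)
    print(f"{contrast:10s} {rep['sensitivity']:6.2f} {rep['specificity']:6.2f} "
          f"{rep['accuracy']:6.2f} {rep['roc_auc']:6.2f}")

single = evaluate(train_mlp(assemble_features(power, fd, "3DvsEO"), MLPConfig(seed=1)))
print(f"\nsingle 70/30 split, 3DvsEO: TP={single.TP} FP={single.FP} "
      f"TN={single.TN} FN={single.FN}, accuracy {single.accuracy:.2f}")
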