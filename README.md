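# roiaudit

Audit image classifiers for **shortcut learning** by masking the region of
interest (ROI) and checking what, if anything, the model can still learn.

Medical image classifiers can reach high benchmark AUCs while relying on
spurious signals — pacemakers, burnt-in camera text, scanner borders, or
even the *size* of an anatomical structure — rather than the pathology
itself.  `roiaudit` makes such behaviour observable for any dataset that
ships per-image ROI masks (lungs in chest X-rays, the optic disc in fundus
photographs):

1. **Masked dataset variants.** Five variants of every image: `FULL`,
   `ONLY_ROI`, `NO_ROI`, and bounding-box versions `ONLY_ROI_BB` /
   `NO_ROI_BB`.  Masked pixels are black, indistinguishable from padding.
2. **Cross-masking AUC matrix.** A classifier is trained per variant
   (5-fold cross-validation) and evaluated on every variant.  The key
   statistic is the Mann–Whitney AUC
   `A = P(s⁺ > s⁻) + ½ P(s⁺ = s⁻)`; a model that is significantly above
   chance when trained *and* evaluated without the ROI is using a shortcut.
3. **Significance.** Correlated AUCs on the same test samples are compared
   with the DeLong test (midrank structural components); following a
   fold-wise rule, a difference counts only when `p < 0.05` in at least
   three of five folds.  The shortcut verdict tests each without-ROI
   diagonal cell against a label-permuted null with the same fold rule.
4. **Dilation sweeps.** Masks are grown by a Euclidean disk of radius
   *f* pixels before masking.  Class-conditional sweeps (dilate only the
   positives' masks) expose ROI-*size* confounds: if the model uses size,
   the AUC climbs to 1 at the smallest factors.
5. **Representation and attribution.** Cosine similarity between
   embeddings of full and masked images, a seeded t-SNE overview, and
   superpixel Shapley attribution with an occlusion baseline (with an
   exact enumeration oracle for ≤ 15 segments).  The in-ROI attribution
   share summarizes whether positive evidence sits on the anatomy or on
   the border.
6. **Synthetic ground truth.** A generator plants controllable shortcuts
   (device-like tokens, border text, global offsets; correlation ρ with
   the label) and an ROI-size/label slope, so the audit can be validated
   against datasets where the right answer is known.

The built-in backbone is a compact pooled-pixel MLP (block mean + max
features, one hidden layer) so a complete 5×5-fold audit runs in minutes on
one CPU; any model exposing `predict_proba` and `embed` can be plugged in
behind `ModelHandle`.

## Worked example

Plant a pacemaker-like token outside the lungs that agrees with the label
90% of the time, then audit:

```python
from roiaudit import (RunConfig, SyntheticConfig, ShortcutSpec,
                      TrainingConfig, run_audit)

config = RunConfig(
    synthetic=SyntheticConfig(
        n_images=600, image_size=128, seed=0,
        shortcut_specs=(ShortcutSpec(kind="token", correlation=0.9),),
    ),
    strategies=("FULL", "NO_ROI", "ONLY_ROI"),
    training=TrainingConfig.desk_scale(),
    seed=0,
    out_dir="demo_run",
)
report = run_audit(config)
print(report["verdict"]["verdict"])
```

Output of this exact run:

```
verdict: shortcut risk detected
flagged: {'strategy': 'NO_ROI', 'class': 'disease', 'mean_auc': 0.7805785123966942}
FULL|FULL|disease: 0.992 +/- 0.005
NO_ROI|NO_ROI|disease: 0.781 +/- 0.033
ONLY_ROI|ONLY_ROI|disease: 0.998 +/- 0.002
FULL|NO_ROI|disease: 0.747 +/- 0.019
tabular baseline: {'disease': 0.5210831689677844}
similarity (All): {'NO_ROI': 0.512, 'ONLY_ROI': 0.41}
attribution ROI share: 0.338
```

Reading it: the model trained and evaluated **without** the ROI still
reaches AUC 0.78 — far above chance and above the metadata-only baseline
(0.52) — because the planted token is 90% predictive, so the audit flags
shortcut risk and names the `NO_ROI` cell.  Even the FULL-trained model
scores 0.75 on ROI-free images.  The attribution share (0.34) confirms that
most positive Shapley mass falls outside the ROI.  With the same config but
`correlation=0.5` (token independent of the label) the `NO_ROI` cell sits
at chance and the verdict is "no shortcut risk detected".

The same audit runs from the shell:

```bash
roiaudit audit --config config.yaml --out demo_run --seed 0
```

with subcommands `generate`, `filter`, `mask`, `train`, `evaluate`,
`sweep`, `embed`, `attribute`, `report` for the individual stages.

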