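# rbseg — semi-supervised segmentation of retinoblastoma-like fundus lesions

Retinoblastoma, the most common pediatric intraocular malignancy, presents on
wide-field fundus photographs as whitish lesions that must be delineated to
plan and follow treatment. Expert pixel-level annotation is scarce, so this
package implements a semi-supervised pipeline that needs **no manual labels**:

1. an unsupervised **Gaussian-mixture pixel labeler** produces pseudo-labels —
   the target image is stacked with three healthy reference fundus images so
   healthy retina dominates, a K = 6 mixture is fitted to the grayscale pixel
   intensities by EM, the most populous cluster is declared healthy and all
   other clusters are merged into a "suspected" mask, which is cleaned with
   median/morphology filtering;
2. the known optic-disc region (the method's classic false positive) is
   erased from each pseudo-label and weak labels are discarded;
3. a compact **convolutional refiner** (three subnetworks of three parallel
   convolutional layers with 3/5/7 kernels, ≈ 8 k parameters) is distilled
   from the pseudo-labels — trained with RMSProp (lr 0.001) at batch size 1,
   either with binary cross-entropy (graded *importance maps*) or mean
   absolute error (hard *boundary maps*), and binarized at 0.5 for
   evaluation.

Evaluation uses the Sørensen–Dice coefficient
`SDC = 2|X∩Y| / (|X|+|Y|) = 2TP / (2TP+FP+FN)` together with sensitivity,
specificity and accuracy. Because clinical retinoblastoma images are not
publicly available, the package ships a seeded **synthetic fundus phantom
generator** (background, vessels, capillary texture, drusen-like speckle,
bright optic disc, blurred whitish tumors — with paired tumor/disc
ground-truth masks) so every stage is runnable and testable end to end.

The audience is researchers in ophthalmic image analysis who want a
reproducible, dependency-light reference implementation of GMM-based
pseudo-labeling distilled into a small CNN, plus a controllable phantom
benchmark. Everything (including the network's forward/backward passes and
RMSProp) runs on numpy/scipy — no deep-learning framework required.

## Worked example

```python
from rbseg import (LabelConfig, PhantomParams, generate_phantom,
                   healthy_references, pseudo_label_image)
from rbseg.metrics import confusion_counts, classification_metrics

phantom = generate_phantom(seed=11, params=PhantomParams(
    tumor_count_range=(1, 1), tumor_radius_range=(34, 44)))
refs = healthy_references(seed=99)
mask = pseudo_label_image(phantom.rgb, refs, LabelConfig(n_init=5, seed=0))
m = classification_metrics(confusion_counts(mask, phantom.tumor_mask))
print(f"dice={m.sdc:.3f} sens={m.sensitivity:.3f} spec={m.specificity:.3f}")
```

prints

```
dice=0.822 sens=1.000 spec=0.985
```

meaning the unsupervised stage alone recovered the tumor completely
(sensitivity 1.0) with a modest halo of false-positive pixels around the
lesion and the optic disc (specificity 0.985), for a Dice overlap of 0.82
against the generator's ground truth — before any disc removal or CNN
refinement.

The full experiment (synthesize → pseudo-label → disc removal → curation →
train → evaluate) is one call or one command:

```bash
rbseg run-all --n 300 --seed 42 --out results/exp
```

which writes the dataset, pseudo-labels, checkpoint, per-image metrics CSV
and a JSON summary under `results/exp/`.

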