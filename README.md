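# fusionacl

Multimodal feature-fusion diagnosis of knee-MRI tear phantoms: a feature
pyramid over a frozen convolutional backbone, a handcrafted "traditional"
feature branch, an energy-based (restricted Boltzmann machine) fusion
classifier, and the evaluation and clinical-concordance statistics used to
judge such a model against an arthroscopic gold standard.

## Who this is for

Researchers prototyping multimodal fusion classifiers for musculoskeletal
MRI who need a fully controlled, reproducible test bed. Patient knee-MRI
datasets with arthroscopic ground truth are rarely shareable, so the
package ships a synthetic phantom generator whose slices show the
qualitative signs of tears — focal high signal interrupting the dark
ligament band or the meniscus wedge — with controllable contrast, noise
and prevalence, plus every statistic needed to evaluate the model end to
end.

## The model

For a slice `I`, block `g` of a five-block convolutional backbone yields a
feature map `H(g)` (side `input/2^(g-1)`). Maps are fused top-down,

    K(g-1) = upsample2( H'(g) ),
    H'(g-1) = y5x5( K(g-1) + y2x2( H(g-1) ) ),

with `y2x2` a lateral 2×2 convolution and `y5x5` an anti-aliasing 5×5
convolution. The finest fused map passes through batch normalization,
ReLU, adaptive max pooling (`stride = floor(In/Out)`,
`kernel = In-(Out-1)*stride`) and an affine projection to the deep vector
`o`. Concatenated with 32 handcrafted features `c`, the multimodal vector
`m = (c, o)` feeds a restricted Boltzmann machine with energy

    E(x,y) = - sum_i t_i x_i - sum_e beta_e y_e - sum_ie x_i theta_ie y_e,

trained by contrastive divergence on the likelihood `sum_j log p(x_j)`,
with a logistic output unit on the hidden activations producing the tear
probability `W`; `W >= 0.5` is called positive. Accuracy, recall and
trapezoidal ROC-AUC evaluate each (task, plane) model; Pearson chi-square
on grade 0–III tables and acute-vs-chronic concomitant-injury rates cover
the clinical concordance side. See `docs/methods.md` for assumptions and
design choices.

## Worked example

```python
from fusionacl import phantom, pipeline

cfg = phantom.PhantomConfig(n_images=200, plane="sagittal",
                            lesion_contrast=0.4, noise_sd=0.1, seed=11)
images = phantom.generate_dataset(cfg)
train, test = images[:160], images[160:]

report = pipeline.run_experiment(train, test,
                                 pipeline.TaskSpec("acl_tear", "sagittal"),
                                 pipeline.ExperimentConfig())
print(report.to_dict())
```

prints

```
{'task': 'acl_tear', 'plane': 'sagittal', 'accuracy': 1.0, 'recall': 1.0,
 'auc': 1.0, 'confusion': {'tp': 31, 'fp': 0, 'tn': 9, 'fn': 0},
 'n_train': 160, 'n_test': 40, 'seed': 0, 'config_hash': 'aae82c773c3a'}
```

i.e. on held-out phantoms at contrast 0.4 and noise 0.1 the fused model
ranks every torn knee above every intact one (AUC 1.0) and calls all 40
test slices correctly at the 0.5 threshold. The clinical statistics run
from printed counts:

```python
from fusionacl import clinical_stats as cs
stat, dof, p = cs.chi_square(cs.STUDY_GRADE_TABLE)
# -> 2.4389, 3, 0.4864 : MRI and arthroscopy grade distributions agree
```

The same functionality is exposed on the command line:

```bash
fusionacl simulate --seed 1 --out data/
fusionacl train --data data/ --task acl_tear --out model.npz
fusionacl evaluate --data data/ --model model.npz --out report.json
fusionacl stats --out stats.json
```

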