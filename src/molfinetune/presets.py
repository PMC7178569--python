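"""Named per-dataset augmentation presets.

These are the augmentation settings used for the four public benchmark
sets: the regression sets get N enumeration variants per molecule with
Gaussian label noise, the unbalanced classification sets get per-class
variant counts chosen to re-balance the training distribution.
"""

from __future__ import annotations

from molfinetune.augment import AugmentationSpec

# regression: n_augment variants per molecule, sigma_noise on variant labels
LIPOPHILICITY = AugmentationSpec(n_augment=25, sigma_noise=0.3)
FREESOLV = AugmentationSpec(n_augment=50, sigma_noise=0.5)

# classification: per-class variant counts (class 1 = active/positive)
HIV = AugmentationSpec(per_class_counts={1: 60, 0: 2})
BBBP = AugmentationSpec(per_class_counts={1: 10, 0: 30})

# language-model pretraining corpus: 4 variants per molecule
PRETRAIN_CORPUS = AugmentationSpec(n_augment=4)

AUGMENTATION_PRESETS: dict[str, AugmentationSpec] = {
    "lipophilicity": LIPOPHILICITY,
    "freesolv": FREESOLV,
    "hiv": HIV,
    "bbbp": BBBP,
    "pretrain": PRETRAIN_CORPUS,
}

# fine-tuning batch size: 128 by default, 64 for the largest set
BATCH_SIZES: dict[str, int] = {
    "lipophilicity": 128,
    "freesolv": 128,
    "hiv": 64,
    "bbbp": 128,
}
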