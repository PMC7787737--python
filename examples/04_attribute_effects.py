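"""Condition the reconstruction on age and BMI.

With z-scored age/BMI appended to the skull latent coordinates, the
regression learns the planted soft-tissue response: reconstructing the
same skull at a higher BMI moves the face outward along the vertex
normals (a fatter face), and a higher age thickens the lower face.
"""

import warnings

import numpy as np

from cranioface import (
    GeneratorConfig,
    PipelineConfig,
    random_split,
    reconstruct,
    sample_population,
    train,
)

warnings.simplefilter("ignore")

samples, _ = sample_population(GeneratorConfig(seed=0))
train_set, test_set = random_split(samples, 12, seed=1)

bundle = train(train_set, PipelineConfig(seed=0, use_attributes=True))
skull = test_set[0].skull


def outward_offset(a, b):
    centre = a.vertices.mean(axis=0)
    n = a.vertices - centre
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return ((b.vertices - a.vertices) * n).sum(axis=1).mean()


slim = reconstruct(bundle, skull, {"age": 45.0, "bmi": 20.0})
stout = reconstruct(bundle, skull, {"age": 45.0, "bmi": 30.0})
young = reconstruct(bundle, skull, {"age": 30.0, "bmi": 24.0})
old = reconstruct(bundle, skull, {"age": 70.0, "bmi": 24.0})

print(f"mean outward soft-tissue offset, BMI 20 -> 30: "
      f"{outward_offset(slim, stout):+.2f} mm (positive = fatter face)")
print(f"mean outward soft-tissue offset, age 30 -> 70: "
      f"{outward_offset(young, old):+.2f} mm")
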