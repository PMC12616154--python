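"""Published reference values used as pipeline inputs.

The five retained model RDMs in the action-recognition study — a CNN
low-level visual model, a GIST scene-descriptor model, a binary
1-vs-2-people model, and behavioral body-part and semantic models — have a
published table of pairwise Pearson correlations (computed between the
normalized model RDM vectors over the 27 basic-level actions). That table is
an input to collinearity diagnostics and to the synthetic behavioral-RDM
generator, so it ships here as data.
"""

import numpy as np

#: Order of the five retained models in the correlation table.
MODEL_NAMES = ("alexnet", "gist", "people", "body", "semantic")

# The ten printed pairwise correlations, keyed by model pair.
_pairs = {
    ("alexnet", "gist"): 0.36,
    ("alexnet", "people"): 0.14,
    ("alexnet", "body"): 0.16,
    ("alexnet", "semantic"): 0.21,
    ("gist", "people"): -0.05,
    ("gist", "body"): 0.34,
    ("gist", "semantic"): 0.19,
    ("people", "body"): -0.01,
    ("people", "semantic"): 0.15,
    ("body", "semantic"): 0.47,
}

#: Pairwise Pearson correlations between the five normalized model RDMs,
#: symmetric with unit diagonal, in MODEL_NAMES order.
MODEL_RDM_CORRELATIONS = np.eye(5)
for (a, b), r in _pairs.items():
    i, j = MODEL_NAMES.index(a), MODEL_NAMES.index(b)
    MODEL_RDM_CORRELATIONS[i, j] = MODEL_RDM_CORRELATIONS[j, i] = r
del _pairs

#: Number of basic-level action conditions in the study design.
N_ACTIONS = 27
#: Exemplars per action: 2 actors x 2 location exemplars x 3 viewpoints.
N_EXEMPLARS = 12
#: Each image appears twice as the first stimulus.
N_REPETITIONS = 2
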