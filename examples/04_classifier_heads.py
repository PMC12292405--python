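"""Run each slide-level classifier head on one toy graph.

All heads consume the same padded node-feature matrix (plus adjacency or
mask where relevant) and emit a probability over the two tumor subtypes
(class 0 = adenocarcinoma, class 1 = squamous cell carcinoma).
"""

import numpy as np

from evoslide.graphs import normalize_adjacency
from evoslide.heads import GCNN, GatedAttentionMIL, OneDCNN, TransMILHead, TwoDCNN

rng = np.random.default_rng(0)
N, d = 6, 2
mask = np.zeros((1, N))
mask[:, :4] = 1.0                       # 4 real nodes, 2 padded
X = rng.normal(size=(1, N, d)) * mask[:, :, None]
A = np.zeros((N, N))
A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
A_hat = normalize_adjacency(A, mask[0].astype(bool))[None]

print("head        P(AC)   P(SCC)")
for name, head, inputs in [
    ("1D-CNN  ", OneDCNN(d_in=d, seed=0), {"X": X}),
    ("2D-CNN  ", TwoDCNN(d_in=d, seed=0), {"X": X}),
    ("GCNN    ", GCNN(d_in=d, seed=0), {"X": X, "A_hat": A_hat, "mask": mask}),
    ("MIL     ", GatedAttentionMIL(d_in=d, seed=0), {"H": X, "mask": mask}),
    ("TransMIL", TransMILHead(d_in=d, n_positions=N, seed=0),
     {"H": X, "mask": mask}),
]:
    p = head.predict_proba(**inputs)[0]
    print(f"{name}    {p[0]:.4f}  {p[1]:.4f}")

print()
print("Weights here are random initializations, so the probabilities hover")
print("around 0.5; training (examples/05) moves them toward the slide label.")
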