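"""The loss components on hand-built feature batches.

Evaluates the coding rate, the CRR hinge, the JS alignment loss and the
joint objective on tiny matrices where every value has a closed form.
"""

import numpy as np

import medcss as m
from medcss.objectives import CodingRateParams

params = CodingRateParams(alpha=1.0, jitter=0.0)

# a two-point +-1 batch has covariance 1, so R = 0.5*ln(2)
F = np.array([[-1.0], [1.0]])
print(f"coding rate of [[-1],[1]]: {m.coding_rate(F, params):.6f} nats "
      f"(closed form {0.5 * np.log(2):.6f})")

# the hinge fires only when the deeper features are LESS compressed
wide = np.array([[-2.0], [2.0]])   # higher coding rate
narrow = np.array([[-0.5], [0.5]])  # lower coding rate
print(f"crr_loss(narrow -> wide): {m.crr_loss(narrow, wide, params):.6f} (inactive)")
print(f"crr_loss(wide -> narrow): {m.crr_loss(wide, narrow, params):.6f} (active)")

# alignment: JS divergence between batch softmax distributions, in bits
H3 = np.array([[2.0, 0.0, 0.0]])
H4 = np.array([[0.0, 0.0, 2.0]])
print(f"alignment_loss(H3, H4) = {m.alignment_loss(H3, H4):.6f} bits")
print(f"alignment_loss(H3, H3) = {m.alignment_loss(H3, H3):.6f} bits")

bundle = m.total_loss(sup=1.0, align=0.5, crr=0.2, lambda_align=0.1, lambda_crr=0.01)
print(f"total = {bundle.total:.3f} = sup + 0.1*align + 0.01*crr")
# The joint objective is a plain weighted sum, so zero weights recover the
# purely supervised baseline exactly.
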