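"""The fold-wise (TT) correction can double the loss under leave-one-out.

Builds a 10-sample leave-one-out prediction matrix in which some
configuration predicts every held-out sample correctly while the
overall winner is wrong on 7 of 10 samples, then applies the TT
correction.  The per-fold minimum loss is 0 in every fold, so the
estimated selection bias equals the winner's own loss and the
"corrected" estimate doubles to a 140% loss — the reason this
correction is unreliable with tiny folds.
"""

import numpy as np

from bbccv import ACCURACY, PredictionTensor, tt_estimate

values = np.zeros((10, 8), dtype=int)
values[:3, 0] = 1  # the winner: correct on 3 of 10 samples
for t, i in enumerate(range(3, 10)):
    values[i, 1 + t] = 1  # each other sample covered by one configuration

y = np.ones(10, dtype=int)
tensor = PredictionTensor.from_matrix(values, np.arange(10))  # leave-one-out
res = tt_estimate(tensor, y, metric=ACCURACY)

print(f"selected configuration: {res.selected}")
print(f"uncorrected 0-1 loss (L_CVT): {res.cvt_loss:.0%}")
print(f"estimated selection bias:     {res.tt_bias:.0%}")
print(f"TT-corrected loss (L_TT):     {res.loss:.0%}")
# A loss estimate above 100% is meaningless: the correction overshoots
# whenever every single-sample fold contains some perfect predictor.
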