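"""Compute the full external-validation battery for an observed/predicted
table and evaluate the stringent criteria gate.

Any observed/predicted pairing can be scored this way, e.g. predictions
exported from another program; here the pairs come from the worked fixture.
"""

import numpy as np

from hsvr import validation
from hsvr.io import PredictionSet
from hsvr.simulate import worked_fixture

cset, desc = worked_fixture()
y = cset.response().to_numpy()
yhat = y + np.random.default_rng(0).normal(0, 0.2, len(y))  # a mock predictor

report = validation.validate_predictions(
    PredictionSet(observed=y, predicted=yhat,
                  train_mean=float(y.mean()), n_train=len(y),
                  train_ss=float(((y - y.mean()) ** 2).sum())),
    context="external",
)

print(f"q2={report.r2:.3f}  qF1={report.qf1:.3f}  qF2={report.qf2:.3f}  "
      f"qF3={report.qf3:.3f}  CCC={report.ccc:.3f}")
print(f"k={report.k:.3f}  r0^2={report.r0_sq:.3f}  rm2={report.rm2:.3f}  "
      f"<rm2>={report.rm2_mean:.3f}  drm2={report.rm2_delta:.3f}")
print("criteria:", {k: v for k, v in report.criteria.items()})

# qF1-3 and CCC measure external predictivity against different references;
# the rm2 family detects systematic bias via through-origin regressions.
# overall_pass is True only when every applicable criterion is fulfilled.
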