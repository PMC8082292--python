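"""Recompute report metrics from a published confusion matrix.

The held-out confusion matrix of the stability+invariance model in the
stratified-split scenario of the multicenter IDH1/2 study reads, with rows
as prediction and columns as reference (mutant, wild-type):

    predicted mutant:     13   1
    predicted wild-type:   2   6

Under the wild-type-positive convention this is TP=6, FP=2, FN=1, TN=13.
"""

from radicp import ConfusionMatrix, mcc, nir_test, sens_spec_acc, wilson_interval
from radicp.metrics import truncate2

cm = ConfusionMatrix(tp=6, fp=2, fn=1, tn=13, positive_class="wild-type")
sens, spec, acc = sens_spec_acc(cm)
nir, p = nir_test(cm)

print(f"sensitivity {sens:.2f}  (Wilson 95% CI "
      f"{[truncate2(v) for v in wilson_interval(6, 7)]})")
print(f"specificity {spec:.2f}  (Wilson 95% CI "
      f"{[truncate2(v) for v in wilson_interval(13, 15)]})")
print(f"accuracy    {acc:.2f}  (Wilson 95% CI "
      f"{[truncate2(v) for v in wilson_interval(19, 22)]})")
print(f"MCC         {mcc(cm):.2f}")
print(f"NIR {nir:.3f}, one-sided binomial p = {p:.3f}")
print("\nAt p < 0.05 the model's accuracy significantly exceeds what always")
print("predicting the majority class (the no-information rate) would achieve.")
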