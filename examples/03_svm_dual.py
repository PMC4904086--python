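"""Train the RBF-SVM on the XOR configuration via its dual problem.

XOR is the textbook non-linearly-separable case: no line separates the
two classes, but the Gaussian kernel lifts the points into a space where
the dual solution classifies all four correctly.  All four points become
support vectors and the decision values are symmetric by construction.
"""

import numpy as np

from mibci import TrainingSet, decision_values, predict, train_svm

x = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
y = np.array([1.0, 1.0, -1.0, -1.0])

model = train_svm(TrainingSet(x, y), C=10.0, g=1.0, tol=1e-10)
print("dual objective :", model.dual_objective)
print("support vectors:", len(model.dual_coefs), "of", len(y))
print("bias b*        :", model.bias)
print("decision values:", np.round(decision_values(model, x), 4))
print("predictions    :", predict(model, x), " (true:", y, ")")
print("kernel note: K = exp(-||x-x'||^2 / g^2); for libsvm-style tools use gamma = 1/g^2")
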