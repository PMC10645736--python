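"""Grid-optimized RBF-SVM classification of the three residue classes.

The penalty C and kernel parameter g are optimized over the integer
(log2 C, log2 g) grid in [-10, 10] with 5-fold cross-validated accuracy as
the objective; ties prefer the simpler (smaller g, then smaller C) model.
"""

from sersmix.study import svm_replicate

rep = svm_replicate(seed=1)
print(f"optimum: log2C = {rep.log2C}, log2g = {rep.log2g} "
      f"(CV accuracy {rep.cv_accuracy:.3f})")
print(f"training accuracy: {100 * rep.train_accuracy:.1f}%  "
      f"(50 Kennard-Stone training samples)")
print(f"test accuracy:     {100 * rep.test_accuracy:.1f}%  "
      f"(28 held-out samples)")
print("accuracies near 100% show the 55 characteristic wavenumbers carry "
      "enough information to separate mixtures from the pure residues")
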