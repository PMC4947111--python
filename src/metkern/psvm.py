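"""Pairwise support vector machine (pSVM) on precomputed pair Gram matrices.

The classifier separates interacting from non-interacting gene pairs with a
soft-margin SVM whose kernel is the symmetrized Kronecker pairwise kernel.
The pair feature map is never materialized: training and prediction consume
precomputed :class:`~metkern.pairwise.PairGram` blocks (kernel trick).

The dual problem

    max_a  sum a_i - 1/2 sum_ij a_i a_j d_i d_j K(p_i, p_j)
    s.t.   0 <= a_i <= C,  sum a_i d_i = 0

is solved with libsvm (scikit-learn's SVC with a precomputed kernel), but
the module's contract is the dual solution itself: the model exposes signed
dual coefficients a_i d_i, the bias b, and the decision function
f(p) = sum_i a_i d_i K(p_i, p) + b, all verified against KKT conditions and
a small-instance QP oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .kernels import KernelError, assert_psd, KernelMatrix
from .pairwise import GenePair, PairGram


@dataclass(frozen=True)
class PsvmModel:
    support_pairs: tuple[GenePair, ...]
    dual_coef: np.ndarray  # signed: alpha_i * d_i
    bias: float
    C: float
    tol: float
    kernel_name: str = ""
    seed: int | None = None

    def __post_init__(self):
        dc = np.asarray(self.dual_coef, float)
        if dc.shape != (len(self.support_pairs),):
            raise KernelError("dual coefficient length mismatch")
        object.__setattr__(self, "dual_coef", dc)


def fit_psvm(gram: PairGram, labels, C: float = 1.0, tol: float = 1e-3,
             kernel_name: str = "", seed: int | None = None) -> PsvmModel:
    """Fit a soft-margin pairwise SVM from a square precomputed Gram matrix."""
    if not gram.is_square:
        raise KernelError("training requires a square PairGram")
    labels = np.asarray(labels, int)
    n = len(gram.row_pairs)
    if labels.shape != (n,):
        raise KernelError("label length does not match Gram size")
    if len(np.unique(labels)) < 2:
        raise KernelError("training labels contain a single class")
    if C <= 0:
        raise KernelError("box constraint C must be positive")
    Kmat = KernelMatrix([f"p{i}" for i in range(n)], gram.values, "pair_gram")
    Kmat, _ = assert_psd(Kmat)  # repair tiny negative eigenvalues if present
    svc = SVC(kernel="precomputed", C=C, tol=tol)
    svc.fit(Kmat.values, labels)
    support = tuple(gram.row_pairs[i] for i in svc.support_)
    # sklearn orders dual_coef_ by class blocks but keeps support_ alignment;
    # with labels in {-1, +1} dual_coef_[0] is already alpha_i * d_i.
    dual = svc.dual_coef_[0].copy()
    return PsvmModel(support, dual, float(svc.intercept_[0]), float(C),
                     float(tol), kernel_name, seed)


def psvm_decision(model: PsvmModel, cross: PairGram) -> np.ndarray:
    """Decision values f(p) for test pairs.

    ``cross`` holds kernel values between test pairs (rows) and the model's
    support pairs (columns, in support order).  The sign is the predicted
    class; the raw value is used for AUC ranking.
    """
    if cross.col_pairs != model.support_pairs:
        raise KernelError("cross Gram columns are not aligned with support pairs")
    return cross.values @ model.dual_coef + model.bias


def dual_objective(gram_values: np.ndarray, labels: np.ndarray,
                   alpha: np.ndarray) -> float:
    """SVM dual objective sum(a) - 1/2 a^T (dd^T o K) a (diagnostics/oracle)."""
    labels = np.asarray(labels, float)
    alpha = np.asarray(alpha, float)
    Q = np.outer(labels, labels) * gram_values
    return float(alpha.sum() - 0.5 * alpha @ Q @ alpha)


def kkt_violation(model: PsvmModel, gram: PairGram, labels) -> float:
    """Maximum KKT violation of a fitted model on its training Gram.

    For each training pair with margin m_i = d_i f(p_i):
      alpha_i = 0  requires m_i >= 1, alpha_i = C requires m_i <= 1,
      0 < alpha_i < C requires m_i = 1.
    Returns the largest violation of these conditions (0 = exact optimum).
    """
    labels = np.asarray(labels, int)
    sup_index = {p: i for i, p in enumerate(gram.row_pairs)}
    cols = [sup_index[p] for p in model.support_pairs]
    f = gram.values[:, cols] @ model.dual_coef + model.bias
    margins = labels * f
    alpha = np.zeros(len(gram.row_pairs))
    for a, p in zip(np.abs(model.dual_coef), model.support_pairs):
        alpha[sup_index[p]] = a
    viol = np.zeros_like(margins)
    free = (alpha > 1e-12) & (alpha < model.C - 1e-12)
    viol[alpha <= 1e-12] = np.maximum(0.0, 1.0 - margins[alpha <= 1e-12])
    viol[alpha >= model.C - 1e-12] = np.maximum(
        0.0, margins[alpha >= model.C - 1e-12] - 1.0)
    viol[free] = np.abs(margins[free] - 1.0)
    return float(viol.max()) if viol.size else 0.0
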