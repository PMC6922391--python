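"""Independent oracles shared by the test modules."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist


def rbf(X, Z, gamma):
    return np.exp(-gamma * cdist(X, Z, "sqeuclidean"))


def qp_dual_oracle(X, y_sign, C, gamma):
    """Independent solve of the soft-margin SVM dual by generic constrained
    optimization (SLSQP). The dual is a concave QP, so the local optimum
    is global. Returns the optimal dual objective value."""
    n = len(y_sign)
    K = rbf(X, X, gamma)
    Q = (y_sign[:, None] * y_sign[None, :]) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_obj,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=neg_grad,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_sign, "jac": lambda a: y_sign}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success, res.message
    return -res.fun


def labels_from_counts(tp, fp, fn, tn):
    """Raw prediction/reference label vectors realizing given 2x2 counts."""
    pred = ["yawn"] * (tp + fp) + ["non_yawn"] * (fn + tn)
    ref = ["yawn"] * tp + ["non_yawn"] * fp + ["yawn"] * fn + ["non_yawn"] * tn
    return pred, ref
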