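"""Linear soft-margin SVM (Platt SMO) and a generic ECOC wrapper.

The decoding analyses fit tens of thousands of SVMs per subject on tiny
training sets (a handful of averaged-trial exemplars), so the solver is a
compact sequential-minimal-optimization routine compiled with numba. Its
solutions are checked against an independent reference implementation and a
brute-force margin-search oracle in the test suite.

The error-correcting-output-codes wrapper is generic over a ±1/0 code matrix
(default one-vs-one) and degenerates to a single binary SVM for two classes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

try:  # pragma: no cover - numba is a hard dependency; fallback aids debugging
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _take_step(K, y, alpha, E, i1, i2, C):
    if i1 == i2:
        return False
    a1, a2 = alpha[i1], alpha[i2]
    y1, y2 = y[i1], y[i2]
    E1, E2 = E[i1], E[i2]
    s = y1 * y2
    if s > 0:
        L = max(0.0, a1 + a2 - C)
        H = min(C, a1 + a2)
    else:
        L = max(0.0, a2 - a1)
        H = min(C, C + a2 - a1)
    if L >= H - 1e-12:
        return False
    k11, k12, k22 = K[i1, i1], K[i1, i2], K[i2, i2]
    eta = k11 + k22 - 2.0 * k12
    if eta > 1e-12:
        a2new = a2 + y2 * (E1 - E2) / eta
        if a2new < L:
            a2new = L
        elif a2new > H:
            a2new = H
    else:
        # flat direction: evaluate the objective at both clip ends
        f1 = y1 * E1 - a1 * k11 - s * a2 * k12
        f2 = y2 * E2 - a2 * k22 - s * a1 * k12
        L1 = a1 + s * (a2 - L)
        H1 = a1 + s * (a2 - H)
        psiL = L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22 + s * L * L1 * k12
        psiH = H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22 + s * H * H1 * k12
        if psiL < psiH - 1e-12:
            a2new = L
        elif psiL > psiH + 1e-12:
            a2new = H
        else:
            a2new = a2
    if abs(a2new - a2) < 1e-12 * (a2new + a2 + 1e-12):
        return False
    a1new = a1 + s * (a2 - a2new)
    d1 = y1 * (a1new - a1)
    d2 = y2 * (a2new - a2)
    for j in range(K.shape[0]):
        E[j] += d1 * K[i1, j] + d2 * K[i2, j]
    alpha[i1] = a1new
    alpha[i2] = a2new
    return True


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):
    """Solve the dual of the binary soft-margin SVM for kernel matrix K.

    ``y`` in {-1, +1}. Returns (alpha, b). The intercept is averaged over
    free support vectors, falling back to the midpoint of the KKT-feasible
    interval when every multiplier is at a bound (the libsvm convention).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    E = -y.astype(np.float64)  # decision (without b) minus target
    it = 0
    examine_all = True
    num_changed = 1
    while it < max_iter and (num_changed > 0 or examine_all):
        it += 1
        num_changed = 0
        for i2 in range(n):
            if not examine_all and (alpha[i2] <= tol or alpha[i2] >= C - tol):
                continue
            r2 = E[i2] * y[i2]
            if (r2 < -tol and alpha[i2] < C) or (r2 > tol and alpha[i2] > 0):
                best = -1.0
                i1 = -1
                for j in range(n):
                    if 0.0 < alpha[j] < C:
                        d = abs(E[j] - E[i2])
                        if d > best:
                            best = d
                            i1 = j
                if i1 >= 0 and _take_step(K, y, alpha, E, i1, i2, C):
                    num_changed += 1
                    continue
                for j in range(n):
                    if j != i2 and _take_step(K, y, alpha, E, j, i2, C):
                        num_changed += 1
                        break
        if examine_all:
            examine_all = False
        elif num_changed == 0:
            examine_all = True
    # intercept
    nfree = 0
    bsum = 0.0
    for i in range(n):
        if tol < alpha[i] < C - tol:
            s = 0.0
            for j in range(n):
                s += alpha[j] * y[j] * K[i, j]
            bsum += y[i] - s
            nfree += 1
    if nfree > 0:
        b = bsum / nfree
    else:
        lo = -1e300
        hi = 1e300
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += alpha[j] * y[j] * K[i, j]
            g = y[i] - s
            on_lower = alpha[i] <= tol
            if (on_lower and y[i] > 0) or (not on_lower and y[i] < 0):
                if g > lo:
                    lo = g
            else:
                if g < hi:
                    hi = g
        b = (lo + hi) / 2.0
    return alpha, b


def svm_train(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              tol: float = 1e-10, max_iter: int = 1000):
    """Train a linear SVM; returns (w, b) of the decision function w·x + b."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    K = X @ X.T
    alpha, b = smo_solve(K, y, C, tol, max_iter)
    w = (alpha * y) @ X
    return w, float(b)


def svm_decision(w: np.ndarray, b: float, X: np.ndarray) -> np.ndarray:
    return X @ w + b


def one_vs_one_code(n_classes: int) -> np.ndarray:
    """±1/0 code matrix (classes × dichotomies) with one column per pair."""
    pairs = list(combinations(range(n_classes), 2))
    M = np.zeros((n_classes, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        M[i, col] = +1
        M[j, col] = -1
    return M


class EcocSvm:
    """Error-correcting output codes over binary linear SVMs.

    Each code-matrix column defines a dichotomy; prediction picks the class
    whose code row has minimal Hamming distance to the signs of the binary
    decision values (ties to the lowest class index). With two classes the
    default code matrix is a single column, i.e. one plain binary SVM.
    """

    def __init__(self, C: float = 1.0, code_matrix: np.ndarray | None = None):
        self.C = C
        self.code_matrix = code_matrix
        self.models_: list[tuple[np.ndarray, float]] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EcocSvm":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        M = self.code_matrix if self.code_matrix is not None else one_vs_one_code(k)
        if M.shape[0] != k:
            raise ValueError("code matrix rows must match class count")
        self._M = M
        class_index = {c: i for i, c in enumerate(self.classes_)}
        codes = np.array([M[class_index[c]] for c in y])
        self.models_ = []
        for col in range(M.shape[1]):
            sel = codes[:, col] != 0
            self.models_.append(svm_train(X[sel], codes[sel, col], C=self.C))
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([svm_decision(w, b, X) for w, b in self.models_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = np.sign(self.decision_values(X))
        s[s == 0] = 1.0
        # Hamming distance to each class's code row (zero entries ignored)
        M = self._M
        dist = ((M[None, :, :] != 0) & (M[None, :, :] != s[:, None, :])).sum(axis=2)
        return self.classes_[np.argmin(dist, axis=1)]


@njit(cache=True)
def decode_timepoints_binary(train, test, C):
    """Per-timepoint binary decoding of averaged-set exemplars.

    ``train``: (T, 4, E) — two averaged sets per class, class 0 first;
    ``test``:  (T, 2, E) — the held-out set of each class.
    Features are z-scored per electrode with training-set statistics. Returns
    predictions (T, 2) in {0, 1}.
    """
    T, n_train, E = train.shape
    y = np.empty(n_train)
    half = n_train // 2
    for i in range(n_train):
        y[i] = 1.0 if i < half else -1.0  # class 0 -> +1, class 1 -> -1
    pred = np.zeros((T, 2), dtype=np.uint8)
    Xtr = np.empty((n_train, E))
    Xte = np.empty((2, E))
    for t in range(T):
        for e in range(E):
            m = 0.0
            for i in range(n_train):
                m += train[t, i, e]
            m /= n_train
            v = 0.0
            for i in range(n_train):
                d = train[t, i, e] - m
                v += d * d
            sd = np.sqrt(v / n_train)
            if sd < 1e-12:
                sd = 1.0
            for i in range(n_train):
                Xtr[i, e] = (train[t, i, e] - m) / sd
            for i in range(2):
                Xte[i, e] = (test[t, i, e] - m) / sd
        K = Xtr @ Xtr.T
        alpha, b = smo_solve(K, y, C, 1e-10, 1000)
        for i in range(2):
            s = b
            for j in range(n_train):
                if alpha[j] > 0.0:
                    dot = 0.0
                    for e in range(E):
                        dot += Xtr[j, e] * Xte[i, e]
                    s += alpha[j] * y[j] * dot
            pred[t, i] = 0 if s >= 0.0 else 1  # ties to class 0, as in EcocSvm
    return pred
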