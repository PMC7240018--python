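"""The pose classifier: a 10-10-6-4 multilayer perceptron.

Architecture: an input layer of one unit per selected feature, two
tanh hidden layers (10 then 6 units), and a 4-unit softmax output
producing class-membership probabilities.  Training minimizes the
sum-of-squared-errors between softmax outputs and one-hot targets with
the Levenberg-Marquardt (LM) algorithm — damped Gauss-Newton steps

    (JᵀJ + λI) δ = −Jᵀr

on the residual vector r = output − target, with the damping λ divided
by ``lambda_down`` on an accepted (loss-reducing) step and multiplied by
``lambda_up`` otherwise.  A cross-entropy + L-BFGS alternative is
available for large training sets where the O(n·weights) Jacobian is
prohibitive.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba``) and composes with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConvergenceError

DEFAULT_HIDDEN = (10, 6)


@dataclass
class TrainConfig:
    """Training and evaluation-protocol settings.

    ``max_epochs`` caps LM iterations (accepted or not); ``k_folds`` and
    ``n_simulations`` set the cross-validation and repeated-simulation
    protocol sizes.  The λ schedule follows the common LM convention.
    """

    max_epochs: int = 1000
    k_folds: int = 10
    n_simulations: int = 50
    seed: int = 0
    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    lambda_max: float = 1e10
    grad_tol: float = 1e-7
    ftol: float = 1e-10
    loss: str = "sse"
    hidden: tuple[int, int] = field(default=DEFAULT_HIDDEN)

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.lambda_init <= 0:
            raise ValueError("lambda_init must be positive")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Net:
    """Weight bookkeeping for the fixed three-layer topology."""

    def __init__(self, n_in: int, hidden: tuple[int, int], n_out: int):
        h1, h2 = hidden
        self.shapes = [(h1, n_in), (h1,), (h2, h1), (h2,), (n_out, h2), (n_out,)]
        self.sizes = [int(np.prod(s)) for s in self.shapes]
        self.n_params = sum(self.sizes)
        self.n_in, self.h1, self.h2, self.n_out = n_in, h1, h2, n_out

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform [−0.5, 0.5] weights scaled by 1/sqrt(fan-in); zero biases."""
        parts = []
        for shape in self.shapes:
            if len(shape) == 2:
                fan_in = shape[1]
                parts.append(rng.uniform(-0.5, 0.5, size=shape).ravel() / np.sqrt(fan_in))
            else:
                parts.append(np.zeros(shape))
        return np.concatenate(parts)

    def unpack(self, params: np.ndarray):
        out, i = [], 0
        for shape, size in zip(self.shapes, self.sizes):
            out.append(params[i:i + size].reshape(shape))
            i += size
        return out  # W1, b1, W2, b2, W3, b3

    def forward(self, params: np.ndarray, X: np.ndarray):
        W1, b1, W2, b2, W3, b3 = self.unpack(params)
        A1 = np.tanh(X @ W1.T + b1)
        A2 = np.tanh(A1 @ W2.T + b2)
        P = _softmax(A2 @ W3.T + b3)
        return P, A1, A2

    def jacobian(self, params: np.ndarray, X: np.ndarray):
        """Residual Jacobian ∂p/∂w, shape (n, n_out, n_params).

        Uses the softmax differential S = diag(p) − p pᵀ and backpropagates
        it through the tanh layers; fully vectorized over samples.
        """
        W1, b1, W2, b2, W3, b3 = self.unpack(params)
        P, A1, A2 = self.forward(params, X)
        n = X.shape[0]
        S = -P[:, :, None] * P[:, None, :]
        ii = np.arange(self.n_out)
        S[:, ii, ii] += P
        G2 = np.einsum("nij,jk->nik", S, W3) * (1.0 - A2 ** 2)[:, None, :]
        G1 = np.einsum("nij,jk->nik", G2, W2) * (1.0 - A1 ** 2)[:, None, :]
        J = np.empty((n, self.n_out, self.n_params))
        i = 0
        for G, act, width in ((G1, X, self.n_in), (G2, A1, self.h1), (S, A2, self.h2)):
            h = G.shape[2]
            J[:, :, i:i + h * width] = np.einsum(
                "nij,nk->nijk", G, act).reshape(n, self.n_out, h * width)
            i += h * width
            J[:, :, i:i + h] = G
            i += h
        return J, P


def train_lm(net: _Net, params: np.ndarray, X: np.ndarray, T: np.ndarray,
             config: TrainConfig):
    """Levenberg-Marquardt on SSE between softmax outputs and one-hot T.

    Returns ``(params, loss_history)`` where the history records the loss
    after every accepted step (non-increasing by construction).  Raises
    :class:`ConvergenceError` (carrying the last params) if λ saturates
    with singular normal equations.
    """
    lam = config.lambda_init
    P, _, _ = net.forward(params, X)
    loss = 0.5 * np.sum((P - T) ** 2)
    history = [loss]
    eye = np.eye(net.n_params)
    for _ in range(config.max_epochs):
        J, P = net.jacobian(params, X)
        r = (P - T).reshape(-1)
        Jf = J.reshape(-1, net.n_params)
        g = Jf.T @ r
        gnorm = np.linalg.norm(g, ord=np.inf)
        if gnorm < config.grad_tol:
            break
        JtJ = Jf.T @ Jf
        accepted = False
        while lam <= config.lambda_max:
            try:
                delta = np.linalg.solve(JtJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            trial = params + delta
            P_trial, _, _ = net.forward(trial, X)
            trial_loss = 0.5 * np.sum((P_trial - T) ** 2)
            if trial_loss < loss:
                params, loss = trial, trial_loss
                lam = max(lam * config.lambda_down, 1e-20)
                history.append(loss)
                accepted = True
                break
            lam *= config.lambda_up
        if not accepted:
            if lam > config.lambda_max and len(history) > 1:
                break  # λ saturated after progress: converged to a minimum
            raise ConvergenceError(
                "LM damping saturated with no accepted step", model=params)
        if len(history) > 2 and history[-2] - history[-1] < config.ftol * max(1.0, history[-1]):
            break
    return params, np.asarray(history)


class PoseMLPClassifier(ClassifierMixin, BaseEstimator):
    """Two-hidden-layer softmax MLP trained by Levenberg-Marquardt.

    Parameters
    ----------
    hidden : (int, int), default=(10, 6)
        Hidden layer widths (tanh activations).
    loss : {"sse", "cross_entropy"}, default="sse"
        "sse" pairs LM with a sum-of-squared-errors objective;
        "cross_entropy" uses L-BFGS on the log loss instead.
    max_epochs : int, default=1000
        Iteration cap for either optimizer.
    lambda_init, lambda_up, lambda_down, lambda_max : float
        LM damping schedule.
    grad_tol, ftol : float
        Stopping tolerances: infinity-norm of the gradient, and relative
        loss improvement between accepted steps.
    random_state : int or None
        Seeds the weight initialization.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in fit.
    params_ : ndarray
        Flat weight vector (W1, b1, W2, b2, W3, b3).
    loss_curve_ : ndarray
        Loss after each accepted optimizer step.
    """

    def __init__(self, hidden=DEFAULT_HIDDEN, loss="sse", max_epochs=1000,
                 lambda_init=1e-3, lambda_up=10.0, lambda_down=0.1,
                 lambda_max=1e10, grad_tol=1e-7, ftol=1e-10, random_state=None):
        self.hidden = hidden
        self.loss = loss
        self.max_epochs = max_epochs
        self.lambda_init = lambda_init
        self.lambda_up = lambda_up
        self.lambda_down = lambda_down
        self.lambda_max = lambda_max
        self.grad_tol = grad_tol
        self.ftol = ftol
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(max_epochs=self.max_epochs, lambda_init=self.lambda_init,
                           lambda_up=self.lambda_up, lambda_down=self.lambda_down,
                           lambda_max=self.lambda_max, grad_tol=self.grad_tol,
                           ftol=self.ftol, loss=self.loss, hidden=tuple(self.hidden))

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least 2 classes")
        T = np.eye(len(self.classes_))[y_idx]
        net = _Net(X.shape[1], tuple(self.hidden), len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        params = net.init_params(rng)
        if self.loss == "sse":
            params, history = train_lm(net, params, X, T, self._config())
        elif self.loss == "cross_entropy":
            params, history = self._fit_lbfgs(net, params, X, T)
        else:
            raise ValueError(f"unknown loss {self.loss!r}")
        self._net = net
        self.params_ = params
        self.loss_curve_ = np.asarray(history)
        self.n_iter_ = len(self.loss_curve_) - 1
        return self

    def _fit_lbfgs(self, net, params, X, T):
        history = []

        def objective(p):
            P, A1, A2 = net.forward(p, X)
            eps = 1e-12
            loss = -np.sum(T * np.log(P + eps)) / len(X)
            # softmax + cross-entropy: output delta is simply (P − T)/n
            D3 = (P - T) / len(X)
            W1, b1, W2, b2, W3, b3 = net.unpack(p)
            D2 = (D3 @ W3) * (1 - A2 ** 2)
            D1 = (D2 @ W2) * (1 - A1 ** 2)
            grads = [D1.T @ X, D1.sum(0), D2.T @ A1, D2.sum(0), D3.T @ A2, D3.sum(0)]
            history.append(loss)
            return loss, np.concatenate([g.ravel() for g in grads])

        res = minimize(objective, params, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_epochs, "gtol": self.grad_tol})
        return res.x, np.asarray(history)

    def decision_function(self, X):
        return self.predict_proba(X)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        P, _, _ = self._net.forward(self.params_, X)
        return P

    def predict(self, X):
        """Argmax class with lowest-class-index tie-break."""
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]


def init_model(n_inputs: int = 10, hidden=DEFAULT_HIDDEN, n_outputs: int = 4,
               seed: int | None = None):
    """Seeded weight initialization; returns ``(net, params)``."""
    net = _Net(n_inputs, tuple(hidden), n_outputs)
    return net, net.init_params(np.random.default_rng(seed))


def forward(net: _Net, params: np.ndarray, X) -> np.ndarray:
    """Class probabilities for rows of X (sums to 1 per row)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P, _, _ = net.forward(params, X)
    return P


def cross_validate(X, y, config: TrainConfig):
    """Stratified k-fold cross-validation, then a full-data refit.

    Returns ``(fold_reports, final_model)`` where each report is an
    :class:`~skelpose.evaluation.EvalReport` on that fold's held-out
    rows and ``final_model`` is retrained on the whole training set.
    """
    from .evaluation import evaluate_predictions

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=config.seed)
    reports = []
    for i, (tr, va) in enumerate(skf.split(X, y)):
        clf = PoseMLPClassifier(hidden=config.hidden, loss=config.loss,
                                max_epochs=config.max_epochs,
                                lambda_init=config.lambda_init,
                                grad_tol=config.grad_tol, ftol=config.ftol,
                                random_state=config.seed + i)
        clf.fit(X[tr], y[tr])
        reports.append(evaluate_predictions(y[va], clf.predict(X[va]),
                                            clf.predict_proba(X[va]),
                                            classes=clf.classes_))
    final = PoseMLPClassifier(hidden=config.hidden, loss=config.loss,
                              max_epochs=config.max_epochs,
                              lambda_init=config.lambda_init,
                              grad_tol=config.grad_tol, ftol=config.ftol,
                              random_state=config.seed)
    final.fit(X, y)
    return reports, final


def repeated_simulations(X_train, y_train, X_test, y_test, config: TrainConfig):
    """Train/evaluate ``config.n_simulations`` independently-initialized nets.

    Each simulation reuses the full training set with initialization seed
    ``config.seed + i`` and is scored on the fixed test set.  Individual
    training failures are recorded, not fatal.

    Returns ``(reports, failures)``.
    """
    from .evaluation import evaluate_predictions

    reports, failures = [], []
    for i in range(config.n_simulations):
        clf = PoseMLPClassifier(hidden=config.hidden, loss=config.loss,
                                max_epochs=config.max_epochs,
                                lambda_init=config.lambda_init,
                                grad_tol=config.grad_tol, ftol=config.ftol,
                                random_state=config.seed + i)
        try:
            clf.fit(X_train, y_train)
        except ConvergenceError as exc:
            failures.append((i, str(exc)))
            continue
        reports.append(evaluate_predictions(y_test, clf.predict(X_test),
                                            clf.predict_proba(X_test),
                                            classes=clf.classes_))
    return reports, failures
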