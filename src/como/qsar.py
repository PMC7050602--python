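"""Ridge regression and Tanimoto-kernel SVR with double cross-validation.

Analogs are represented by extended-connectivity fingerprints (bond diameter
4, folded to 1024 bits).  Model selection follows a double cross-validation
protocol: the series is repeatedly split into 80% training/test and 20%
external validation; hyperparameters are chosen by internal five-fold CV on
the 80% and the refit model predicts the external 20%.  External predictions
are averaged per compound over all trials, and model quality is the
coefficient of determination R^2 = 1 - RSS/TSS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from como.chem import Analog, AnalogSeries, mol_from_smiles

logger = logging.getLogger(__name__)

FP_BITS = 1024
FP_RADIUS = 2  # bond diameter 4


def featurize(analogs: Sequence[Analog], n_bits: int = FP_BITS) -> np.ndarray:
    """ECFP4-style binary fingerprints folded to ``n_bits``, one row per analog."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=n_bits)
    rows = np.zeros((len(analogs), n_bits), dtype=np.uint8)
    for i, analog in enumerate(analogs):
        try:
            mol = mol_from_smiles(analog.smiles)
        except ValueError as exc:
            raise ValueError(f"cannot featurize compound {analog.id}: {exc}") from exc
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return rows


def tanimoto_kernel(x: np.ndarray, y: Optional[np.ndarray] = None) -> np.ndarray:
    """Tanimoto similarity matrix |a AND b| / |a OR b| on binary vectors.

    Pairs of all-zero vectors get similarity 1 (degenerate convention).
    """
    xa = np.asarray(x, dtype=float)
    ya = xa if y is None else np.asarray(y, dtype=float)
    inter = xa @ ya.T
    nx = xa.sum(axis=1)
    ny = ya.sum(axis=1)
    union = nx[:, None] + ny[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return k


class RidgeModel:
    """Penalized least-squares linear model (ordinary LS when alpha = 0)."""

    def __init__(self, alpha: float):
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.alpha = alpha
        self._est = None
        self._const: Optional[float] = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RidgeModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) < 2:
            raise ValueError("need at least two training instances")
        if np.all(x == x[0]):
            logger.warning("degenerate features: falling back to intercept-only model")
            self._const = float(y.mean())
            return self
        self._est = (
            LinearRegression() if self.alpha == 0 else Ridge(alpha=self.alpha)
        )
        self._est.fit(x, y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        if self._est is None:
            return np.zeros(0)
        return self._est.coef_

    @property
    def intercept_(self) -> float:
        if self._est is None:
            return float(self._const)
        return float(self._est.intercept_)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._const is not None:
            return np.full(len(x), self._const)
        return self._est.predict(x)


class TanimotoSVR:
    """Epsilon-insensitive SVR with a precomputed Tanimoto kernel."""

    def __init__(self, c: float, eps: float):
        if c <= 0:
            raise ValueError("C must be > 0")
        if eps < 0:
            raise ValueError("eps must be >= 0")
        self.c = c
        self.eps = eps
        self._svr = SVR(kernel="precomputed", C=c, epsilon=eps)
        self._x_train: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "TanimotoSVR":
        self._x_train = np.asarray(x, dtype=float)
        gram = tanimoto_kernel(self._x_train)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._svr.fit(gram, np.asarray(y, dtype=float))
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._x_train is None:
            raise RuntimeError("model is not fitted")
        return self._svr.predict(tanimoto_kernel(np.asarray(x, dtype=float), self._x_train))

    @property
    def dual_coef(self) -> np.ndarray:
        return self._svr.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self._svr.intercept_[0])

    @property
    def support_(self) -> np.ndarray:
        return self._svr.support_


def fit_rr(x: np.ndarray, y: np.ndarray, alpha: float) -> RidgeModel:
    return RidgeModel(alpha).fit(x, y)


def fit_svr(x: np.ndarray, y: np.ndarray, c: float, eps: float) -> TanimotoSVR:
    return TanimotoSVR(c, eps).fit(x, y)


def r_squared(true: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination R^2 = 1 - RSS/TSS (may be negative)."""
    y = np.asarray(true, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError("true and predicted must be equal-length 1D sequences")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("zero variance in true values")
    rss = float(((y - f) ** 2).sum())
    return 1.0 - rss / tss


@dataclass
class CVProtocol:
    """Double cross-validation protocol parameters."""

    n_trials: int = 35
    external_fraction: float = 0.2
    internal_folds: int = 5
    seed: int = 0
    rr_alpha_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 7))
    svr_c_grid: tuple[float, ...] = tuple(np.logspace(-4, 5, 18))
    svr_eps_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5)
    coverage_retry_budget: int = 50


@dataclass
class CVResult:
    """Accumulated external predictions and per-trial model quality."""

    model_kind: str
    compound_ids: list[str]
    mean_prediction: dict[str, float]
    n_external: dict[str, int]
    trial_r2: list[float]
    trial_seeds: list[int]
    uncovered_fw_eas: list[str] = field(default_factory=list)
    va_mean_prediction: dict[str, float] = field(default_factory=dict)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.trial_r2))


def _draw_splits(
    n: int, protocol: CVProtocol, rng: np.random.Generator
) -> list[np.ndarray]:
    n_ext = max(1, int(round(protocol.external_fraction * n)))
    return [rng.permutation(n)[:n_ext] for _ in range(protocol.n_trials)]


def _splits_with_coverage(
    n: int,
    protocol: CVProtocol,
    fw_idx: set[int],
) -> tuple[list[np.ndarray], list[str]]:
    """Trial external sets; repaired until every FW EA is external once.

    Uncovered FW EAs are swapped into a random trial's external set in place
    of a compound that is external in at least one other trial, keeping set
    sizes and the 80/20 proportion intact.
    """
    rng = np.random.default_rng(protocol.seed)
    splits = _draw_splits(n, protocol, rng)
    for _ in range(protocol.coverage_retry_budget):
        counts = np.zeros(n, dtype=int)
        for ext in splits:
            counts[ext] += 1
        uncovered = sorted(i for i in fw_idx if counts[i] == 0)
        if not uncovered:
            return splits, []
        for c in uncovered:
            for t in rng.permutation(len(splits)):
                ext = splits[t]
                swappable = [j for j, idx in enumerate(ext) if counts[idx] >= 2]
                if swappable:
                    j = swappable[int(rng.integers(len(swappable)))]
                    counts[ext[j]] -= 1
                    ext[j] = c
                    counts[c] += 1
                    break
    counts = np.zeros(n, dtype=int)
    for ext in splits:
        counts[ext] += 1
    return splits, sorted(str(i) for i in fw_idx if counts[i] == 0)


def _internal_grid_search(
    x: np.ndarray,
    y: np.ndarray,
    protocol: CVProtocol,
    model_kind: str,
    trial_seed: int,
) -> tuple:
    """Pick hyperparameters by mean fold R^2; ties -> stronger regularization."""
    if model_kind == "rr":
        grid = [(a,) for a in protocol.rr_alpha_grid]
        # larger alpha = stronger regularization; iterate descending so the
        # strictly-greater comparison keeps the stronger choice on ties
        grid = sorted(grid, key=lambda g: -g[0])
    elif model_kind == "svr":
        grid = [
            (c, e) for c in protocol.svr_c_grid for e in protocol.svr_eps_grid
        ]
        grid = sorted(grid, key=lambda g: (g[0], -g[1]))
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    kf = KFold(
        n_splits=protocol.internal_folds, shuffle=True, random_state=trial_seed % (2**32)
    )
    folds = list(kf.split(x))
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, te in folds:
            model = (
                fit_rr(x[tr], y[tr], params[0])
                if model_kind == "rr"
                else fit_svr(x[tr], y[tr], *params)
            )
            pred = model.predict(x[te])
            if np.var(y[te]) == 0:
                scores.append(-float(((y[te] - pred) ** 2).mean()))
            else:
                scores.append(r_squared(y[te], pred))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def run_double_cv(
    series: AnalogSeries,
    protocol: CVProtocol,
    model_kind: str,
    fw_ea_ids: Optional[Sequence[str]] = None,
    va_analogs: Optional[Sequence[Analog]] = None,
) -> CVResult:
    """Double (internal/external) cross-validation over one analog series.

    For each trial, a random 20% external set is held out, hyperparameters
    are selected by internal five-fold CV on the remaining 80%, the model is
    refit and external compounds are predicted.  Per-compound predictions are
    averaged over all trials in which the compound was external.  When
    ``fw_ea_ids`` is given, splits are resampled (within a retry budget)
    until each of these compounds is external at least once.  Optional
    ``va_analogs`` are predicted by every trial model and averaged.
    """
    members = [a for a in series.members if a.potency is not None]
    n = len(members)
    if n < 25:
        raise ValueError("series too small for the 80/20 + 5-fold protocol (need >= 25)")
    ids = [a.id for a in members]
    x = featurize(members)
    y = np.array([a.potency for a in members])

    fw_idx = {ids.index(i) for i in (fw_ea_ids or []) if i in ids}
    splits, uncovered = _splits_with_coverage(n, protocol, fw_idx)
    if uncovered:
        uncovered_ids = [ids[int(i)] for i in uncovered]
        logger.warning(
            "FW EA coverage constraint unsatisfied for: %s", uncovered_ids
        )
    else:
        uncovered_ids = []

    va_x = featurize(list(va_analogs)) if va_analogs else None
    va_sum = np.zeros(va_x.shape[0]) if va_x is not None else None

    seed_rng = np.random.default_rng(protocol.seed + 1)
    trial_seeds = [int(seed_rng.integers(2**31)) for _ in range(len(splits))]

    pred_sum = {i: 0.0 for i in ids}
    pred_n = {i: 0 for i in ids}
    trial_r2: list[float] = []
    for ext_idx, trial_seed in zip(splits, trial_seeds):
        mask = np.zeros(n, dtype=bool)
        mask[ext_idx] = True
        x_tr, y_tr = x[~mask], y[~mask]
        x_ext, y_ext = x[mask], y[mask]
        params = _internal_grid_search(x_tr, y_tr, protocol, model_kind, trial_seed)
        model = (
            fit_rr(x_tr, y_tr, params[0])
            if model_kind == "rr"
            else fit_svr(x_tr, y_tr, *params)
        )
        pred = model.predict(x_ext)
        for j, p in zip(np.where(mask)[0], pred):
            pred_sum[ids[j]] += float(p)
            pred_n[ids[j]] += 1
        trial_r2.append(r_squared(y_ext, pred))
        if va_x is not None:
            va_sum += model.predict(va_x)

    mean_prediction = {
        i: pred_sum[i] / pred_n[i] for i in ids if pred_n[i] > 0
    }
    va_mean = (
        {
            a.id: float(s / len(splits))
            for a, s in zip(va_analogs, va_sum)
        }
        if va_x is not None
        else {}
    )
    return CVResult(
        model_kind=model_kind,
        compound_ids=ids,
        mean_prediction=mean_prediction,
        n_external=pred_n,
        trial_r2=trial_r2,
        trial_seeds=trial_seeds,
        uncovered_fw_eas=uncovered_ids,
        va_mean_prediction=va_mean,
    )
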