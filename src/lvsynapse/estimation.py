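"""Least-squares training of Laguerre–Volterra models and accuracy metrics.

Coefficients solve ``y = V c`` in the least-squares sense, where V has one
column per term of the series (a constant column first, then the
element-wise products of basis convolutions for every term). Small problems
are solved directly with the pseudoinverse (:func:`fit_coefficients`); the
full training pipeline accumulates the normal equations in chunks (no
multi-million-row design matrix in memory) and solves them with column
scaling and a documented spectral truncation — the high-order product
columns are strongly collinear, and the truncation is what makes the fitted
series generalize to novel input trains.

The two decay constants (fast and slow basis set) are optimized by a
deterministic log-grid search with golden-section refinement on the summed
absolute training error, refitting the coefficients at every candidate.

Accuracy is quantified with the normalized root-mean-square error

    NRMSE = sqrt( sum (y - y_hat)^2 / sum y^2 ),

with the baseline at zero, plus an event-windowed variant that scores each
event's (or merged event cluster's) response segment separately, and a
frequency-sweep protocol that scores a fitted model against its oracle on
fresh Poisson trains across mean rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .events import (BinnedSignal, EventTrain, bin_events,
                     generate_poisson_rit, generate_poisson_rit_for_duration,
                     concatenate_hybrid)
from .laguerre import build_basis, convolve_basis
from .volterra import VolterraModel, enumerate_terms, predict

__all__ = [
    "build_design_matrix", "fit_coefficients", "nrmse",
    "event_windowed_nrmse", "frequency_sweep", "optimize_decays",
    "train_receptor_model", "TrainingRecord", "TrainingProtocol",
    "FitResult", "LaguerreVolterraRegressor",
]


# ---------------------------------------------------------------------------
# Design matrix and direct least squares
# ---------------------------------------------------------------------------

def _term_columns(term_index, v, sl: slice) -> np.ndarray:
    """Design-matrix block for a bin range: (1 + n_terms, width).

    Row 0 is the constant column; row 1+i is the element-wise product of
    the basis convolutions named by term i.
    """
    width = v[0][:, sl].shape[1]
    C = np.empty((1 + len(term_index), width))
    C[0] = 1.0
    for i, term in enumerate(term_index):
        n0, j0 = term[0]
        col = v[n0][j0, sl].copy()
        for n, j in term[1:]:
            col *= v[n][j, sl]
        C[1 + i] = col
    return C


def build_design_matrix(term_index, v) -> np.ndarray:
    """Full design matrix, one row per time bin, constant column first.

    ``v`` is a list with one ``(L, T)`` array of basis convolutions per
    basis set; every (set, function) pair referenced by a term must exist.
    """
    for term in term_index:
        for n, j in term:
            if n >= len(v) or j >= v[n].shape[0]:
                raise ValueError(
                    f"term references basis series ({n},{j}) that was not "
                    "provided")
    return _term_columns(term_index, v, slice(None)).T


def fit_coefficients(V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares coefficients of ``y = V c``.

    Solved via the pseudoinverse (singular values below
    ``max(V.shape) * eps * sigma_max`` are dropped); deterministic. The
    first entry is the constant c0 when V was built by
    :func:`build_design_matrix`.
    """
    V = np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float)
    if V.size == 0 or y.size == 0:
        raise ValueError("empty design matrix or target")
    if V.shape[0] != y.shape[0]:
        raise ValueError("design matrix rows must match target length")
    c, *_ = np.linalg.lstsq(V, y, rcond=None)
    return c


def _solve_normal(G: np.ndarray, b: np.ndarray,
                  cutoff: float = 1e-8) -> np.ndarray:
    """Regularized minimum-norm solution from accumulated normal equations.

    Columns are scaled to unit RMS, the scaled Gram matrix is
    eigendecomposed, and eigenvalues below ``cutoff`` times the largest are
    truncated (equivalent to dropping design-matrix singular values below
    ``sqrt(cutoff)`` of the largest, after column scaling). High-order
    product columns are strongly collinear, so a documented truncation well
    above machine precision is required for the solution to generalize off
    the training train; for exactly degenerate directions (e.g. duplicated
    columns) this reduces to the minimum-norm pseudoinverse solution.
    """
    s = np.sqrt(np.diag(G) / max(G.shape[0], 1))
    s[s == 0] = 1.0
    Gs = G / np.outer(s, s)
    bs = b / s
    w, U = np.linalg.eigh(Gs)
    keep = w > cutoff * w.max()
    return (U[:, keep] @ ((U[:, keep].T @ bs) / w[keep])) / s


def _chunked_normal_equations(term_index, v, y, chunk: int):
    n = 1 + len(term_index)
    G = np.zeros((n, n))
    b = np.zeros(n)
    T = y.shape[0]
    for a in range(0, T, chunk):
        sl = slice(a, min(a + chunk, T))
        C = _term_columns(term_index, v, sl)
        G += C @ C.T
        b += C @ y[sl]
    return G, b


def _chunked_abs_error(term_index, v, y, c, chunk: int) -> float:
    err = 0.0
    T = y.shape[0]
    for a in range(0, T, chunk):
        sl = slice(a, min(a + chunk, T))
        C = _term_columns(term_index, v, sl)
        err += float(np.abs(y[sl] - c @ C).sum())
    return err


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def _values(y) -> np.ndarray:
    return y.values if isinstance(y, BinnedSignal) else np.asarray(y, float)


def nrmse(y, y_hat) -> float:
    """Normalized RMSE: sqrt(sum (y - y_hat)^2 / sum y^2), baseline 0."""
    y = _values(y)
    y_hat = _values(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("series must have equal length")
    denom = float(np.sum(y * y))
    if denom == 0.0:
        raise ValueError("NRMSE undefined for an all-zero reference")
    return float(np.sqrt(np.sum((y - y_hat) ** 2) / denom))


def event_windowed_nrmse(y: BinnedSignal, y_hat: BinnedSignal,
                         events: EventTrain, window: float) -> pd.DataFrame:
    """Per-event NRMSE over each event's response segment.

    Events closer together than ``window`` are merged into one cluster (a
    paired response is scored as a single row). A cluster's segment runs
    from its first event to the earlier of (last event + window) and the
    next cluster's start.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = events.times
    rows = []
    if times.size == 0:
        return pd.DataFrame(columns=["events", "t_start", "t_end", "nrmse"])
    # cluster events with gaps < window
    breaks = np.flatnonzero(np.diff(times) >= window) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [times.size]])
    yv, yh, dt = y.values, y_hat.values, y.dt
    for gi, (a, b) in enumerate(zip(starts, stops)):
        t_start = times[a]
        t_end = times[b - 1] + window
        if gi + 1 < starts.size:
            t_end = min(t_end, times[starts[gi + 1]])
        k0 = int(np.floor(t_start / dt))
        k1 = min(int(np.ceil(t_end / dt)), yv.size)
        rows.append({
            "events": f"{a + 1}" if b - a == 1 else f"{a + 1}-{b}",
            "t_start": float(t_start),
            "t_end": float(t_end),
            "nrmse": nrmse(yv[k0:k1], yh[k0:k1]),
        })
    return pd.DataFrame(rows)


def frequency_sweep(model, oracle, rates, duration: float = 20.0,
                    seed: int = 0, dt: float | None = None) -> pd.DataFrame:
    """Validate a fitted model against its oracle across mean input rates.

    For each rate a fresh Poisson train of the given duration is generated
    (sub-seeds derived deterministically from ``seed``), the oracle and the
    model are run on the identical train, and the NRMSE is reported.
    """
    if any(r <= 0 for r in rates):
        raise ValueError("rates must be positive")
    if dt is None:
        dt = model.dt
    if isinstance(oracle, VolterraModel):
        ref = oracle
        oracle_response = lambda tr, d, n: predict(
            ref, bin_events(tr, d, n_bins=n))
    else:
        oracle_response = lambda tr, d, n: oracle.response(tr, d, n_bins=n)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=len(rates))
    rows = []
    for rate, s in zip(rates, sub):
        train = generate_poisson_rit_for_duration(rate, duration, int(s))
        n_bins = int(np.floor(duration / dt)) + 1
        y = oracle_response(train, dt, n_bins)
        y_hat = predict(model, bin_events(train, dt, n_bins=n_bins))
        rows.append({"rate_hz": float(rate), "n_events": train.n_events,
                     "nrmse": nrmse(y, y_hat)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scikit-learn style estimator
# ---------------------------------------------------------------------------

class LaguerreVolterraRegressor(RegressorMixin, BaseEstimator):
    """Laguerre-expanded Volterra series regressor for point-process inputs.

    Fits ``y(t) = c0 + sum c_term prod v_j^n(t)`` by (minimum-norm) least
    squares, where the ``v_j^n`` are Laguerre basis kernels of one or more
    decay sets convolved with the input impulse series. Optionally optimizes
    the decay constants by grid + golden-section search on the summed
    absolute training error.

    Parameters
    ----------
    order : int, default 3
        Volterra series order Q (1..4).
    n_functions : tuple of int, default (4, 4)
        Number of Laguerre functions per basis set.
    decays : tuple of float, default (0.5, 0.03)
        Decay constant per set (fast first); starting values when
        ``optimize_decays`` is enabled.
    decay_units : {"per_bin", "per_second"}, default "per_bin"
        Unit convention for the decay constants.
    cross_terms : bool, default False
        Pool basis functions across sets in the product terms.
    dt : float, default 1e-4
        Bin width of the input/target series, seconds.
    memory_window : float, default 2.0
        Kernel memory M_k, seconds.
    optimize_decays : bool, default False
        Search the decay constants before the final fit.
    decay_bounds : tuple of (lo, hi), optional
        Per-set search bounds; required when optimizing.
    decay_grid : int, default 4
        Log-grid points per axis in the coarse search.
    decay_tol : float, default 1e-3
        Relative golden-section tolerance per axis.
    decay_fit_bins : int or None
        Cap on the number of training bins used inside the decay search
        (the final coefficient fit always uses all bins).
    chunk_size : int, default 131072
        Rows per block in the chunked normal-equation accumulation.

    Attributes
    ----------
    model_ : VolterraModel
        The fitted series model.
    c0_ : float
    coef_ : ndarray of shape (n_terms,)
    decays_ : tuple of float
        Decay constants actually used.
    term_index_ : list
    train_abs_error_ : float
        Summed absolute training error (the decay-search objective).
    """

    def __init__(self, order=3, n_functions=(4, 4), decays=(0.5, 0.03),
                 decay_units="per_bin", cross_terms=False, dt=1e-4,
                 memory_window=2.0, optimize_decays=False, decay_bounds=None,
                 decay_grid=4, decay_tol=1e-3, decay_fit_bins=None,
                 gram_cutoff=1e-8, chunk_size=131072):
        self.order = order
        self.n_functions = n_functions
        self.decays = decays
        self.decay_units = decay_units
        self.cross_terms = cross_terms
        self.dt = dt
        self.memory_window = memory_window
        self.optimize_decays = optimize_decays
        self.decay_bounds = decay_bounds
        self.decay_grid = decay_grid
        self.decay_tol = decay_tol
        self.decay_fit_bins = decay_fit_bins
        self.gram_cutoff = gram_cutoff
        self.chunk_size = chunk_size

    # -- helpers -----------------------------------------------------------

    def _as_series(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single binned input series "
                                 "(shape (n_bins,) or (n_bins, 1))")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-D or a single column")
        return X

    def _bases(self, decays) -> list:
        return [build_basis(p, L, self.dt, self.memory_window,
                            p_units=self.decay_units)
                for p, L in zip(decays, self.n_functions)]

    def _fit_at(self, decays, x, y, n_bins_cap=None):
        """Fit coefficients at fixed decays; return (bases, c, abs_err)."""
        if n_bins_cap is not None and n_bins_cap < x.size:
            x = x[:n_bins_cap]
            y = y[:n_bins_cap]
        bases = self._bases(decays)
        sig = BinnedSignal(dt=self.dt, values=x)
        v = [convolve_basis(b, sig) for b in bases]
        terms = enumerate_terms(self.order, self.n_functions,
                                self.cross_terms)
        G, b = _chunked_normal_equations(terms, v, y, self.chunk_size)
        c = _solve_normal(G, b, self.gram_cutoff)
        err = _chunked_abs_error(terms, v, y, c, self.chunk_size)
        return bases, terms, c, err

    def _search_decays(self, x, y):
        """Deterministic log-grid + golden-section search per axis."""
        bounds = self.decay_bounds
        if bounds is None:
            raise ValueError("decay_bounds are required when "
                             "optimize_decays=True")
        if len(bounds) != len(self.n_functions):
            raise ValueError("one (lo, hi) bound pair per basis set")
        cap = self.decay_fit_bins

        def objective(ps):
            ps = tuple(ps)
            if any(ps[i] <= ps[i + 1] for i in range(len(ps) - 1)):
                return np.inf  # enforce strictly decreasing decays
            *_, err = self._fit_at(ps, x, y, n_bins_cap=cap)
            return err

        grids = [np.geomspace(lo, hi, self.decay_grid) for lo, hi in bounds]
        best, best_err = None, np.inf
        from itertools import product
        for ps in product(*grids):
            e = objective(ps)
            if e < best_err:
                best, best_err = list(ps), e
        if best is None:
            raise ValueError("decay bounds admit no candidate with "
                             "strictly decreasing decays")
        # coordinate-wise golden-section refinement around the grid optimum
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(2):
            for axis in range(len(best)):
                g = grids[axis]
                i = int(np.argmin(np.abs(g - best[axis])))
                lo = g[max(i - 1, 0)]
                hi = g[min(i + 1, g.size - 1)]
                if hi <= lo:
                    continue
                a, b_ = np.log(lo), np.log(hi)
                c1 = b_ - invphi * (b_ - a)
                c2 = a + invphi * (b_ - a)
                def f(logp, axis=axis):
                    trial = list(best)
                    trial[axis] = float(np.exp(logp))
                    return objective(trial)
                f1, f2 = f(c1), f(c2)
                while (b_ - a) > self.decay_tol:
                    if f1 < f2:
                        b_, c2, f2 = c2, c1, f1
                        c1 = b_ - invphi * (b_ - a)
                        f1 = f(c1)
                    else:
                        a, c1, f1 = c1, c2, f2
                        c2 = a + invphi * (b_ - a)
                        f2 = f(c2)
                cand = float(np.exp((a + b_) / 2.0))
                trial = list(best)
                trial[axis] = cand
                e = objective(trial)
                if e < best_err:
                    best, best_err = trial, e
        return tuple(best)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Fit the series to a binned input series and target series."""
        x = self._as_series(X)
        y = np.asarray(_values(y), dtype=float)
        if x.size != y.size:
            raise ValueError("input and target series must share the grid")
        if x.size == 0:
            raise ValueError("empty training data")
        decays = tuple(float(p) for p in self.decays)
        if self.optimize_decays:
            decays = self._search_decays(x, y)
        bases, terms, c, err = self._fit_at(decays, x, y)
        self.decays_ = decays
        self.term_index_ = terms
        self.c0_ = float(c[0])
        self.coef_ = c[1:]
        self.train_abs_error_ = err
        self.n_terms_ = len(terms)
        self.model_ = VolterraModel(order=self.order, bases=bases,
                                    cross_terms=self.cross_terms,
                                    term_index=terms, c0=self.c0_,
                                    coefficients=self.coef_)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        x = self._as_series(X)
        sig = BinnedSignal(dt=self.dt, values=x)
        return predict(self.model_, sig).values


# ---------------------------------------------------------------------------
# Training-protocol plumbing
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecord:
    """One input/target pair for coefficient estimation."""

    inputs: EventTrain
    target: BinnedSignal
    dt: float
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.dt, self.target.dt, rtol=1e-9, atol=0.0):
            raise ValueError("record dt must match the target's bin width")
        if self.target.duration + self.dt < self.inputs.duration:
            raise ValueError("target grid must span the input train")


@dataclass
class TrainingProtocol:
    """End-to-end training configuration.

    ``rates`` lists the mean rates of the (possibly hybrid) training train;
    ``n_events`` is the total event count, split evenly across rates (e.g.
    rates (2, 10) with 1000 events gives a 500-event 2 Hz segment followed
    by a 500-event 10 Hz segment). Validation always uses a fresh train.
    """

    rates: tuple = (2.0,)
    n_events: int = 1000
    dt: float = 1e-4
    order: int = 3
    n_functions: tuple = (4, 4)
    cross_terms: bool = False
    seed: int = 0
    memory_window: float = 2.0
    decays: tuple = (0.5, 0.03)
    decay_units: str = "per_bin"
    optimize_decays: bool = True
    decay_bounds: tuple = ((0.02, 1.0), (0.0005, 0.05))
    decay_grid: int = 4
    decay_tol: float = 0.05
    decay_search_events: int | None = 150
    gram_cutoff: float = 1e-8
    validation_rate: float = 2.0
    validation_duration: float = 20.0
    oracle_method: str = "expm"

    def describe(self) -> dict:
        d = asdict(self)
        for k, val in d.items():
            if isinstance(val, tuple):
                d[k] = list(val)
        return d


@dataclass
class FitResult:
    """Outcome of a training run."""

    model: VolterraModel
    train_abs_error: float
    validation_nrmse: float
    decays: tuple
    protocol: dict = field(default_factory=dict)


def optimize_decays(record: TrainingRecord, n_functions, order: int,
                    cross_terms: bool, decay_bounds, decay_grid: int = 4,
                    decay_tol: float = 1e-3, decay_units: str = "per_bin",
                    memory_window: float = 2.0,
                    decay_fit_bins: int | None = None) -> FitResult:
    """Optimize the basis decay constants on a training record.

    Minimizes the summed absolute training error over (p_fast, p_slow, ...)
    with p's strictly decreasing across sets, refitting the coefficients at
    every candidate. Deterministic given the search specification. Returns
    a :class:`FitResult` whose validation NRMSE is computed on the training
    record itself (use :func:`train_receptor_model` for held-out
    validation).
    """
    for i in range(len(decay_bounds) - 1):
        if decay_bounds[i][0] <= decay_bounds[i + 1][0] and \
           decay_bounds[i][1] <= decay_bounds[i + 1][1]:
            raise ValueError("bounds must allow p_fast > p_slow ordering")
    est = LaguerreVolterraRegressor(
        order=order, n_functions=tuple(n_functions),
        decays=tuple(b[1] for b in decay_bounds), decay_units=decay_units,
        cross_terms=cross_terms, dt=record.dt, memory_window=memory_window,
        optimize_decays=True, decay_bounds=tuple(decay_bounds),
        decay_grid=decay_grid, decay_tol=decay_tol,
        decay_fit_bins=decay_fit_bins)
    x = bin_events(record.inputs, record.dt, n_bins=len(record.target))
    est.fit(x.values, record.target.values)
    val = nrmse(record.target.values, est.predict(x.values))
    return FitResult(model=est.model_, train_abs_error=est.train_abs_error_,
                     validation_nrmse=val, decays=est.decays_,
                     protocol=dict(record.protocol))


def _build_training_train(protocol: TrainingProtocol, rng,
                          per_rate: int | None = None) -> EventTrain:
    if per_rate is None:
        per_rate = protocol.n_events // len(protocol.rates)
    segs = [generate_poisson_rit(r, per_rate,
                                 int(rng.integers(0, 2 ** 31 - 1)))
            for r in protocol.rates]
    train = segs[0]
    for seg in segs[1:]:
        train = concatenate_hybrid(train, seg)
    return train


def _oracle_response(oracle, train, dt, n_bins, method):
    if isinstance(oracle, VolterraModel):
        return predict(oracle, bin_events(train, dt, n_bins=n_bins))
    return oracle.response(train, dt, n_bins=n_bins, method=method)


def train_receptor_model(oracle, protocol: TrainingProtocol) -> FitResult:
    """End-to-end reduction of a kinetic oracle to an IO model.

    Generates the training RIT, simulates the oracle, optimizes the decay
    constants (on a shorter train drawn from the same rate protocol, so
    every rate segment informs the search), fits the coefficients on the
    full training train, then validates on a *fresh* train of
    ``validation_duration`` seconds at ``validation_rate``. Bit-reproducible
    given the protocol seed.
    """
    rng = np.random.default_rng(protocol.seed)
    train = _build_training_train(protocol, rng)
    dt = protocol.dt
    n_bins = int(np.floor(train.duration / dt)) + 1
    y = _oracle_response(oracle, train, dt, n_bins, protocol.oracle_method)
    x = bin_events(train, dt, n_bins=n_bins)

    decays = protocol.decays
    if protocol.optimize_decays:
        if protocol.decay_search_events is not None:
            search_train = _build_training_train(
                protocol, rng, per_rate=protocol.decay_search_events)
        else:
            search_train = train
        sn = int(np.floor(search_train.duration / dt)) + 1
        ys = _oracle_response(oracle, search_train, dt, sn,
                              protocol.oracle_method)
        xs = bin_events(search_train, dt, n_bins=sn)
        search = LaguerreVolterraRegressor(
            order=protocol.order, n_functions=protocol.n_functions,
            decays=protocol.decays, decay_units=protocol.decay_units,
            cross_terms=protocol.cross_terms, dt=dt,
            memory_window=protocol.memory_window, optimize_decays=True,
            decay_bounds=protocol.decay_bounds,
            decay_grid=protocol.decay_grid, decay_tol=protocol.decay_tol,
            gram_cutoff=protocol.gram_cutoff)
        search.fit(xs.values, ys.values)
        decays = search.decays_

    est = LaguerreVolterraRegressor(
        order=protocol.order, n_functions=protocol.n_functions,
        decays=decays, decay_units=protocol.decay_units,
        cross_terms=protocol.cross_terms, dt=dt,
        memory_window=protocol.memory_window, optimize_decays=False,
        gram_cutoff=protocol.gram_cutoff)
    est.fit(x.values, y.values)

    # held-out validation on a novel train
    val_seed = int(rng.integers(0, 2 ** 31 - 1))
    val_train = generate_poisson_rit_for_duration(
        protocol.validation_rate, protocol.validation_duration, val_seed)
    vn = int(np.floor(protocol.validation_duration / dt)) + 1
    y_val = _oracle_response(oracle, val_train, dt, vn,
                             protocol.oracle_method)
    y_hat = predict(est.model_, bin_events(val_train, dt, n_bins=vn))
    return FitResult(model=est.model_,
                     train_abs_error=est.train_abs_error_,
                     validation_nrmse=nrmse(y_val, y_hat),
                     decays=est.decays_,
                     protocol=protocol.describe())
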