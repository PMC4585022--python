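"""The Volterra functional power series over Laguerre basis convolutions.

The model output is

    u(t) = c0 + sum_terms c_term * prod_{(n, j) in term} v_j^n(t),

where ``v_j^n(t)`` is the j-th Laguerre kernel of basis set ``n`` convolved
with the input. A *term* is a multiset of (set, function) pairs whose size is
the term's order; order-1 terms give the linear response, higher orders
capture interactions between input events (paired-pulse facilitation,
desensitization-driven depression, saturation).

Two product conventions are supported:

* ``cross_terms=False`` — every product stays within a single basis set
  (self-kernels only). A 3rd-order model with two sets of 4 functions has
  2*4 + 2*C(5,2) + 2*C(6,3) = 68 coefficients.
* ``cross_terms=True`` — products are multisets over the pooled functions of
  both sets, mixing decays at every order. A 4th-order model with two sets
  of 3 functions has C(6,1)+C(7,2)+C(8,3)+C(9,4) = 209 coefficients.

The constant c0 is stored separately and excluded from term counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .events import BinnedSignal, EventTrain, bin_index
from .laguerre import convolve_basis

__all__ = ["Term", "enumerate_terms", "VolterraModel", "predict",
           "predict_events", "active_events", "MAX_ORDER"]

MAX_ORDER = 4

# A term is a tuple of (set_id, function_id) pairs, sorted; the empty tuple
# would be the constant and never appears in a term index.
Term = tuple


def enumerate_terms(Q: int, L_per_set, cross_terms: bool) -> list[Term]:
    """Enumerate the canonical term index for a model.

    Parameters
    ----------
    Q : int
        Model order, 1..4.
    L_per_set : sequence of int
        Number of basis functions in each set.
    cross_terms : bool
        If True, products are multisets over the pooled functions of all
        sets; if False, every product draws from a single set.

    Returns
    -------
    list of terms, each a sorted tuple of (set_id, function_id) pairs.
    The ordering is canonical — by order, then lexicographically by the
    (set, function) pairs — and stable across runs, so coefficient files
    are portable. The constant term is excluded.
    """
    if not (1 <= Q <= MAX_ORDER):
        raise ValueError(f"unsupported model order {Q}; must be 1..{MAX_ORDER}")
    L_per_set = [int(L) for L in L_per_set]
    if any(L < 1 for L in L_per_set):
        raise ValueError("every basis set needs at least one function")
    terms: list[Term] = []
    if cross_terms:
        pooled = [(n, j) for n, L in enumerate(L_per_set) for j in range(L)]
        for q in range(1, Q + 1):
            terms.extend(combinations_with_replacement(pooled, q))
    else:
        for q in range(1, Q + 1):
            for n, L in enumerate(L_per_set):
                funcs = [(n, j) for j in range(L)]
                terms.extend(combinations_with_replacement(funcs, q))
            # re-sort within the order so ordering is (order, set, function)
        terms.sort(key=lambda t: (len(t), t))
    return terms


@dataclass
class VolterraModel:
    """A fitted (or hand-built) Laguerre–Volterra input–output model.

    Attributes
    ----------
    order : int
        Highest term order Q (1..4).
    bases : list of LaguerreBasis
        One entry per basis set; all must share dt and memory length.
    cross_terms : bool
        Product convention used by the term index.
    term_index : list of Term
        Canonical term enumeration (see :func:`enumerate_terms`).
    c0 : float
        Constant (baseline) coefficient.
    coefficients : ndarray
        One coefficient per term, aligned with ``term_index``.
    """

    order: int
    bases: list
    cross_terms: bool
    term_index: list
    c0: float
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (1 <= self.order <= MAX_ORDER):
            raise ValueError(f"unsupported model order {self.order}")
        if len(self.coefficients) != len(self.term_index):
            raise ValueError(
                "corrupt model: coefficient vector length "
                f"{len(self.coefficients)} does not match term index length "
                f"{len(self.term_index)}")
        if any(len(t) > self.order for t in self.term_index):
            raise ValueError("corrupt model: term order exceeds model order")
        dts = {b.dt for b in self.bases}
        if len(dts) != 1:
            raise ValueError("all basis sets must share the bin width")

    @property
    def dt(self) -> float:
        return self.bases[0].dt

    @property
    def memory_window(self) -> float:
        """Memory window M_k in seconds."""
        return max(b.window for b in self.bases)

    @property
    def L_per_set(self) -> list[int]:
        return [b.L for b in self.bases]


def _combine_terms(model: VolterraModel, v: list[np.ndarray]) -> np.ndarray:
    """u(t) from precomputed basis convolutions ``v[set][j]``."""
    T = v[0].shape[1]
    u = np.full(T, model.c0)
    for c, term in zip(model.coefficients, model.term_index):
        if c == 0.0:
            continue
        n0, j0 = term[0]
        prod = v[n0][j0].copy()
        for n, j in term[1:]:
            prod *= v[n][j]
        u += c * prod
    return u


def predict(model: VolterraModel, x: BinnedSignal) -> BinnedSignal:
    """Evaluate the series on a binned input via full convolution.

    Only input within the memory window contributes (the kernels have finite
    support M_k). An all-zero input yields the constant baseline c0.
    """
    model.validate()
    v = [convolve_basis(b, x) for b in model.bases]
    return BinnedSignal(dt=x.dt, values=_combine_terms(model, v), t0=x.t0)


def predict_events(model: VolterraModel, train: EventTrain,
                   n_bins: int | None = None) -> BinnedSignal:
    """Event-driven evaluation: kernel lookups summed over active events.

    Builds each ``v_j`` by scattering shifted kernel copies at the event
    bins (no FFT), then combines terms exactly as :func:`predict`. Agrees
    with the convolution path to numerical precision and is the natural
    path for sparse inputs.
    """
    model.validate()
    dt = model.dt
    if n_bins is None:
        n_bins = int(np.floor(train.duration / dt)) + 1
    event_bins = bin_index(train.times, dt)
    v = []
    for b in model.bases:
        vb = np.zeros((b.L, n_bins))
        for eb in event_bins:
            if eb >= n_bins:
                continue
            span = min(b.n_bins, n_bins - eb)
            vb[:, eb:eb + span] += b.kernels[:, :span]
        v.append(vb)
    return BinnedSignal(dt=dt, values=_combine_terms(model, v))


def active_events(train: EventTrain, t: float, M_k: float) -> EventTrain:
    """Events still inside the memory window at time ``t``.

    An event is active when its age ``t - t_event`` lies in ``[0, M_k]``
    (inclusive at both ends).
    """
    if M_k <= 0:
        raise ValueError("memory window must be positive")
    mask = (train.times <= t) & (t - train.times <= M_k)
    times = train.times[mask]
    return EventTrain(times=times, duration=train.duration)
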