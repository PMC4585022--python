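"""Laguerre polynomials and discretized Laguerre basis-function kernels.

The Volterra kernels are expanded over orthonormal Laguerre functions

    b_j(t) = sqrt(2p) * (-1)^j * L_j(2pt) * exp(-pt),

where ``L_j`` is the degree-j Laguerre polynomial and ``p`` sets the decay.
The first members are b0 = sqrt(2p) e^{-pt}, b1 = sqrt(2p)(2pt - 1) e^{-pt},
b2 = sqrt(2p)(2 p^2 t^2 - 4pt + 1) e^{-pt}. The family is orthonormal on
[0, inf): int b_i b_j dt = delta_ij. Two basis sets with distinct decay
constants are used in the receptor models — a fast set for the main response
waveform and a slow one for desensitization-scale dynamics.

The decay constant ``p`` is a bare number in the receptor-model literature;
here it can be interpreted either per time-bin of the discretization
(``p_units="per_bin"``, the default used by the trained models) or per
second (``p_units="per_second"``). Kernels are evaluated at bin centers
``tau = (k + 1/2) * dt`` so convolutions are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve

from .events import BinnedSignal

__all__ = ["laguerre_polynomial", "LaguerreBasis", "build_basis",
           "convolve_basis"]


def laguerre_polynomial(n: int, x):
    """Degree-``n`` Laguerre polynomial via the stable three-term recurrence.

    L_0 = 1, L_1 = 1 - x, (k+1) L_{k+1} = (2k + 1 - x) L_k - k L_{k-1}.
    Vectorized over ``x``. The recurrence (rather than the factorial /
    derivative form) keeps evaluation stable well beyond degree ~20.
    """
    if n < 0:
        raise ValueError("polynomial order must be non-negative")
    x = np.asarray(x, dtype=float)
    prev = np.ones_like(x)
    if n == 0:
        return prev if prev.shape else float(prev)
    cur = 1.0 - x
    for k in range(1, n):
        prev, cur = cur, ((2 * k + 1 - x) * cur - k * prev) / (k + 1)
    return cur if cur.shape else float(cur)


@dataclass(frozen=True)
class LaguerreBasis:
    """One set of discretized Laguerre basis kernels.

    Attributes
    ----------
    p : float
        Decay constant (per bin or per second, see ``p_units``).
    L : int
        Number of basis functions in the set.
    dt : float
        Bin width in seconds.
    n_bins : int
        Memory length M_k in bins; the kernels cover ages
        ``[0, n_bins * dt)``.
    kernels : ndarray, shape (L, n_bins)
        ``kernels[j, k] = b_j((k + 1/2) * u)`` with ``u`` the time unit
        implied by ``p_units``.
    p_units : str
        ``"per_bin"`` or ``"per_second"``.
    """

    p: float
    L: int
    dt: float
    n_bins: int
    kernels: np.ndarray
    p_units: str = "per_bin"

    @property
    def window(self) -> float:
        """Memory window in seconds."""
        return self.n_bins * self.dt

    def gram(self) -> np.ndarray:
        """Discrete Gram matrix of the kernels.

        Inner products are weighted so that, for a window much longer than
        the slowest mode and a fine enough grid, the result approaches the
        identity (orthonormality of the Laguerre functions).
        """
        w = self.dt if self.p_units == "per_second" else 1.0
        return (self.kernels @ self.kernels.T) * w


def build_basis(p: float, L: int, dt: float, window: float,
                p_units: str = "per_bin") -> LaguerreBasis:
    """Discretize the first ``L`` Laguerre basis functions.

    Parameters
    ----------
    p : float
        Decay constant; must be positive. Interpreted per bin of width
        ``dt`` (default) or per second.
    L : int
        Number of functions (>= 1).
    dt : float
        Bin width in seconds.
    window : float
        Memory window in seconds; the kernel length is
        ``M_k = round(window / dt)`` bins.
    """
    if p <= 0:
        raise ValueError("decay constant p must be positive")
    if L < 1:
        raise ValueError("need at least one basis function")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if window < dt:
        raise ValueError("window must be at least one bin wide")
    if p_units not in ("per_bin", "per_second"):
        raise ValueError("p_units must be 'per_bin' or 'per_second'")
    n_bins = int(round(window / dt))
    # Bin-center ages in the unit implied by p_units.
    k = np.arange(n_bins) + 0.5
    tau = k if p_units == "per_bin" else k * dt
    x = 2.0 * p * tau
    decay = np.exp(-p * tau)
    kernels = np.empty((L, n_bins))
    for j in range(L):
        kernels[j] = np.sqrt(2.0 * p) * ((-1.0) ** j) \
            * laguerre_polynomial(j, x) * decay
    return LaguerreBasis(p=float(p), L=int(L), dt=float(dt), n_bins=n_bins,
                         kernels=kernels, p_units=p_units)


def convolve_basis(basis: LaguerreBasis, x: BinnedSignal) -> np.ndarray:
    """Convolve every kernel in the set with a binned input.

    Returns an ``(L, len(x))`` array of the series
    ``v_j(t) = sum_tau b_j(tau) x(t - tau)`` — a causal finite convolution
    truncated at the memory window and aligned with the input's grid.
    """
    if not np.isclose(basis.dt, x.dt, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"basis dt ({basis.dt}) does not match signal dt ({x.dt})")
    T = len(x)
    out = np.empty((basis.L, T))
    for j in range(basis.L):
        out[j] = oaconvolve(x.values, basis.kernels[j])[:T]
    return out
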