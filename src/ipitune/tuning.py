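"""Difference-of-exponentials IPI tuning function and its fits.

The response of AMMC-B1 auditory interneurons to pulse songs, expressed as a
normalized peak calcium response, is modelled as a function of the
inter-pulse interval ``x`` (ms)::

    y(x) = a * exp(-x / tau_b) - c * exp(-x / tau_d)

a slow excitatory decay (intercept ``a``, time constant ``tau_b``) minus a
fast inhibitory decay (intercept ``c``, time constant ``tau_d``).  With
``tau_b > tau_d`` and ``c * tau_b > a * tau_d`` the function has a unique
interior maximum — the band-pass "peak IPI" — available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TuningParams",
    "tuning_value",
    "analytic_peak",
    "fit_individual",
]


@dataclass(frozen=True)
class TuningParams:
    """Parameters (a, tau_b, c, tau_d) of the IPI tuning function.

    Time constants are in milliseconds; ``a`` and ``c`` are unitless
    intercepts on the normalized-response scale.  ``peak_ipi_ms`` is derived
    and cached at construction.
    """

    a: float
    tau_b: float
    c: float
    tau_d: float
    peak_ipi_ms: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.tau_b > 0 and self.tau_d > 0):
            raise ValueError(f"all parameters must be positive, got {self.as_tuple()}")
        if not self.tau_b > self.tau_d:
            raise ValueError(
                f"slow decay must outlast fast decay (tau_b={self.tau_b} <= tau_d={self.tau_d})"
            )
        if not self.c * self.tau_b > self.a * self.tau_d:
            raise ValueError(
                "no interior maximum: requires c*tau_b > a*tau_d, got "
                f"c*tau_b={self.c * self.tau_b:.6g} <= a*tau_d={self.a * self.tau_d:.6g}"
            )
        object.__setattr__(self, "peak_ipi_ms", analytic_peak(self))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.tau_b, self.c, self.tau_d)


def tuning_value(params, x):
    """Evaluate the tuning function at IPI ``x`` (ms; scalar or array).

    ``params`` may be a :class:`TuningParams` or any (a, tau_b, c, tau_d)
    sequence.
    """
    a, tau_b, c, tau_d = _unpack(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("IPI must be non-negative")
    out = a * np.exp(-x / tau_b) - c * np.exp(-x / tau_d)
    return float(out) if out.ndim == 0 else out


def analytic_peak(params) -> float:
    """Closed-form peak IPI of the tuning function, in ms.

    The unique stationary point of a*exp(-x/tau_b) - c*exp(-x/tau_d) is

        x* = tau_b*tau_d/(tau_b - tau_d) * ln(c*tau_b / (a*tau_d))

    which is the interior maximum whenever tau_b > tau_d and
    c*tau_b > a*tau_d; otherwise the function has no interior peak and this
    raises.
    """
    a, tau_b, c, tau_d = _unpack(params)
    if tau_b <= tau_d:
        raise ValueError("analytic peak requires tau_b > tau_d")
    ratio = (c * tau_b) / (a * tau_d)
    if ratio <= 1.0:
        raise ValueError(
            f"no interior maximum: c*tau_b/(a*tau_d) = {ratio:.6g} <= 1"
        )
    return tau_b * tau_d / (tau_b - tau_d) * np.log(ratio)


def fit_individual(curve, init=None, tol: float = 1e-10) -> TuningParams:
    """Deterministic least-squares fit of one individual's tuning curve.

    Minimizes the sum of squared deviations between the curve's normalized
    peaks and the tuning function over its IPIs.  Parameters are optimized on
    the log scale, which enforces positivity without explicit bounds.  Given
    the same ``init`` the result is deterministic.

    Parameters
    ----------
    curve
        Anything with ``ipis_ms`` and ``normalized_peaks`` attributes, or an
        ``(ipis_ms, values)`` pair of arrays.
    init
        Starting :class:`TuningParams` (or 4-sequence).  Defaults to a
        generic band-pass initialization (a=0.2, tau_b=80, c=2, tau_d=4).
    tol
        Termination tolerance handed to the trust-region solver.

    Raises
    ------
    RuntimeError
        If the solver reports failure; the message carries the final cost.
    """
    if hasattr(curve, "ipis_ms"):
        x = np.asarray(curve.ipis_ms, dtype=float)
        y = np.asarray(curve.normalized_peaks, dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)

    def resid(theta):
        a, tau_b, c, tau_d = np.exp(theta)
        return a * np.exp(-x / tau_b) - c * np.exp(-x / tau_d) - y

    # Always include a canonical band-pass start alongside the caller's:
    # the unregularized problem has degenerate basins (time constants running
    # to 0 or infinity) that a lone distant start can fall into, and the fit
    # is contractually robust to starts across [0.01, 1] x the magnitudes.
    starts = [_DEFAULT_INIT] if init is None else [_unpack(init), _DEFAULT_INIT]
    best = None
    last_message = ""
    for start in starts:
        sol = optimize.least_squares(
            resid, np.log(start), method="trf",
            xtol=tol, ftol=tol, gtol=tol, max_nfev=10_000,
        )
        last_message = f"{sol.message} (final cost {sol.cost:.3e})"
        if not sol.success:
            continue
        try:
            candidate = TuningParams(*np.exp(sol.x))
        except ValueError:
            continue  # degenerate basin: not a band-pass solution
        if best is None or sol.cost < best[0] - 1e-15:
            best = (sol.cost, candidate)
    if best is None:
        raise RuntimeError(f"tuning fit did not converge: {last_message}")
    return best[1]


_DEFAULT_INIT = (0.2, 80.0, 2.0, 4.0)


def _unpack(params) -> tuple[float, float, float, float]:
    if isinstance(params, TuningParams):
        return params.as_tuple()
    a, tau_b, c, tau_d = (float(v) for v in params)
    return a, tau_b, c, tau_d
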