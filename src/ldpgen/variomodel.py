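"""Exponential variogram model fitting and lesion-pattern summary coordinates.

The exponential model

    gamma(h) = c * (1 - exp(-3 |h| / a))

reaches ~95% of its sill c at h = a (the "practical range"). Fitted per
direction by unweighted nonlinear least squares, it condenses a directional
empirical variogram to (a, c): a is a measure of spatial continuity (bigger,
smoother lesions push a up), c is a proxy of total lesion load.

A lesion pattern is then summarized on the log scale by

    a_bar = ln(mean(a_x, a_y, a_z)),   c_bar = ln(mean(c_x, c_y, c_z))

i.e. the log of the arithmetic mean of the per-direction parameters — not
the mean of the logs (by Jensen's inequality the two differ whenever the
directions disagree, which is exactly the anisotropic case of interest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .variography import EmpiricalVariogram

logger = logging.getLogger(__name__)

__all__ = [
    "ExpModelFit",
    "LDPRecord",
    "exponential_model",
    "default_guesses",
    "fit_exponential",
    "ldp_summary",
]


def exponential_model(h, a: float, c: float):
    """Exponential variogram model gamma(h) = c (1 - exp(-3 h / a)).

    ``a`` (mm) must be positive; ``c`` (variance units) non-negative; the
    model passes through the origin and approaches the sill c as h grows.
    """
    if a <= 0:
        raise ValueError(f"range a must be positive, got {a}")
    h = np.asarray(h, dtype=np.float64)
    return c * (1.0 - np.exp(-3.0 * np.abs(h) / a))


@dataclass(frozen=True)
class ExpModelFit:
    """Fitted exponential model for one direction, with fit diagnostics.

    ``converged`` is False when the optimizer failed, produced non-positive
    parameters, or did not improve on the starting estimates; ``a``/``c``
    then hold the last iterate for diagnosis and must not be consumed.
    """

    direction: str
    a: float
    c: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""


def default_guesses(emp: EmpiricalVariogram) -> tuple[float, float]:
    """Scale-free starting estimates for the nonlinear fit.

    guess_a: half the maximum lag distance (mm); guess_c: mean of the upper
    half of the empirical gamma values (the near-plateau region).
    """
    guess_a = float(emp.distances_mm[-1]) / 2.0
    upper = np.sort(emp.gamma)[len(emp.gamma) // 2:]
    guess_c = float(upper.mean())
    return guess_a, guess_c


def fit_exponential(
    emp: EmpiricalVariogram,
    guess_a: float | None = None,
    guess_c: float | None = None,
) -> ExpModelFit:
    """Unweighted least-squares fit of the exponential model to one variogram.

    Only the positive lags 1..max_lag enter the fit; no (0, 0) anchor point
    is appended. Positivity of (a, c) is enforced by fitting unconstrained
    and flagging non-positive solutions as non-converged, mirroring a plain
    ``nls`` call. Needs at least 3 finite gamma values.
    """
    h = np.asarray(emp.distances_mm, dtype=np.float64)
    g = np.asarray(emp.gamma, dtype=np.float64)
    finite = np.isfinite(g)
    h, g = h[finite], g[finite]
    n_points = len(g)
    if n_points < 3:
        raise ValueError(f"need >= 3 finite gamma values to fit, got {n_points}")

    if guess_a is None or guess_c is None:
        auto_a, auto_c = default_guesses(emp)
        guess_a = auto_a if guess_a is None else float(guess_a)
        guess_c = auto_c if guess_c is None else float(guess_c)

    def fail(msg: str, a=float("nan"), c=float("nan"), rss=float("nan")) -> ExpModelFit:
        logger.warning("fit (%s direction) did not converge: %s", emp.direction, msg)
        return ExpModelFit(emp.direction, a, c, rss, False, n_points, msg)

    if np.all(g == 0):
        return fail("all gamma values are zero (empty or constant mask); sill is degenerate")
    if guess_a <= 0 or guess_c <= 0:
        return fail(f"starting estimates must be positive (guess_a={guess_a}, guess_c={guess_c})")

    rss0 = float(np.sum((g - exponential_model(h, guess_a, guess_c)) ** 2))

    def model(hh, a, c):
        # unconstrained evaluation: let the optimizer wander, reject afterwards
        with np.errstate(over="ignore"):
            return c * (1.0 - np.exp(-3.0 * np.abs(hh) / a))

    # The least-squares surface is flat in a both as a -> 0 and a -> inf, so a
    # single Levenberg-Marquardt run can stall on a plateau. Run from the user
    # start plus a small deterministic ladder of range starts and keep the
    # valid solution with the lowest residual sum of squares.
    d_max = float(h[-1])
    starts = [(guess_a, guess_c)]
    starts += [
        (frac * d_max, guess_c)
        for frac in (0.05, 0.15, 0.35, 0.7, 1.0)
        if abs(frac * d_max - guess_a) > 1e-12
    ]

    best: tuple[float, float, float] | None = None  # (rss, a, c)
    last_err = ""
    for a0, c0 in starts:
        try:
            with warnings.catch_warnings():
                # the parameter covariance is unused; plateau starts make it singular
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                model, h, g,
                p0=(a0, c0),
                method="lm",
                maxfev=10000,
                ftol=1e-15, xtol=1e-15, gtol=1e-15,
            )
        except RuntimeError as exc:
            last_err = str(exc)
            continue
        a_try, c_try = float(popt[0]), float(popt[1])
        if not (np.isfinite(a_try) and np.isfinite(c_try)) or a_try <= 0 or c_try <= 0:
            last_err = f"invalid solution (a={a_try:.6g}, c={c_try:.6g})"
            continue
        rss = float(np.sum((g - model(h, a_try, c_try)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, a_try, c_try)

    if best is None:
        return fail(f"optimizer failure from every start: {last_err}")
    rss, a_fit, c_fit = best
    if rss > rss0 * (1 + 1e-12):
        return fail(f"no improvement over starting estimates (rss {rss:.3g} > {rss0:.3g})",
                    a_fit, c_fit, rss)
    return ExpModelFit(emp.direction, a_fit, c_fit, rss, True, n_points)


@dataclass(frozen=True)
class LDPRecord:
    """One row of the `.var` table: log-scale pattern coordinates of one mask."""

    id: int
    ln_mean_a: float
    ln_mean_c: float
    ln_aX: float
    ln_cX: float
    ln_aY: float
    ln_cY: float
    ln_aZ: float
    ln_cZ: float
    filename: str

    @property
    def component_lns(self) -> tuple[tuple[str, float, float], ...]:
        """Per-direction (axis, ln a, ln c) triples in x, y, z order."""
        return (
            ("x", self.ln_aX, self.ln_cX),
            ("y", self.ln_aY, self.ln_cY),
            ("z", self.ln_aZ, self.ln_cZ),
        )


def ldp_summary(
    fits: tuple[ExpModelFit, ExpModelFit, ExpModelFit],
    id: int,
    filename: str,
) -> LDPRecord:
    """Combine three directional fits into one pattern-discrimination record.

    ln_mean_a = ln((a_x + a_y + a_z) / 3) and likewise for c: the log of the
    arithmetic mean of the untransformed parameters. All three fits must have
    converged with positive parameters.
    """
    by_dir = {f.direction: f for f in fits}
    if sorted(by_dir) != ["x", "y", "z"]:
        raise ValueError(f"need one fit per direction x, y, z; got {[f.direction for f in fits]}")
    bad = [f"{f.direction}: {f.message or 'not converged'}" for f in fits if not f.converged]
    if bad:
        raise ValueError(f"cannot summarize {filename}: " + "; ".join(bad))

    fx, fy, fz = by_dir["x"], by_dir["y"], by_dir["z"]
    mean_a = (fx.a + fy.a + fz.a) / 3.0
    mean_c = (fx.c + fy.c + fz.c) / 3.0
    return LDPRecord(
        id=int(id),
        ln_mean_a=float(np.log(mean_a)),
        ln_mean_c=float(np.log(mean_c)),
        ln_aX=float(np.log(fx.a)), ln_cX=float(np.log(fx.c)),
        ln_aY=float(np.log(fy.a)), ln_cY=float(np.log(fy.c)),
        ln_aZ=float(np.log(fz.a)), ln_cZ=float(np.log(fz.c)),
        filename=filename,
    )
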