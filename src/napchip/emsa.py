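"""EMSA saturation-binding quantification: fraction bound per lane and
apparent-KD estimation.

The default model is the single-site hyperbolic isotherm on protein monomer
concentration, theta = [P] / (KD + [P]); the Hill variant
theta = [P]^h / (KD^h + [P]^h) is optional. Fits are labelled "apparent"
because ladder-like multi-dimer binding violates the single-site model; KD
is then simply the concentration at half-maximal binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "EmsaTitration",
    "BindingFit",
    "fraction_bound",
    "read_emsa_tsv",
    "BindingIsothermRegressor",
    "fit_kd",
]


@dataclass
class EmsaTitration:
    """One probe's titration: ascending monomer concentrations (nM) and the
    fraction of probe bound at each."""

    probe_id: str
    concentrations: np.ndarray  # nM, strictly increasing, >= 0
    fraction_bound: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if len(self.concentrations) != len(self.fraction_bound):
            raise ValueError("concentration and fraction vectors differ in length")
        if np.any(np.diff(self.concentrations) <= 0) or np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if np.any(self.fraction_bound < 0) or np.any(self.fraction_bound > 1):
            raise ValueError("fractions bound must lie in [0, 1]")


def fraction_bound(free_signal: np.ndarray, total_signal: np.ndarray) -> np.ndarray:
    """Per-lane fraction bound = 1 - free/total, clipped to [0, 1]."""
    free = np.asarray(free_signal, dtype=float)
    total = np.asarray(total_signal, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total signal must be > 0 in every lane")
    return np.clip(1.0 - free / total, 0.0, 1.0)


def read_emsa_tsv(path: str | Path) -> list[EmsaTitration]:
    """Read lane intensities (columns: probe_id, concentration_nM,
    free_signal, total_signal) and return one titration per probe."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "concentration_nM", "free_signal", "total_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EMSA table missing columns {sorted(missing)}")
    out = []
    for probe, sub in df.groupby("probe_id", sort=False):
        sub = sub.sort_values("concentration_nM")
        theta = fraction_bound(sub.free_signal.to_numpy(), sub.total_signal.to_numpy())
        out.append(EmsaTitration(str(probe), sub.concentration_nM.to_numpy(), theta))
    return out


@dataclass
class BindingFit:
    probe_id: str
    kd_apparent: float  # nM
    hill_coefficient: float | None
    residual_sse: float
    converged: bool
    model: str
    message: str = ""


def _theta(conc: np.ndarray, kd: float, hill: float = 1.0) -> np.ndarray:
    c = np.power(conc, hill)
    return c / (np.power(kd, hill) + c)


class BindingIsothermRegressor(BaseEstimator, RegressorMixin):
    """Least-squares apparent-KD estimator for a saturation-binding curve.

    Parameters
    ----------
    model : {"hyperbolic", "hill"}
        Single-site hyperbola (default) or Hill equation with a free
        cooperativity exponent.
    n_starts : int
        Number of log-spaced KD initial values for the multistart search.

    Fitted attributes: ``kd_`` (nM), ``hill_`` (1.0 for the hyperbolic
    model), ``sse_``, ``converged_``.
    """

    def __init__(self, model: str = "hyperbolic", n_starts: int = 7):
        self.model = model
        self.n_starts = n_starts

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        theta = np.asarray(y, dtype=float).ravel()
        if self.model not in ("hyperbolic", "hill"):
            raise ValueError(f"unknown isotherm model {self.model!r}")
        if len(conc) < 4:
            raise ValueError("need at least 4 concentration points")
        positive = conc[conc > 0]
        if len(positive) == 0:
            raise ValueError("need at least one positive concentration")

        kd_grid = np.geomspace(positive.min() / 10, positive.max() * 10,
                               self.n_starts)
        best = None
        for kd0 in kd_grid:
            if self.model == "hyperbolic":
                x0, lb, ub = [np.log(kd0)], [-np.inf], [np.inf]

                def resid(p):
                    return _theta(conc, np.exp(p[0])) - theta
            else:
                x0, lb, ub = [np.log(kd0), 1.0], [-np.inf, 0.1], [np.inf, 10.0]

                def resid(p):
                    return _theta(conc, np.exp(p[0]), p[1]) - theta

            try:
                sol = least_squares(resid, x0, bounds=(lb, ub))
            except Exception:  # pragma: no cover - solver failure path
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        if best is None or not best.success:
            self.kd_ = float("nan")
            self.hill_ = float("nan")
            self.sse_ = float("nan")
            self.converged_ = False
            self.message_ = "no least-squares start converged"
            return self
        self.kd_ = float(np.exp(best.x[0]))
        self.hill_ = float(best.x[1]) if self.model == "hill" else 1.0
        self.sse_ = float(2 * best.cost)
        self.converged_ = True
        self.message_ = "ok"
        return self

    def predict(self, X):
        if not hasattr(self, "kd_"):
            raise RuntimeError("BindingIsothermRegressor is not fitted")
        return _theta(np.asarray(X, dtype=float).ravel(), self.kd_, self.hill_)


def fit_kd(titration: EmsaTitration, model: str = "hyperbolic") -> BindingFit:
    """Fit the apparent KD of one titration; non-convergence is reported via
    ``converged=False`` rather than an exception."""
    reg = BindingIsothermRegressor(model=model)
    try:
        reg.fit(titration.concentrations, titration.fraction_bound)
    except ValueError:
        raise
    return BindingFit(
        probe_id=titration.probe_id,
        kd_apparent=reg.kd_,
        hill_coefficient=reg.hill_ if model == "hill" else None,
        residual_sse=reg.sse_,
        converged=reg.converged_,
        model=model,
        message=getattr(reg, "message_", ""),
    )
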