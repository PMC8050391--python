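"""Competitive-inhibition kinetics: model, global fit, diagnostics.

The fully competitive model raises the apparent Michaelis constant with
inhibitor while leaving Vmax unchanged:

    v0 = Vmax [S] / (KM (1 + [I]/KI) + [S])

All inhibitor series are fit globally (one shared Vmax, KM, KI) by
bounded nonlinear least squares with multi-start restarts, and the
competitive signature is checked via the shared Lineweaver-Burk ordinate
intercept (an F-test of a common 1/Vmax intercept across series).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy import stats


class FitFailureError(RuntimeError):
    """Global fit did not converge after the bounded restarts."""


@dataclass
class RateObservation:
    S: float          # substrate, uM
    I: float          # inhibitor, uM
    v0: float         # initial rate, uM/s
    enzyme_conc: float = 5.0

    def __post_init__(self):
        if self.S <= 0 or self.I < 0 or self.v0 < 0:
            raise ValueError("require S > 0, I >= 0, v0 >= 0")


@dataclass
class RateDataset:
    observations: list

    def __post_init__(self):
        if not self.observations:
            raise ValueError("empty dataset")
        concs = {o.enzyme_conc for o in self.observations}
        if len(concs) != 1:
            raise ValueError("one enzyme concentration per dataset")

    @property
    def enzyme_conc(self) -> float:
        return self.observations[0].enzyme_conc

    @property
    def inhibitor_levels(self):
        return sorted({o.I for o in self.observations})

    def arrays(self):
        S = np.array([o.S for o in self.observations])
        I = np.array([o.I for o in self.observations])
        v = np.array([o.v0 for o in self.observations])
        return S, I, v

    def to_frame(self) -> pd.DataFrame:
        S, I, v = self.arrays()
        return pd.DataFrame({"S_uM": S, "I_uM": I, "v0_uM_per_s": v})

    @classmethod
    def from_csv(cls, path, enzyme_conc: float | None = None) -> "RateDataset":
        """CSV with columns S_uM, I_uM, v0_uM_per_s; optional '# enzyme_uM = x' header."""
        path = Path(path)
        if enzyme_conc is None:
            enzyme_conc = 5.0
            for line in path.read_text().splitlines():
                if line.startswith("#") and "enzyme_uM" in line:
                    enzyme_conc = float(line.split("=")[1])
                if not line.startswith("#"):
                    break
        df = pd.read_csv(path, comment="#")
        obs = [RateObservation(S=r.S_uM, I=r.I_uM, v0=r.v0_uM_per_s,
                               enzyme_conc=enzyme_conc)
               for r in df.itertuples()]
        return cls(observations=obs)


@dataclass
class InhibitionFit:
    Vmax: float
    KM: float
    KI: float
    enzyme_conc: float
    standard_errors: dict
    covariance: np.ndarray
    residuals: np.ndarray
    n_obs: int

    @property
    def kcat(self) -> float:
        return self.Vmax / self.enzyme_conc

    def confidence_intervals(self, level: float = 0.95) -> dict:
        """Wald intervals parameter -> (lo, hi) from the asymptotic SEs."""
        dof = max(self.n_obs - 3, 1)
        tcrit = stats.t.ppf(0.5 + level / 2, dof)
        out = {}
        for name, val in (("Vmax", self.Vmax), ("KM", self.KM), ("KI", self.KI)):
            se = self.standard_errors.get(name, np.nan)
            out[name] = (val - tcrit * se, val + tcrit * se)
        return out

    def as_dict(self) -> dict:
        return {
            "Vmax_uM_per_s": self.Vmax, "kcat_per_s": self.kcat,
            "KM_uM": self.KM, "KI_uM": self.KI,
            "standard_errors": dict(self.standard_errors),
            "n_obs": self.n_obs,
        }


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def competitive_rate(S, I, Vmax: float, KM: float, KI: float):
    """v0 = Vmax S / (KM (1 + I/KI) + S); concentrations in uM."""
    if Vmax <= 0 or KM <= 0 or KI <= 0:
        raise ValueError("Vmax, KM, KI must all be positive")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    return Vmax * S / (KM * (1.0 + I / KI) + S)


def lineweaver_point(S: float, I: float, Vmax: float, KM: float, KI: float):
    """Double-reciprocal coordinates (1/S, 1/v0) on the competitive line."""
    v0 = float(competitive_rate(S, I, Vmax, KM, KI))
    if v0 <= 0:
        raise ValueError("zero rate cannot be transformed")
    return 1.0 / S, 1.0 / v0


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def global_fit(d: RateDataset, init=None, weighting: str = "unit",
               n_restarts: int = 5, seed: int = 0) -> InhibitionFit:
    """Global nonlinear least squares over all inhibitor series.

    Unit weights by default (``weighting="inv_v2"`` selects 1/v^2).
    Default initialisation: Vmax = 1.2 max(v0), KM = median(S),
    KI = median(nonzero I); bounded positive, with jittered restarts
    before declaring failure.  Standard errors come from the covariance
    of the converged solution.
    """
    S, I, v = d.arrays()
    if len(np.unique(S)) < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if len(d.inhibitor_levels) < 2:
        raise FitFailureError(
            "KI is unidentifiable with a single inhibitor level")
    if init is None:
        nz = I[I > 0]
        init = (1.2 * float(v.max()), float(np.median(S)), float(np.median(nz)))
    w = np.ones_like(v) if weighting == "unit" else 1.0 / np.maximum(v, 1e-12) ** 2
    sqrtw = np.sqrt(w)

    def residual(params):
        model = competitive_rate(S, I, params["Vmax"].value,
                                 params["KM"].value, params["KI"].value)
        return sqrtw * (v - model)

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts):
        factor = 1.0 if trial == 0 else float(np.exp(rng.normal(0, 0.5)))
        params = lmfit.Parameters()
        params.add("Vmax", value=init[0] * factor, min=1e-12)
        params.add("KM", value=init[1] * factor, min=1e-12)
        params.add("KI", value=init[2] * factor, min=1e-12)
        res = lmfit.minimize(residual, params, method="least_squares")
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
        if best is not None and trial == 0:
            break  # converged on the default start; restarts unneeded
    if best is None:
        raise FitFailureError(f"no convergence after {n_restarts} restarts")

    names = ["Vmax", "KM", "KI"]
    se = {}
    cov = np.full((3, 3), np.nan)
    if best.covar is not None:
        var_order = [best.var_names.index(n) for n in names]
        cov = best.covar[np.ix_(var_order, var_order)]
        se = {n: float(np.sqrt(cov[i, i])) for i, n in enumerate(names)}
    else:
        se = {n: float("nan") for n in names}
    return InhibitionFit(
        Vmax=float(best.params["Vmax"].value), KM=float(best.params["KM"].value),
        KI=float(best.params["KI"].value), enzyme_conc=d.enzyme_conc,
        standard_errors=se, covariance=cov,
        residuals=np.asarray(best.residual), n_obs=len(v))


# ---------------------------------------------------------------------------
# competitive diagnostic
# ---------------------------------------------------------------------------

def competitive_diagnostic(f: InhibitionFit, d: RateDataset) -> dict:
    """Shared Lineweaver-Burk ordinate intercept test.

    Per inhibitor level a line 1/v = a + b/S is fit; a shared-intercept
    model is compared with per-level intercepts via an F-test.  For a
    competitive inhibitor the intercepts coincide (p above the usual
    0.05 threshold); non-coincident intercepts flag departure from
    competitive behaviour.
    """
    S, I, v = d.arrays()
    mask = v > 0
    S, I, v = S[mask], I[mask], v[mask]
    x, y = 1.0 / S, 1.0 / v
    levels = sorted(set(I))
    k = len(levels)
    # full model: per-level intercept and slope
    X_full = np.zeros((len(y), 2 * k))
    for j, lev in enumerate(levels):
        sel = I == lev
        X_full[sel, j] = 1.0
        X_full[sel, k + j] = x[sel]
    beta_full, rss_full = _ols(X_full, y)
    # reduced: shared intercept, per-level slope
    X_red = np.zeros((len(y), 1 + k))
    X_red[:, 0] = 1.0
    for j, lev in enumerate(levels):
        X_red[I == lev, 1 + j] = x[I == lev]
    beta_red, rss_red = _ols(X_red, y)
    df_num = k - 1
    df_den = len(y) - 2 * k
    if rss_full <= 0 or df_den <= 0:
        fstat, pval = 0.0, 1.0
    else:
        fstat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
        pval = float(stats.f.sf(max(fstat, 0.0), df_num, df_den))
    intercepts = {lev: float(beta_full[j]) for j, lev in enumerate(levels)}
    return {
        "intercepts_per_level": intercepts,
        "shared_intercept": float(beta_red[0]),
        "expected_intercept": 1.0 / f.Vmax,
        "F": float(fstat),
        "p_value": pval,
        "competitive_consistent": bool(pval > 0.05),
    }


def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)
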