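"""Thermodynamic linkage between surface binding and folding stability.

Two pieces of thermodynamics connect the binding measurements to folding
outcomes.  First, a segment of the unfolded chain that spends a fraction
``p_B`` of its time bound to the ribosome has its unfolded state
stabilized by

    dG(U_free -> U) = RT ln(1 - p_B)      (<= 0),

which destabilizes folding by the same magnitude because the native state
cannot bind.  Second, equilibrium denaturation curves (CD signal, or
fraction PEGylated for nascent chains) are fitted globally to a two-state
model with constant baselines and a shared denaturant m value,

    y([D]) = a_N + a_D * exp(m ([D] - D50) / RT) / (1 + exp(m ([D] - D50) / RT)),

from which stabilities follow as dG(D-N) = m * D50.  Nascent-chain curves
are fitted only below a denaturant cutoff (ribosomes dissociate at high
urea), optionally with m fixed to the isolated-protein value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import T_DEFAULT, rt_kcal

__all__ = [
    "LinkageResult",
    "DenaturationCurve",
    "TwoStateFit",
    "unfolded_state_stabilization",
    "required_binding_for_destabilization",
    "two_state_signal",
    "two_state_global_fit",
    "stability_difference",
    "predict_stability_shift",
]


@dataclass
class LinkageResult:
    """Unfolded-state stabilization implied by a bound fraction."""

    p_B: float
    temperature: float
    delta_g: float  # kcal/mol, <= 0 (stabilization of U, destabilization of folding)

    @property
    def destabilization(self) -> float:
        """Magnitude of the folding destabilization, kcal/mol (>= 0)."""
        return -self.delta_g


def unfolded_state_stabilization(
    p_B: float, temperature: float = T_DEFAULT
) -> LinkageResult:
    """dG(U_free -> U) = RT ln(1 - p_B); domain 0 <= p_B < 1."""
    if not 0.0 <= p_B < 1.0:
        raise ValueError(f"p_B must lie in [0, 1), got {p_B}")
    dg = rt_kcal(temperature) * math.log1p(-p_B)
    return LinkageResult(p_B=float(p_B), temperature=float(temperature), delta_g=dg)


def required_binding_for_destabilization(
    delta_g: float, temperature: float = T_DEFAULT
) -> float:
    """Bound fraction needed to destabilize folding by ``delta_g`` (> 0) kcal/mol.

    Inverse of :func:`unfolded_state_stabilization`:
    p_B = 1 - exp(-delta_g / RT).
    """
    if delta_g <= 0:
        raise ValueError(f"delta_g must be positive, got {delta_g}")
    return -math.expm1(-delta_g / rt_kcal(temperature))


@dataclass
class DenaturationCurve:
    """One equilibrium denaturation curve (signal vs denaturant)."""

    label: str
    denaturant: np.ndarray  # M
    signal: np.ndarray
    signal_error: np.ndarray
    temperature: float = T_DEFAULT
    kind: str = "cd"  # 'cd' (continuous signal) or 'fraction' (PEGylation)
    urea_cutoff: Optional[float] = None  # fit only points with [D] < cutoff

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, float)
        self.signal = np.asarray(self.signal, float)
        self.signal_error = np.asarray(self.signal_error, float)
        if not (len(self.denaturant) == len(self.signal) == len(self.signal_error)):
            raise ValueError(f"curve {self.label!r}: column lengths differ")
        if not (self.signal_error > 0).all():
            raise ValueError(f"curve {self.label!r}: signal_error must be positive")

    def mask(self) -> np.ndarray:
        """Boolean inclusion mask: points strictly below the urea cutoff."""
        if self.urea_cutoff is None:
            return np.ones_like(self.denaturant, bool)
        return self.denaturant < self.urea_cutoff


@dataclass
class TwoStateFit:
    """Global two-state fit across denaturation curves."""

    per_curve: pd.DataFrame  # label, d50, d50_se, alpha_n, alpha_d, dg, dg_se, n_points
    m: float
    m_se: float
    m_fixed: bool
    temperature: float
    params: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    index: dict = field(repr=False)  # parameter name -> position in params/cov
    diagnostics: dict = field(default_factory=dict)

    def dg(self, label: str) -> tuple[float, float]:
        row = self.per_curve[self.per_curve["label"] == label]
        if row.empty:
            raise KeyError(f"no fitted curve {label!r}")
        return float(row["dg"].iloc[0]), float(row["dg_se"].iloc[0])


def two_state_signal(
    d: np.ndarray,
    d50: float,
    m: float,
    alpha_n: float,
    alpha_d: float,
    temperature: float = T_DEFAULT,
) -> np.ndarray:
    """Two-state sigmoid: native baseline a_N, denatured plateau a_N + a_D."""
    x = m * (np.asarray(d, float) - d50) / rt_kcal(temperature)
    # numerically stable logistic
    f = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return alpha_n + alpha_d * f


def _init_curve(curve: DenaturationCurve, msk: np.ndarray) -> tuple[float, float, float]:
    d = curve.denaturant[msk]
    y = curve.signal[msk]
    order = np.argsort(d)
    d, y = d[order], y[order]
    a_n = float(np.mean(y[: max(1, len(y) // 6)]))
    a_d = float(np.mean(y[-max(1, len(y) // 6):]) - a_n)
    mid = a_n + 0.5 * a_d
    # first crossing of the half-amplitude level
    above = (y - mid) * np.sign(a_d if a_d != 0 else 1.0) > 0
    idx = int(np.argmax(above)) if above.any() else len(d) - 1
    d50 = float(d[idx]) if idx > 0 else float(np.median(d))
    return d50, a_n, a_d


def two_state_global_fit(
    curves: Sequence[DenaturationCurve],
    share_m: bool = True,
    m_fixed: Optional[float] = None,
    urea_cutoff: Optional[Mapping[str, float]] = None,
    temperature: Optional[float] = None,
    n_boot: int = 0,
    seed: int = 0,
) -> TwoStateFit:
    """Weighted global nonlinear least squares of the two-state model.

    Parameters
    ----------
    curves
        Denaturation curves; each contributes per-curve parameters
        (D50, a_N, a_D).  With ``share_m`` a single m value is fitted
        across all curves; with ``m_fixed`` the m value is held at the
        supplied number (e.g. the isolated-protein value when fitting
        masked nascent-chain curves).
    urea_cutoff
        Optional ``{label: cutoff}`` overriding each curve's own cutoff;
        points at or above the cutoff never enter the fit.
    n_boot, seed
        Optional residual-bootstrap draws for parameter uncertainties
        (covariance-based SEs are always reported).

    Stabilities are dG = m * D50 per curve, with SEs propagated through
    the full parameter covariance (including the shared-m terms).
    """
    if not share_m and m_fixed is None:
        # independent m per curve: fit each curve separately and concatenate
        raise NotImplementedError(
            "per-curve m values are not supported in the global fit; "
            "fit curves individually instead"
        )
    if temperature is None:
        temperature = curves[0].temperature
    labels = [c.label for c in curves]
    if len(set(labels)) != len(labels):
        raise ValueError("curve labels must be unique")
    masks = []
    for c in curves:
        if urea_cutoff and c.label in urea_cutoff:
            c = DenaturationCurve(
                label=c.label, denaturant=c.denaturant, signal=c.signal,
                signal_error=c.signal_error, temperature=c.temperature,
                kind=c.kind, urea_cutoff=urea_cutoff[c.label],
            )
        masks.append(c.mask())
    n_points = [int(m.sum()) for m in masks]
    fit_m = m_fixed is None
    n_params = (1 if fit_m else 0) + 3 * len(curves)
    for c, npts in zip(curves, n_points):
        if npts < 5:
            raise ValueError(
                f"curve {c.label!r}: only {npts} points pass the mask; need >= 5"
            )
    if sum(n_points) <= n_params:
        raise ValueError("fewer masked points than free parameters")

    index: dict[str, int] = {}
    x0 = []
    if fit_m:
        index["m"] = 0
        x0.append(1.5)
    for i, (c, msk) in enumerate(zip(curves, masks)):
        d50, a_n, a_d = _init_curve(c, msk)
        base = len(x0)
        index[f"d50_{c.label}"] = base
        index[f"alpha_n_{c.label}"] = base + 1
        index[f"alpha_d_{c.label}"] = base + 2
        x0.extend([d50, a_n, a_d])
    x0 = np.asarray(x0, float)

    def residuals(x):
        m_val = x[index["m"]] if fit_m else m_fixed
        out = []
        for c, msk in zip(curves, masks):
            d50 = x[index[f"d50_{c.label}"]]
            a_n = x[index[f"alpha_n_{c.label}"]]
            a_d = x[index[f"alpha_d_{c.label}"]]
            pred = two_state_signal(c.denaturant[msk], d50, m_val, a_n, a_d, temperature)
            out.append((c.signal[msk] - pred) / c.signal_error[msk])
        return np.concatenate(out)

    lo = np.full(len(x0), -np.inf)
    hi = np.full(len(x0), np.inf)
    if fit_m:
        lo[0], hi[0] = 1e-3, 100.0
    sol = least_squares(residuals, np.clip(x0, lo + 1e-6, hi - 1e-6), bounds=(lo, hi))

    dof = sum(n_points) - len(x0)
    s2 = 2.0 * sol.cost / max(dof, 1)
    jtj = sol.jac.T @ sol.jac
    cov = s2 * np.linalg.pinv(jtj)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = residuals(sol.x)
        fitted = {}
        for c, msk in zip(curves, masks):
            m_val = sol.x[index["m"]] if fit_m else m_fixed
            fitted[c.label] = two_state_signal(
                c.denaturant[msk],
                sol.x[index[f"d50_{c.label}"]],
                m_val,
                sol.x[index[f"alpha_n_{c.label}"]],
                sol.x[index[f"alpha_d_{c.label}"]],
                temperature,
            )
        draws = np.empty((n_boot, len(sol.x)))
        for b in range(n_boot):
            eps = rng.choice(resid, size=resid.shape, replace=True)
            pos = 0
            ys = {}
            for c, msk in zip(curves, masks):
                k = int(msk.sum())
                ys[c.label] = fitted[c.label] + eps[pos : pos + k] * c.signal_error[msk]
                pos += k
            def residuals_b(x, _ys=ys):
                m_val = x[index["m"]] if fit_m else m_fixed
                out = []
                for c, msk in zip(curves, masks):
                    pred = two_state_signal(
                        c.denaturant[msk],
                        x[index[f"d50_{c.label}"]],
                        m_val,
                        x[index[f"alpha_n_{c.label}"]],
                        x[index[f"alpha_d_{c.label}"]],
                        temperature,
                    )
                    out.append((_ys[c.label] - pred) / c.signal_error[msk])
                return np.concatenate(out)
            draws[b] = least_squares(residuals_b, sol.x, bounds=(lo, hi)).x
        cov_boot = np.cov(draws.T)
        cov = cov_boot  # bootstrap covariance supersedes the asymptotic one
    m_val = float(sol.x[index["m"]]) if fit_m else float(m_fixed)
    m_se = float(np.sqrt(cov[index["m"], index["m"]])) if fit_m else 0.0

    rows = []
    for c in curves:
        i50 = index[f"d50_{c.label}"]
        d50 = float(sol.x[i50])
        dg = m_val * d50
        grad = np.zeros(len(sol.x))
        grad[i50] = m_val
        if fit_m:
            grad[index["m"]] = d50
        dg_se = float(np.sqrt(grad @ cov @ grad))
        rows.append(
            {
                "label": c.label,
                "d50": d50,
                "d50_se": float(np.sqrt(cov[i50, i50])),
                "alpha_n": float(sol.x[index[f"alpha_n_{c.label}"]]),
                "alpha_d": float(sol.x[index[f"alpha_d_{c.label}"]]),
                "dg": dg,
                "dg_se": dg_se,
                "n_points": int(dict(zip(labels, n_points))[c.label]),
            }
        )
    return TwoStateFit(
        per_curve=pd.DataFrame(rows),
        m=m_val,
        m_se=m_se,
        m_fixed=not fit_m,
        temperature=float(temperature),
        params=sol.x,
        cov=cov,
        index=index,
        diagnostics={
            "cost": float(sol.cost),
            "dof": int(dof),
            "converged": bool(sol.status > 0),
            "reduced_chi2": float(s2),
            "n_boot": int(n_boot),
        },
    )


def stability_difference(
    fit: TwoStateFit, label_a: str, label_b: str
) -> tuple[float, float]:
    """ddG = dG(a) - dG(b) with SE including the shared-m covariance."""
    ia = fit.index[f"d50_{label_a}"]
    ib = fit.index[f"d50_{label_b}"]
    d50a, d50b = float(fit.params[ia]), float(fit.params[ib])
    ddg = fit.m * (d50a - d50b)
    grad = np.zeros(len(fit.params))
    grad[ia] = fit.m
    grad[ib] = -fit.m
    if not fit.m_fixed:
        grad[fit.index["m"]] = d50a - d50b
    se = float(np.sqrt(grad @ fit.cov @ grad))
    return float(ddg), se


def predict_stability_shift(
    pb_wt: float,
    pb_e6: float,
    ddg_isolated: float,
    temperature: float = T_DEFAULT,
) -> float:
    """Predicted inter-variant folding stability gap on the ribosome.

    With the charge-reversed variant binding less (p_B smaller), the
    wild-type unfolded state is preferentially stabilized and the gap
    shrinks relative to the isolated proteins:

        ddG_pred = ddG_isolated + RT ln[(1 - p_B,wt) / (1 - p_B,e6)].
    """
    for name, p in (("pb_wt", pb_wt), ("pb_e6", pb_e6)):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {p}")
    rt = rt_kcal(temperature)
    return float(ddg_isolated + rt * (math.log1p(-pb_wt) - math.log1p(-pb_e6)))
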