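"""Chemical-shift perturbation analysis of nascent chain-ribosome binding.

Under fast exchange between a free and a ribosome-bound state, an observed
resonance sits at the population-weighted average position, so its
perturbation relative to the isolated protein is

    CSP(variant, L, resonance, dim) = p_B(variant, L) * dmax(resonance, dim)

where ``p_B`` is the bound fraction at linker length ``L`` and ``dmax`` is
the (unknown) full free-to-bound shift change.  A single variant at a
single length cannot separate ``p_B`` from ``dmax``; the global fit here
breaks the degeneracy by analysing two charge variants jointly across
several linker lengths under two assumptions: the inter-variant binding
free-energy difference is independent of length (both experience the same
effective ribosome concentration), and ``dmax`` is shared between variants.

The same CSPs, viewed as trajectories in the (1H, 15N) plane across
lengths, must be collinear along ``dmax`` if a single two-site equilibrium
is at work; :func:`collinearity_test` checks this and flags residues (such
as those right at the exit tunnel) whose deviations disqualify them from
the global fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from .constants import N15_WEIGHT_DEFAULT, T_DEFAULT, rt_kcal

__all__ = [
    "CollinearityResult",
    "BindingFitResult",
    "IdentifiabilityError",
    "compute_csp",
    "collinearity_test",
    "global_exchange_fit",
    "bound_fraction_curve",
]


class IdentifiabilityError(ValueError):
    """The experimental design cannot separate populations from endpoint shifts."""


@dataclass
class CollinearityResult:
    """Per-residue total-least-squares collinearity diagnostics."""

    df: pd.DataFrame  # residue_index, dir_H, dir_Nw, perp_rms, span, collinear
    tolerance: float
    weighting: float

    @property
    def excluded_residues(self) -> list[int]:
        """Residues failing the collinearity tolerance (to drop from the fit)."""
        bad = self.df.loc[~self.df["collinear"], "residue_index"]
        return [int(r) for r in bad]


@dataclass
class BindingFitResult:
    """Result of the global two-variant, multi-length fast-exchange fit."""

    populations: pd.DataFrame  # variant, length, p_B, p_B_se, ci_low, ci_high
    ddg: float
    ddg_se: float
    ddg_ci: tuple[float, float]
    dmax: pd.DataFrame  # residue_index, dim, value, se
    temperature: float
    diagnostics: dict = field(default_factory=dict)

    def p_bound(self, variant: str, length: int) -> float:
        sel = self.populations[
            (self.populations["variant"] == variant)
            & (self.populations["length"] == length)
        ]
        if sel.empty:
            raise KeyError(f"no fitted population for ({variant}, {length})")
        return float(sel["p_B"].iloc[0])


def compute_csp(
    pairs: pd.DataFrame,
    weighting: float = N15_WEIGHT_DEFAULT,
    sigma: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Signed per-residue shift differences (sample a - sample b).

    ``pairs`` is the output of :func:`rnclink.nmr_io.match_peaks` with the
    perturbed sample as ``a`` and the reference as ``b``.  The combined
    metric is ``sqrt(dH^2 + (w*dN)^2)`` with 15N weighting ``w``; the
    global fit itself consumes the per-dimension values, so ``w`` only
    affects reporting and collinearity scaling.  ``sigma = (sH, sN)``
    optionally supplies per-dimension shift uncertainties (ppm) for error
    propagation.
    """
    if weighting <= 0:
        raise ValueError(f"weighting must be positive, got {weighting}")
    d_h = (pairs["shift_H_a"] - pairs["shift_H_b"]).to_numpy(float)
    d_n = (pairs["shift_N_a"] - pairs["shift_N_b"]).to_numpy(float)
    combined = np.hypot(d_h, weighting * d_n)
    out = pd.DataFrame(
        {
            "residue_index": pairs["residue_index"].astype(int),
            "delta_H": d_h,
            "delta_N": d_n,
            "delta_combined": combined,
        }
    )
    if sigma is not None:
        s_h, s_n = float(sigma[0]), float(sigma[1])
        out["err_H"] = s_h
        out["err_N"] = s_n
        with np.errstate(invalid="ignore", divide="ignore"):
            err_c = np.sqrt(
                (d_h * s_h) ** 2 + (weighting**2 * d_n * s_n) ** 2
            ) / np.where(combined > 0, combined, np.nan)
        # at zero CSP the combined error degenerates to the larger axis error
        out["err_combined"] = np.where(combined > 0, err_c, max(s_h, weighting * s_n))
    return out


def collinearity_test(
    positions: Mapping[int, Sequence[Sequence[float]]],
    tolerance: float = 0.01,
    weighting: float = N15_WEIGHT_DEFAULT,
) -> CollinearityResult:
    """Total-least-squares collinearity of per-residue peak trajectories.

    ``positions`` maps residue -> sequence of (1H ppm, 15N ppm) peak
    positions across linker lengths plus the free state (>= 3 points).
    Points are scaled to (H, w*N) and fitted by TLS (SVD of the centred
    coordinates); a residue is collinear when the RMS perpendicular
    deviation is within ``tolerance`` (ppm, 1H scale).  A degenerate
    cluster of identical points is trivially collinear with undefined
    direction.
    """
    rows = []
    for residue, pts in positions.items():
        x = np.asarray(pts, float)
        if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
            raise ValueError(
                f"residue {residue}: need >= 3 (H, N) positions, got shape {x.shape}"
            )
        scaled = np.column_stack([x[:, 0], weighting * x[:, 1]])
        centred = scaled - scaled.mean(axis=0)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        n = len(scaled)
        perp_rms = s[1] / np.sqrt(n)
        proj = centred @ vt[0]
        span = float(proj.max() - proj.min())
        if span > 0:
            direction = vt[0]
            if direction[np.argmax(np.abs(direction))] < 0:
                direction = -direction
            dir_h, dir_nw = float(direction[0]), float(direction[1])
        else:
            dir_h, dir_nw = np.nan, np.nan
        rows.append(
            {
                "residue_index": int(residue),
                "dir_H": dir_h,
                "dir_Nw": dir_nw,
                "perp_rms": float(perp_rms),
                "span": span,
                "collinear": bool(perp_rms <= tolerance),
            }
        )
    return CollinearityResult(
        df=pd.DataFrame(rows), tolerance=tolerance, weighting=weighting
    )


def _design_from_tables(csp_tables, resonances, exclude):
    variants = list(csp_tables.keys())
    lengths = sorted({L for per_v in csp_tables.values() for L in per_v})
    if resonances is None:
        common = None
        for per_v in csp_tables.values():
            for prof in per_v.values():
                res = set(int(r) for r in prof["residue_index"])
                common = res if common is None else common & res
        resonances = sorted(common or [])
    resonances = [r for r in resonances if r not in set(exclude)]
    if not resonances:
        raise ValueError("no resonances left to fit after exclusions")
    obs = np.full((len(variants), len(lengths), len(resonances), 2), np.nan)
    for iv, v in enumerate(variants):
        for il, L in enumerate(lengths):
            prof = csp_tables[v].get(L)
            if prof is None:
                continue
            indexed = prof.set_index("residue_index")
            for ir, r in enumerate(resonances):
                if r in indexed.index:
                    obs[iv, il, ir, 0] = indexed.at[r, "delta_H"]
                    obs[iv, il, ir, 1] = indexed.at[r, "delta_N"]
    return variants, lengths, resonances, obs


def _model(lnk1, ddg_terms, dmax, rt):
    """Predicted CSPs, shape (n_v, n_L, n_r, 2)."""
    lnk = np.vstack([lnk1] + [lnk1 - dd / rt for dd in ddg_terms])
    p = expit(lnk)  # K/(1+K)
    return p[:, :, None, None] * dmax[None, None, :, :], p


def global_exchange_fit(
    csp_tables: Mapping[str, Mapping[int, pd.DataFrame]],
    resonances: Optional[Sequence[int]] = None,
    temperature: float = T_DEFAULT,
    sigma: tuple[float, float] = (0.005, 0.03),
    n_starts: int = 16,
    n_boot: int = 200,
    seed: int = 0,
    exclude: Sequence[int] = (),
) -> BindingFitResult:
    """Global fast-exchange fit of CSPs across variants and linker lengths.

    Parameters
    ----------
    csp_tables
        ``{variant: {linker_length: csp_profile}}`` where each profile is a
        :func:`compute_csp` frame.  The first variant is the reference; the
        fitted ``ddg`` (kcal/mol) is positive when later variants bind more
        weakly.
    resonances
        Residues to fit (default: those present everywhere), minus
        ``exclude`` (e.g. residues failing the collinearity test).
    sigma
        Per-dimension CSP uncertainties (ppm) used as weights.
    n_starts, n_boot, seed
        Multi-start count for the nonlinear least squares, residual
        bootstrap draws for confidence intervals, and the RNG seed
        controlling both.

    Free parameters: ln K(reference, L) per length, one ddg per non-reference
    variant, and dmax per (resonance, dimension).  The length-independence of
    ddg and the sharing of dmax between variants are what make the absolute
    populations identifiable.
    """
    variants, lengths, res_fit, obs = _design_from_tables(
        csp_tables, resonances, exclude
    )
    n_v, n_l, n_r = len(variants), len(lengths), len(res_fit)
    if n_v < 2:
        raise IdentifiabilityError("need at least two variants to anchor populations")
    if n_l < 2:
        raise IdentifiabilityError(
            "a single linker length cannot separate p_B from dmax; provide >= 2 lengths"
        )
    rt = rt_kcal(temperature)
    mask = np.isfinite(obs)
    if mask.sum() <= n_l + (n_v - 1) + 2 * n_r:
        raise IdentifiabilityError("fewer observations than free parameters")
    w = np.empty_like(obs)
    w[..., 0] = 1.0 / float(sigma[0])
    w[..., 1] = 1.0 / float(sigma[1])

    n_ddg = n_v - 1

    def unpack(x):
        lnk1 = x[:n_l]
        ddg = x[n_l : n_l + n_ddg]
        dmax = x[n_l + n_ddg :].reshape(n_r, 2)
        return lnk1, ddg, dmax

    def residuals(x):
        lnk1, ddg, dmax = unpack(x)
        pred, _ = _model(lnk1, ddg, dmax, rt)
        return ((obs - pred) * w)[mask]

    # Data-driven endpoint-shift guess: CSP at the shortest length of the
    # reference variant, inflated assuming ~80% binding there.
    dmax0 = np.nan_to_num(obs[0, 0] / 0.8, nan=0.05)
    dmax0 = np.clip(dmax0, -2.9, 2.9)

    rng = np.random.default_rng(seed)
    lo = np.concatenate([np.full(n_l, -12.0), np.full(n_ddg, -10.0), np.full(2 * n_r, -3.0)])
    hi = -lo
    hi[n_l : n_l + n_ddg] = 10.0
    lo[n_l : n_l + n_ddg] = -10.0

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            lnk_init = np.linspace(2.0, -2.0, n_l)
            ddg_init = np.full(n_ddg, 1.0)
            dm_init = dmax0.ravel()
        else:
            lnk_init = np.sort(rng.uniform(-3.0, 3.0, n_l))[::-1]
            ddg_init = rng.uniform(0.0, 3.5, n_ddg)
            dm_init = dmax0.ravel() * rng.uniform(0.5, 2.0)
        x0 = np.clip(np.concatenate([lnk_init, ddg_init, dm_init]), lo + 1e-6, hi - 1e-6)
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol

    lnk1, ddg_arr, dmax = unpack(best.x)
    pred, p_fit = _model(lnk1, ddg_arr, dmax, rt)
    resid = (obs - pred)[mask]
    wresid = ((obs - pred) * w)[mask]
    dof = int(mask.sum() - len(best.x))

    # Residual bootstrap: resample whitened residuals, refit from the optimum.
    boot_ddg = np.empty((max(n_boot, 0), n_ddg))
    boot_p = np.empty((max(n_boot, 0), n_v, n_l))
    for b in range(n_boot):
        eps = rng.choice(wresid, size=wresid.shape, replace=True)
        obs_b = pred.copy()
        obs_b[mask] = pred[mask] + eps / w[mask]
        def residuals_b(x, _obs=obs_b):
            lnk1_b, ddg_b, dmax_b = unpack(x)
            pred_b, _ = _model(lnk1_b, ddg_b, dmax_b, rt)
            return ((_obs - pred_b) * w)[mask]
        sol_b = least_squares(residuals_b, best.x, bounds=(lo, hi), method="trf")
        lnk1_b, ddg_b, dmax_b = unpack(sol_b.x)
        _, p_b = _model(lnk1_b, ddg_b, dmax_b, rt)
        boot_ddg[b] = ddg_b
        boot_p[b] = p_b

    if n_boot > 0:
        ddg_se = float(boot_ddg[:, 0].std(ddof=1))
        ddg_ci = tuple(np.percentile(boot_ddg[:, 0], [2.5, 97.5]))
        p_se = boot_p.std(axis=0, ddof=1)
        p_lo = np.percentile(boot_p, 2.5, axis=0)
        p_hi = np.percentile(boot_p, 97.5, axis=0)
    else:
        ddg_se, ddg_ci = float("nan"), (float("nan"), float("nan"))
        p_se = np.full((n_v, n_l), np.nan)
        p_lo = np.full((n_v, n_l), np.nan)
        p_hi = np.full((n_v, n_l), np.nan)

    pop_rows = []
    for iv, v in enumerate(variants):
        for il, L in enumerate(lengths):
            pop_rows.append(
                {
                    "variant": v,
                    "length": int(L),
                    "p_B": float(p_fit[iv, il]),
                    "p_B_se": float(p_se[iv, il]),
                    "ci_low": float(p_lo[iv, il]),
                    "ci_high": float(p_hi[iv, il]),
                }
            )
    dmax_rows = []
    for ir, r in enumerate(res_fit):
        for idim, dim in enumerate(("H", "N")):
            dmax_rows.append(
                {"residue_index": int(r), "dim": dim, "value": float(dmax[ir, idim])}
            )

    monotone = bool(np.all(np.diff(p_fit[0]) <= 1e-9))
    return BindingFitResult(
        populations=pd.DataFrame(pop_rows),
        ddg=float(ddg_arr[0]),
        ddg_se=ddg_se,
        ddg_ci=(float(ddg_ci[0]), float(ddg_ci[1])),
        dmax=pd.DataFrame(dmax_rows),
        temperature=float(temperature),
        diagnostics={
            "cost": float(best.cost),
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "weighted_rms": float(np.sqrt(np.mean(wresid**2))),
            "dof": dof,
            "converged": bool(best.status > 0),
            "n_starts": int(n_starts),
            "n_boot": int(n_boot),
            "reference_p_monotone_decreasing": monotone,
            "variants": variants,
            "lengths": [int(L) for L in lengths],
            "resonances": [int(r) for r in res_fit],
        },
    )


def bound_fraction_curve(
    fit: BindingFitResult,
    lengths_query: Sequence[float],
    variant: Optional[str] = None,
) -> pd.DataFrame:
    """Shape-preserving interpolation of fitted p_B over linker length.

    Monotone (PCHIP) interpolation between fitted lengths; extrapolation is
    refused because the effective ribosome concentration outside the fitted
    range is unconstrained.  Confidence bounds are interpolated the same
    way (an approximation, noted in the output).
    """
    pops = fit.populations
    variants = [variant] if variant is not None else list(pops["variant"].unique())
    q = np.asarray(lengths_query, float)
    rows = []
    for v in variants:
        sub = pops[pops["variant"] == v].sort_values("length")
        if sub.empty:
            raise KeyError(f"no fitted populations for variant {v!r}")
        L = sub["length"].to_numpy(float)
        if q.min() < L.min() or q.max() > L.max():
            raise ValueError(
                f"query lengths outside fitted range [{L.min():g}, {L.max():g}]; "
                "extrapolation is refused"
            )
        interp = PchipInterpolator(L, sub["p_B"].to_numpy())
        lo_ok = np.isfinite(sub["ci_low"]).all()
        interp_lo = PchipInterpolator(L, sub["ci_low"].to_numpy()) if lo_ok else None
        interp_hi = PchipInterpolator(L, sub["ci_high"].to_numpy()) if lo_ok else None
        for Lq in q:
            rows.append(
                {
                    "variant": v,
                    "length": float(Lq),
                    "p_B": float(interp(Lq)),
                    "ci_low": float(interp_lo(Lq)) if interp_lo else float("nan"),
                    "ci_high": float(interp_hi(Lq)) if interp_hi else float("nan"),
                }
            )
    return pd.DataFrame(rows)
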