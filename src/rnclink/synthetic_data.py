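"""Synthetic datasets with the statistical structure the analyses assume.

Every input class consumed by the downstream modules can be generated
here from an explicit ground truth and a seed, so the whole pipeline is
testable without external data:

* CSP datasets: peak lists for two nascent-chain variants across linker
  lengths, with observed shifts following the fast-exchange average
  ``shift_free + p_B * dmax`` plus Gaussian noise.  The bound fraction
  derives from a per-length binding free energy for the reference variant
  and a single length-independent inter-variant offset, so the odds ratio
  between variants is the same at every length and CSPs across lengths
  are exactly collinear before noise.
* CCR datasets: transferred relaxation ``eta_free + p_B * eta_bound``.
* Denaturation curves: two-state sigmoids with constant baselines and a
  shared m value, as continuous (CD-style) signals or fractions
  (PEGylation-style).
* Bead trajectories: frames alternating between docked and free poses of
  a nascent-chain segment near a static ribosome surface, with a target
  stationary bound-frame fraction and configurable per-ribosome-residue
  contact propensities.

Default parameter values reflect the experimental conditions the package
is designed around: 283 K, linker lengths 26-110 residues, an
inter-variant binding free-energy gap of 1.9 kcal/mol with ~90%/60%
binding of the reference variant at the 26/42-residue linkers, a shared
denaturant m value of 1.67 kcal/mol/M, and ~60% bound-segment occupancy
for trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import T_DEFAULT, rt_kcal
from .folding_thermo import DenaturationCurve, two_state_signal
from .nmr_io import PeakList
from .relaxation import CCRTable
from .cg_contacts import Trajectory

__all__ = [
    "BindingGroundTruth",
    "DenaturationGroundTruth",
    "CurveTruth",
    "TrajectoryGroundTruth",
    "simulate_csp_dataset",
    "simulate_ccr_dataset",
    "simulate_denaturation",
    "simulate_trajectory",
]

#: Default per-length bound fractions of the reference (strong-binding)
#: variant, anchored at 0.90 (L=26) and 0.60 (L=42) with a monotone decay
#: to near-zero binding at the longest linker.
DEFAULT_P_STRONG = {26: 0.90, 31: 0.82, 42: 0.60, 47: 0.47, 67: 0.25, 110: 0.06}

#: Default endpoint shift changes (free -> bound), ppm, for four
#: well-resolved reporter resonances flanking the binding segment.  The
#: largest 15N component corresponds to ~30 Hz at 22.3 T when 90% bound.
DEFAULT_DMAX = {
    717: (0.040, 0.24),
    720: (0.055, -0.27),
    724: (-0.045, 0.345),
    725: (0.035, 0.30),
}


def _default_free_shifts(residues: Sequence[int]) -> dict[int, tuple[float, float]]:
    """Deterministic pseudo-random but realistic free-state peak positions."""
    return {
        int(r): (8.0 + 0.07 * (r % 7), 112.0 + 1.3 * (r % 11)) for r in residues
    }


@dataclass
class BindingGroundTruth:
    """Ground truth for the two-variant, multi-length fast-exchange model.

    ``dg_bind_strong[L]`` is the binding free energy (kcal/mol) of the
    reference variant at linker length L, with the effective-concentration
    effect absorbed (no functional form in L is assumed).  ``ddg`` is the
    length-independent offset of the second variant (> 0: weaker binding).
    """

    dg_bind_strong: Mapping[int, float]
    ddg: float = 1.9
    dmax: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DMAX)
    )
    temperature: float = T_DEFAULT
    variants: tuple[str, str] = ("A3A3", "A3A3E6")
    free_shifts: Optional[Mapping[int, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if len(self.variants) != 2:
            raise ValueError("exactly two variants are modelled")
        for r, (dh, dn) in self.dmax.items():
            if dh == 0 and dn == 0:
                raise ValueError(f"residue {r}: dmax components must not both be zero")
        if self.free_shifts is None:
            self.free_shifts = _default_free_shifts(self.dmax.keys())
        for L in self.lengths:
            for v in range(2):
                p = self.p_bound(v, L)
                if not 0.0 < p < 1.0:
                    raise ValueError(
                        f"implied p_B out of (0, 1) for variant {v}, L={L}: {p}"
                    )

    @classmethod
    def from_populations(
        cls,
        p_strong: Mapping[int, float] = None,
        ddg: float = 1.9,
        temperature: float = T_DEFAULT,
        **kwargs,
    ) -> "BindingGroundTruth":
        """Build the truth from reference-variant bound fractions per length."""
        if p_strong is None:
            p_strong = dict(DEFAULT_P_STRONG)
        rt = rt_kcal(temperature)
        dg = {}
        for L, p in p_strong.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"p_strong[{L}] must lie in (0, 1), got {p}")
            dg[int(L)] = -rt * math.log(p / (1.0 - p))
        return cls(dg_bind_strong=dg, ddg=ddg, temperature=temperature, **kwargs)

    @property
    def lengths(self) -> list[int]:
        return sorted(int(L) for L in self.dg_bind_strong)

    def p_bound(self, variant_index: int, length: int) -> float:
        """Bound fraction of variant 0 (reference) or 1 at a linker length."""
        dg = self.dg_bind_strong[length] + (self.ddg if variant_index == 1 else 0.0)
        k = math.exp(-dg / rt_kcal(self.temperature))
        return k / (1.0 + k)


def simulate_csp_dataset(
    truth: BindingGroundTruth,
    noise_sd: tuple[float, float] = (0.003, 0.02),
    seed: int = 0,
    base_intensity: float = 1000.0,
    intensity_noise: float = 20.0,
    beta: float = 1.0,
    drop_threshold: float = 0.01,
) -> dict[tuple[str, Optional[int]], PeakList]:
    """Peak lists for both variants at every length, plus isolated references.

    Observed shifts are ``free + p_B * dmax`` plus Gaussian noise of SD
    ``noise_sd = (sigma_H, sigma_N)`` (ppm); the isolated references carry
    the same noise around the free positions.  Intensities decay
    monotonically with binding as ``(1 - p_B) * exp(-beta * p_B)`` (a
    phenomenological broadening model); residues whose attenuation falls
    below ``drop_threshold`` are dropped, mimicking resonances broadened
    beyond detection.  The second variant's free positions are offset
    slightly from the first (local sequence effects near the mutations).
    """
    if noise_sd[0] < 0 or noise_sd[1] < 0:
        raise ValueError("noise_sd components must be non-negative")
    rng = np.random.default_rng(seed)
    residues = sorted(truth.dmax.keys())
    out: dict[tuple[str, Optional[int]], PeakList] = {}
    offsets = [(0.0, 0.0), (0.015, 0.25)]
    for iv, variant in enumerate(truth.variants):
        off_h, off_n = offsets[iv]
        # isolated reference (linker_length None): free positions + noise
        rows = []
        for r in residues:
            fh, fn = truth.free_shifts[r]
            rows.append(
                {
                    "residue_index": r,
                    "residue_name": "X",
                    "shift_H": fh + off_h + rng.normal(0.0, noise_sd[0]),
                    "shift_N": fn + off_n + rng.normal(0.0, noise_sd[1]),
                    "intensity": max(base_intensity + rng.normal(0.0, intensity_noise), 0.0),
                    "noise": intensity_noise,
                }
            )
        out[(variant, None)] = PeakList(
            df=pd.DataFrame(rows),
            sample_id=f"{variant}_isolated",
            variant=variant,
            linker_length=None,
            temperature=truth.temperature,
        )
        for L in truth.lengths:
            p = truth.p_bound(iv, L)
            atten = (1.0 - p) * math.exp(-beta * p)
            rows = []
            for r in residues:
                if atten < drop_threshold:
                    continue
                fh, fn = truth.free_shifts[r]
                dh, dn = truth.dmax[r]
                rows.append(
                    {
                        "residue_index": r,
                        "residue_name": "X",
                        "shift_H": fh + off_h + p * dh + rng.normal(0.0, noise_sd[0]),
                        "shift_N": fn + off_n + p * dn + rng.normal(0.0, noise_sd[1]),
                        "intensity": max(
                            base_intensity * atten + rng.normal(0.0, intensity_noise),
                            0.0,
                        ),
                        "noise": intensity_noise,
                    }
                )
            out[(variant, L)] = PeakList(
                df=pd.DataFrame(
                    rows,
                    columns=[
                        "residue_index", "residue_name", "shift_H",
                        "shift_N", "intensity", "noise",
                    ],
                ),
                sample_id=f"{variant}+{L}",
                variant=variant,
                linker_length=L,
                temperature=truth.temperature,
            )
    return out


def simulate_ccr_dataset(
    p_profile: Mapping[int, float],
    eta_bound: float = 7000.0,
    eta_free: Union[float, Mapping[int, float]] = 5.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    temperature: float = T_DEFAULT,
) -> tuple[CCRTable, CCRTable]:
    """Transferred-relaxation tables: eta_rnc = eta_free + p_B * eta_bound + noise.

    Returns ``(rnc, isolated)`` tables over the residues of ``p_profile``;
    the isolated table carries independent noise around ``eta_free``.
    """
    if eta_bound <= 0:
        raise ValueError(f"eta_bound must be positive, got {eta_bound}")
    rng = np.random.default_rng(seed)
    residues = sorted(int(r) for r in p_profile)
    err = max(noise_sd, 1e-6)
    rows_rnc, rows_iso = [], []
    for r in residues:
        p = float(p_profile[r])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_profile[{r}] must lie in [0, 1], got {p}")
        ef = float(eta_free[r]) if isinstance(eta_free, Mapping) else float(eta_free)
        rows_rnc.append(
            {
                "residue_index": r,
                "eta_xy": ef + p * eta_bound + rng.normal(0.0, noise_sd),
                "eta_error": err,
            }
        )
        rows_iso.append(
            {
                "residue_index": r,
                "eta_xy": ef + rng.normal(0.0, noise_sd),
                "eta_error": err,
            }
        )
    rnc = CCRTable(df=pd.DataFrame(rows_rnc), sample_id="rnc", temperature=temperature)
    iso = CCRTable(
        df=pd.DataFrame(rows_iso), sample_id="isolated", temperature=temperature
    )
    return rnc, iso


@dataclass
class CurveTruth:
    """Ground truth for one denaturation curve."""

    label: str
    dg: float  # kcal/mol
    alpha_n: float
    alpha_d: float
    noise_sd: float
    kind: str = "cd"  # or 'fraction'


@dataclass
class DenaturationGroundTruth:
    """Shared-m two-state ground truth across denaturation curves."""

    curves: Sequence[CurveTruth]
    m: float = 1.67  # kcal mol^-1 M^-1
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")


def simulate_denaturation(
    truth: DenaturationGroundTruth,
    denaturant_grid: Sequence[float],
    seed: int = 0,
) -> list[DenaturationCurve]:
    """Two-state curves on a denaturant grid with Gaussian noise.

    Midpoints D50 = dG/m must fall inside the simulated grid (otherwise
    the curve carries no information about the transition and the truth
    is rejected).  Fraction-style curves are not clipped to [0, 1]: small
    excursions outside the physical range are what real densitometry
    noise produces.
    """
    grid = np.asarray(denaturant_grid, float)
    rng = np.random.default_rng(seed)
    out = []
    for ct in truth.curves:
        d50 = ct.dg / truth.m
        if not grid.min() <= d50 <= grid.max():
            raise ValueError(
                f"curve {ct.label!r}: midpoint {d50:.2f} M outside the grid "
                f"[{grid.min():g}, {grid.max():g}] M"
            )
        y = two_state_signal(grid, d50, truth.m, ct.alpha_n, ct.alpha_d, truth.temperature)
        y = y + rng.normal(0.0, ct.noise_sd, size=grid.shape)
        out.append(
            DenaturationCurve(
                label=ct.label,
                denaturant=grid.copy(),
                signal=y,
                signal_error=np.full_like(grid, max(ct.noise_sd, 1e-9)),
                temperature=truth.temperature,
                kind=ct.kind,
            )
        )
    return out


@dataclass
class TrajectoryGroundTruth:
    """Ground truth for a synthetic docked/free bead trajectory."""

    n_frames: int = 2000
    bound_fraction_target: float = 0.6
    segment: Sequence[int] = tuple(range(730, 747))
    n_ribosome_residues: int = 12
    contact_profile: Optional[Sequence[float]] = None  # per ribosome residue, in [0,1]
    ribosome_charges: Optional[Sequence[float]] = None
    cutoff: float = 0.8  # nm

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction_target <= 1.0:
            raise ValueError("bound_fraction_target must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if not self.segment:
            raise ValueError("segment must be non-empty")
        if self.contact_profile is None:
            self.contact_profile = np.linspace(0.9, 0.1, self.n_ribosome_residues)
        self.contact_profile = np.asarray(self.contact_profile, float)
        if len(self.contact_profile) != self.n_ribosome_residues:
            raise ValueError("contact_profile length must match n_ribosome_residues")
        if self.ribosome_charges is None:
            # predominantly rRNA-like surface: one negative charge per residue
            self.ribosome_charges = np.full(self.n_ribosome_residues, -1.0)
        self.ribosome_charges = np.asarray(self.ribosome_charges, float)


def simulate_trajectory(truth: TrajectoryGroundTruth, seed: int = 0) -> Trajectory:
    """Frames alternating between docked and free poses of the segment.

    Each frame is labelled bound with probability
    ``bound_fraction_target``.  In a bound frame the segment touches
    ribosome residue ``j`` with probability ``contact_profile[j]``
    (guaranteeing at least one contact); in a free frame every chain bead
    is far from the surface.  Ribosome beads are static, spaced so that a
    chain bead can contact exactly one ribosome residue at a time.
    """
    rng = np.random.default_rng(seed)
    cut = truth.cutoff
    n_rib = truth.n_ribosome_residues
    spacing = 4.0 * cut
    rib_pos = np.column_stack(
        [np.arange(n_rib) * spacing, np.zeros(n_rib), np.zeros(n_rib)]
    )
    seg = sorted(int(r) for r in truth.segment)
    chain_residues = np.arange(seg[0] - 4, seg[-1] + 5)
    n_chain = len(chain_residues)
    seg_beads = np.flatnonzero(np.isin(chain_residues, seg))

    labels = rng.random(truth.n_frames) < truth.bound_fraction_target
    far_y, free_y = 6.0 * cut, 8.0 * cut
    pos = np.empty((truth.n_frames, n_chain, 3))
    for f in range(truth.n_frames):
        base = np.column_stack(
            [
                np.linspace(0.0, (n_rib - 1) * spacing, n_chain),
                np.full(n_chain, free_y),
                np.zeros(n_chain),
            ]
        )
        if labels[f]:
            base[:, 1] = far_y
            contacted = np.flatnonzero(rng.random(n_rib) < truth.contact_profile)
            if contacted.size == 0:
                contacted = np.array([int(np.argmax(truth.contact_profile))])
            for k, j in enumerate(contacted[: len(seg_beads)]):
                bead = seg_beads[k]
                base[bead] = (rib_pos[j, 0], 0.5 * cut, 0.0)
        pos[f] = base + rng.normal(0.0, 0.02 * cut, size=(n_chain, 3))
    return Trajectory(
        ribosome_positions=rib_pos,
        ribosome_charges=truth.ribosome_charges,
        ribosome_groups=np.arange(n_rib),
        chain_positions=pos,
        chain_residues=chain_residues,
        labels=labels,
    )
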