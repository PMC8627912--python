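"""Contact analysis of coarse-grained ribosome-nascent chain trajectories.

The nascent chain is represented by one bead per residue and the (rigid)
ribosome surface by beads grouped into ribosome residues; electrostatics
between charged beads follow Debye-Hueckel screening.  From trajectory
frames this module computes per-ribosome-residue contact probabilities,
per-chain-residue interaction propensities, the bound fraction of a
designated segment, and the correlation of contact probabilities with
experimentally determined binding across linker lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL_NM

__all__ = [
    "Trajectory",
    "ContactSet",
    "debye_huckel_energy",
    "contact_probability",
    "correlate_contacts_with_binding",
]


@dataclass
class Trajectory:
    """Bead-model trajectory with a static ribosome and a mobile chain.

    ``ribosome_groups[i]`` is the ribosome residue id of ribosome bead
    ``i`` (several beads may share a residue, as for multi-bead RNA);
    ``chain_residues[j]`` is the nascent-chain residue index of chain bead
    ``j``.  ``labels`` optionally carries generator ground-truth
    bound/unbound flags per frame.
    """

    ribosome_positions: np.ndarray  # (n_rib_beads, 3), nm
    ribosome_charges: np.ndarray  # (n_rib_beads,), e
    ribosome_groups: np.ndarray  # (n_rib_beads,) residue ids
    chain_positions: np.ndarray  # (n_frames, n_chain, 3), nm
    chain_residues: np.ndarray  # (n_chain,)
    chain_charges: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ribosome_positions = np.asarray(self.ribosome_positions, float)
        self.chain_positions = np.asarray(self.chain_positions, float)
        self.ribosome_groups = np.asarray(self.ribosome_groups)
        self.chain_residues = np.asarray(self.chain_residues)
        if not np.isfinite(self.ribosome_positions).all():
            raise ValueError("ribosome bead positions must be finite")
        if not np.isfinite(self.chain_positions).all():
            raise ValueError("chain bead positions must be finite")
        if self.chain_positions.ndim != 3:
            raise ValueError("chain_positions must have shape (n_frames, n_chain, 3)")

    @property
    def n_frames(self) -> int:
        return self.chain_positions.shape[0]


@dataclass
class ContactSet:
    """Frame-averaged contact statistics for one trajectory."""

    ribosome: pd.DataFrame  # ribosome_id, contact_probability
    chain: pd.DataFrame  # residue_index, propensity
    bound_fraction: float
    cutoff: float
    n_frames: int
    min_contacts: int = 1

    def probability(self, ribosome_id) -> float:
        sel = self.ribosome[self.ribosome["ribosome_id"] == ribosome_id]
        if sel.empty:
            raise KeyError(f"no ribosome residue {ribosome_id!r}")
        return float(sel["contact_probability"].iloc[0])


def debye_huckel_energy(
    q1: float,
    q2: float,
    r: float,
    debye_length: float = 1.0,
    dielectric: float = 80.0,
) -> float:
    """Screened Coulomb pair energy, kcal/mol.

    U = k q1 q2 exp(-r / lambda_D) / (eps_r r) with k in
    kcal mol^-1 nm e^-2, ``r`` and ``debye_length`` in nm.
    """
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    if debye_length <= 0:
        raise ValueError(f"debye_length must be positive, got {debye_length}")
    if dielectric <= 0:
        raise ValueError(f"dielectric must be positive, got {dielectric}")
    return COULOMB_KCAL_NM * q1 * q2 * np.exp(-r / debye_length) / (dielectric * r)


def contact_probability(
    traj: Trajectory,
    segment: Sequence[int] = tuple(range(730, 747)),
    cutoff: float = 0.8,
    min_contacts: int = 1,
) -> ContactSet:
    """Cutoff-based contact statistics of a nascent-chain segment.

    For each ribosome residue, the contact probability is the fraction of
    frames in which any segment bead lies within ``cutoff`` of any bead of
    that residue.  A frame counts as *bound* when the total number of
    (segment bead, ribosome bead) pairs within the cutoff is at least
    ``min_contacts`` (default 1, i.e. any contact).
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    seg_mask = np.isin(traj.chain_residues, np.asarray(list(segment)))
    if not seg_mask.any():
        raise ValueError("segment selects no chain beads")
    seg_pos = traj.chain_positions[:, seg_mask, :]  # (F, S, 3)
    diff = seg_pos[:, :, None, :] - traj.ribosome_positions[None, None, :, :]
    within = np.einsum("fsrd,fsrd->fsr", diff, diff) <= cutoff**2  # (F, S, R)

    groups = traj.ribosome_groups
    rib_rows = []
    for gid in pd.unique(groups):
        beads = groups == gid
        hit = within[:, :, beads].any(axis=(1, 2))
        rib_rows.append({"ribosome_id": gid, "contact_probability": float(hit.mean())})

    # interaction propensity of every chain residue (not just the segment)
    diff_all = traj.chain_positions[:, :, None, :] - traj.ribosome_positions[None, None, :, :]
    within_all = np.einsum("fcrd,fcrd->fcr", diff_all, diff_all) <= cutoff**2
    chain_hit = within_all.any(axis=2)  # (F, C)
    chain_rows = [
        {"residue_index": int(res), "propensity": float(chain_hit[:, j].mean())}
        for j, res in enumerate(traj.chain_residues)
    ]

    n_pairs = within.sum(axis=(1, 2))
    bound = n_pairs >= min_contacts
    return ContactSet(
        ribosome=pd.DataFrame(rib_rows),
        chain=pd.DataFrame(chain_rows),
        bound_fraction=float(bound.mean()),
        cutoff=float(cutoff),
        n_frames=traj.n_frames,
        min_contacts=int(min_contacts),
    )


def correlate_contacts_with_binding(
    contacts_by_length: Mapping[int, ContactSet],
    experimental_pb: Mapping[int, float],
) -> pd.DataFrame:
    """Pearson correlation of contact probability with binding across lengths.

    For each ribosome residue present at every common length, correlates
    its contact probability with the experimentally determined bound
    fraction over the >= 3 common linker lengths.  Residues whose contact
    probabilities do not vary (or when the p_B series is constant) are
    flagged with an undefined correlation.
    """
    lengths = sorted(set(contacts_by_length) & set(experimental_pb))
    if len(lengths) < 3:
        raise ValueError(
            f"need >= 3 common lengths, got {len(lengths)}: {lengths}"
        )
    pb = np.array([experimental_pb[L] for L in lengths], float)
    ids = set(contacts_by_length[lengths[0]].ribosome["ribosome_id"])
    for L in lengths[1:]:
        ids &= set(contacts_by_length[L].ribosome["ribosome_id"])
    rows = []
    pb_const = np.ptp(pb) == 0
    for gid in sorted(ids, key=str):
        probs = np.array(
            [contacts_by_length[L].probability(gid) for L in lengths], float
        )
        if pb_const or np.ptp(probs) == 0:
            r = np.nan
            flagged = True
        else:
            r = float(np.corrcoef(probs, pb)[0, 1])
            flagged = False
        rows.append(
            {"ribosome_id": gid, "r": r, "n_lengths": len(lengths), "flagged": flagged}
        )
    return pd.DataFrame(rows)
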