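"""Tabular I/O for NMR observables and residue-wise profile arithmetic.

Peak tables hold per-residue 2D (1H, 15N) resonance positions with
intensities and spectral-noise estimates for one sample (an arrested
ribosome-nascent chain complex at a given linker length, or an isolated
reference protein).  All comparisons between samples are residue-wise;
residues broadened beyond detection are represented by *absence* and the
:func:`completeness_report` makes that absence explicit, because which
resonances vanish is itself information about where the chain contacts the
ribosome surface.

File format: comma-separated values with a mandatory header, plus an
optional YAML side-car (``<file>.meta.yaml``) holding sample metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PeakList",
    "PeakTableFormatError",
    "PeakTableValidationError",
    "VARIANTS",
    "read_peak_table",
    "write_peak_table",
    "read_ccr_table",
    "write_ccr_table",
    "read_denaturation_table",
    "write_denaturation_table",
    "match_peaks",
    "completeness_report",
    "intensity_ratio_profile",
]

#: Recognized nascent-chain variant labels.
VARIANTS = frozenset({"wt", "F3A3", "A3Y3", "A3A3", "A3A3E6", "E6", "Y719E", "other"})

PEAK_COLUMNS = ["residue_index", "residue_name", "shift_H", "shift_N", "intensity", "noise"]
CCR_COLUMNS = ["residue_index", "eta_xy", "eta_error"]
DENAT_COLUMNS = ["denaturant_M", "signal", "signal_error"]


class PeakTableFormatError(ValueError):
    """The file does not conform to the expected delimited layout."""


class PeakTableValidationError(ValueError):
    """The file parses but one or more rows violate the table invariants."""


@dataclass
class PeakList:
    """Per-residue 2D resonance table for one sample.

    ``df`` columns: residue_index, residue_name, shift_H (ppm), shift_N
    (ppm), intensity (arbitrary units, >= 0), noise (same units, > 0).
    ``linker_length`` is ``None`` for isolated reference proteins.
    """

    df: pd.DataFrame
    sample_id: str = ""
    variant: str = "other"
    linker_length: Optional[int] = None
    ionic_strength: Optional[float] = None
    field_strength: Optional[float] = None
    temperature: float = 283.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise PeakTableFormatError(f"peak table missing columns: {missing}")
        if self.variant not in VARIANTS:
            raise PeakTableValidationError(
                f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}"
            )
        if self.linker_length is not None and self.linker_length <= 0:
            raise PeakTableValidationError("linker_length must be positive when present")
        problems = _validate_peak_rows(self.df)
        if problems:
            raise PeakTableValidationError("; ".join(problems))

    @property
    def residues(self) -> np.ndarray:
        return self.df["residue_index"].to_numpy()

    def metadata(self) -> dict:
        md = {
            "sample_id": self.sample_id,
            "variant": self.variant,
            "linker_length": self.linker_length,
            "ionic_strength": self.ionic_strength,
            "field_strength": self.field_strength,
            "temperature": self.temperature,
        }
        md.update(self.extra)
        return md


def _validate_peak_rows(df: pd.DataFrame) -> list[str]:
    """Return human-readable problems, each naming the offending residue/line.

    Line numbers refer to the CSV layout (header on line 1).
    """
    problems: list[str] = []
    res = df["residue_index"]
    dup = res[res.duplicated(keep=False)]
    if len(dup):
        for r in sorted(dup.unique()):
            lines = [int(i) + 2 for i in res.index[res == r]]
            problems.append(f"duplicate residue {int(r)} (lines {lines})")
    for i, row in df.iterrows():
        line = int(i) + 2
        if not (np.isfinite(row["shift_H"]) and np.isfinite(row["shift_N"])):
            problems.append(f"non-finite shift at residue {int(row['residue_index'])} (line {line})")
        if not row["intensity"] >= 0:
            problems.append(f"negative intensity at residue {int(row['residue_index'])} (line {line})")
        if not row["noise"] > 0:
            problems.append(f"non-positive noise at residue {int(row['residue_index'])} (line {line})")
    return problems


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def read_peak_table(path, metadata: Optional[dict] = None) -> PeakList:
    """Read a CSV peak table; metadata from ``metadata`` or the YAML side-car."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{path}: missing columns {missing}")
    if metadata is None:
        sidecar = _sidecar_path(path)
        metadata = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    md = dict(metadata)
    extra = {k: md.pop(k) for k in list(md) if k not in {
        "sample_id", "variant", "linker_length", "ionic_strength",
        "field_strength", "temperature"}}
    return PeakList(df=df[PEAK_COLUMNS].copy(), extra=extra, **md)


def write_peak_table(peaks: PeakList, path, sidecar: bool = True) -> Path:
    """Write a CSV peak table plus (optionally) a YAML metadata side-car."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    peaks.df[PEAK_COLUMNS].to_csv(path, index=False)
    if sidecar:
        _sidecar_path(path).write_text(yaml.safe_dump(peaks.metadata(), sort_keys=True))
    return path


def read_ccr_table(path, metadata: Optional[dict] = None):
    """Read a CSV table of cross-correlated relaxation rates."""
    from .relaxation import CCRTable

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CCR table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in CCR_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{path}: missing columns {missing}")
    if metadata is None:
        sidecar = _sidecar_path(path)
        metadata = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    return CCRTable(df=df[CCR_COLUMNS].copy(), **dict(metadata))


def write_ccr_table(table, path, sidecar: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df[CCR_COLUMNS].to_csv(path, index=False)
    if sidecar:
        _sidecar_path(path).write_text(yaml.safe_dump(table.metadata(), sort_keys=True))
    return path


def read_denaturation_table(path, label: Optional[str] = None, **kwargs):
    """Read a CSV denaturation curve (denaturant_M, signal, signal_error)."""
    from .folding_thermo import DenaturationCurve

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"denaturation table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in DENAT_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableFormatError(f"{path}: missing columns {missing}")
    return DenaturationCurve(
        label=label or path.stem,
        denaturant=df["denaturant_M"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        signal_error=df["signal_error"].to_numpy(float),
        **kwargs,
    )


def write_denaturation_table(curve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "denaturant_M": curve.denaturant,
            "signal": curve.signal,
            "signal_error": curve.signal_error,
        }
    ).to_csv(path, index=False)
    return path


def match_peaks(a: PeakList, b: PeakList) -> pd.DataFrame:
    """Pair resonances of two samples residue-wise.

    Returns one row per residue present in *both* lists, ascending by
    residue index, with suffixes ``_a``/``_b`` on the per-sample columns.
    An empty intersection returns an empty frame and emits a warning.
    """
    cols = ["residue_index", "shift_H", "shift_N", "intensity", "noise"]
    merged = pd.merge(
        a.df[cols], b.df[cols], on="residue_index", suffixes=("_a", "_b")
    ).sort_values("residue_index", ignore_index=True)
    if merged.empty:
        warnings.warn("match_peaks: no residues in common between the two peak lists")
    return merged


def completeness_report(rnc: PeakList, reference: PeakList) -> dict:
    """Which residues vanished (broadened beyond detection) in either sample."""
    res_rnc = set(int(r) for r in rnc.residues)
    res_ref = set(int(r) for r in reference.residues)
    return {
        "missing_in_rnc": sorted(res_ref - res_rnc),
        "missing_in_reference": sorted(res_rnc - res_ref),
        "common": sorted(res_rnc & res_ref),
    }


def intensity_ratio_profile(
    rnc: PeakList,
    reference: PeakList,
    window: int = 3,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-residue intensity ratios I_rnc / I_ref with a moving average.

    ``scale`` multiplies the raw ratio, accounting for any overall
    normalization difference between the two spectra (receiver gain,
    scan count, sample concentration); it defaults to 1 and is reported
    by the caller, never inferred.

    Ratio errors follow first-order propagation of the two spectral-noise
    estimates.  The smoothed profile is a centred moving average of odd
    ``window`` over the residues actually present, shrinking the window at
    the chain ends; rows flagged for a non-positive reference intensity are
    excluded from smoothing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    pairs = match_peaks(rnc, reference)
    if pairs.empty:
        raise ValueError("intensity_ratio_profile requires at least one matched residue")

    i_r = pairs["intensity_a"].to_numpy(float)
    i_ref = pairs["intensity_b"].to_numpy(float)
    n_r = pairs["noise_a"].to_numpy(float)
    n_ref = pairs["noise_b"].to_numpy(float)

    flagged = i_ref <= 0
    ratio = np.full(len(pairs), np.nan)
    err = np.full(len(pairs), np.nan)
    ok = ~flagged
    ratio[ok] = scale * i_r[ok] / i_ref[ok]
    # d(ratio) from independent noise on both intensities; written without
    # dividing by I_rnc so that vanished (zero-intensity) peaks stay finite
    err[ok] = np.sqrt(
        (scale * n_r[ok] / i_ref[ok]) ** 2 + (ratio[ok] * n_ref[ok] / i_ref[ok]) ** 2
    )

    smoothed = np.full(len(pairs), np.nan)
    valid_idx = np.flatnonzero(ok)
    half = window // 2
    for pos, j in enumerate(valid_idx):
        lo = max(0, pos - half)
        hi = min(len(valid_idx), pos + half + 1)
        smoothed[j] = ratio[valid_idx[lo:hi]].mean()

    return pd.DataFrame(
        {
            "residue_index": pairs["residue_index"].astype(int),
            "ratio": ratio,
            "ratio_error": err,
            "smoothed_ratio": smoothed,
            "flagged": flagged,
        }
    )
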