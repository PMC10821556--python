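"""From centroided peak lists to normalized glycan profiles.

Targeted extraction in the MassyTools style: an optional internal
recalibration against known glycan masses, nearest-peak matching of every
library glycan within a fixed Da tolerance, a signal-to-noise filter, and
total-area normalization so each profile reports every glycan as a
percentage of the summed annotated signal.  Replicate spots of the same
sample are averaged on the percentage scale, which cancels spot-to-spot
differences in total ion yield.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .glycan_core import GlycanAnnotation, MassConfig, theoretical_mz

__all__ = [
    "PeakList",
    "AnnotationConfig",
    "GlycanProfile",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "recalibrate",
    "annotate",
    "normalize_profile",
    "average_replicates",
    "profiles_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks of one MALDI spot: (m/z, intensity) pairs."""

    sample_id: str
    replicate: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class AnnotationConfig:
    """Matching, filtering and calibration settings.

    match_tolerance is an absolute window in Da (0.15 by default, generous
    for reflector-mode TOF data over 1000-4500 m/z).  Peaks below
    sn_threshold x the noise estimate are ignored; the default noise estimate
    is the median intensity of peaks left unmatched by the library (a
    targeted-extraction analogue of a local background), overridable by
    passing an explicit noise level to :func:`annotate`.
    """

    match_tolerance: float = 0.15
    sn_threshold: float = 3.0
    calibration_degree: int = 1
    min_calibrants: int = 5

    def __post_init__(self) -> None:
        if self.match_tolerance <= 0:
            raise ValueError("match tolerance must be positive")
        if self.sn_threshold < 0:
            raise ValueError("S/N threshold must be non-negative")
        if self.calibration_degree not in (0, 1, 2):
            raise ValueError("calibration degree must be 0, 1 or 2")


@dataclass(frozen=True)
class GlycanProfile:
    """Per-sample relative abundances (%) over the glycan library."""

    sample_id: str
    abundances: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances:
            if any(v < 0 for v in self.abundances.values()):
                raise ValueError("abundances must be non-negative")
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"profile must sum to 100, got {total}")

    def __getitem__(self, key: str) -> float:
        return self.abundances.get(key, 0.0)


def read_peaklist_csv(path: Union[str, Path], sample_id: str | None = None, replicate: int | None = None) -> PeakList:
    """Read one spot's peak table (columns mz, intensity).

    If sample id / replicate are not given they are taken from a file name of
    the form ``{sample}_{replicate}.csv``.
    """
    path = Path(path)
    if sample_id is None or replicate is None:
        stem = path.stem
        if "_" not in stem:
            raise ValueError(f"cannot infer sample/replicate from file name {path.name}")
        sample_id, rep = stem.rsplit("_", 1)
        replicate = int(rep)
    df = pd.read_csv(path)
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ValueError(f"{path} must have columns mz, intensity")
    return PeakList(sample_id, replicate, df["mz"].to_numpy(float), df["intensity"].to_numpy(float))


def write_peaklist_csv(pl: PeakList, path: Union[str, Path]) -> None:
    pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity}).to_csv(path, index=False)


def recalibrate(pl: PeakList, calibrant_mzs: Sequence[float], cfg: AnnotationConfig = AnnotationConfig()) -> PeakList:
    """Internal mass recalibration against known glycan m/z values.

    Calibrants are matched to the nearest observed peak within 3x the match
    tolerance; a least-squares polynomial of the configured degree is fitted
    to the mass errors and subtracted from every peak.  With fewer matches
    than ``min_calibrants`` the list is returned unchanged (warning logged);
    the degree is reduced when there are too few matches to support it.
    """
    cal = np.sort(np.asarray(calibrant_mzs, dtype=float))
    if len(pl) == 0 or len(cal) == 0:
        return pl
    window = 3.0 * cfg.match_tolerance
    idx = np.searchsorted(pl.mz, cal)
    matched_obs, matched_err = [], []
    for c, i in zip(cal, idx):
        candidates = [j for j in (i - 1, i) if 0 <= j < len(pl)]
        if not candidates:
            continue
        j = min(candidates, key=lambda j: abs(pl.mz[j] - c))
        if abs(pl.mz[j] - c) <= window:
            matched_obs.append(pl.mz[j])
            matched_err.append(pl.mz[j] - c)
    n = len(matched_obs)
    if n < cfg.min_calibrants:
        log.warning(
            "recalibrate(%s_%d): only %d calibrants matched (< %d), leaving masses unchanged",
            pl.sample_id, pl.replicate, n, cfg.min_calibrants,
        )
        return pl
    degree = min(cfg.calibration_degree, n - 1)
    coeffs = np.polyfit(np.asarray(matched_obs), np.asarray(matched_err), degree)
    corrected = pl.mz - np.polyval(coeffs, pl.mz)
    return PeakList(pl.sample_id, pl.replicate, corrected, pl.intensity.copy())


def annotate(
    pl: PeakList,
    library: Iterable[GlycanAnnotation],
    mass_cfg: MassConfig = MassConfig(),
    ann_cfg: AnnotationConfig = AnnotationConfig(),
    noise: float | None = None,
) -> Dict[str, float]:
    """Assign each library glycan the intensity of its matching peak.

    Matching is injective: each glycan takes the nearest peak within
    tolerance and each peak serves at most one glycan; conflicts are resolved
    globally by ascending |mass error|, ties toward the lower-m/z glycan.
    Peaks failing the S/N filter are invisible to matching.  Unmatched
    glycans get intensity 0.
    """
    lib = sorted(library, key=lambda a: theoretical_mz(a.composition, mass_cfg))
    targets = np.array([theoretical_mz(a.composition, mass_cfg) for a in lib])
    keys = [a.key for a in lib]
    result: Dict[str, float] = {k: 0.0 for k in keys}
    if len(pl) == 0 or not keys:
        return result

    # candidate (glycan, peak) pairs within tolerance
    pairs: list[Tuple[float, float, int, int]] = []  # (|err|, glycan m/z, glycan idx, peak idx)
    lo = np.searchsorted(pl.mz, targets - ann_cfg.match_tolerance, side="left")
    hi = np.searchsorted(pl.mz, targets + ann_cfg.match_tolerance, side="right")
    for gi, (a, b) in enumerate(zip(lo, hi)):
        for pi in range(a, b):
            pairs.append((abs(pl.mz[pi] - targets[gi]), targets[gi], gi, pi))

    if noise is None:
        matched_peaks = {pi for *_, pi in pairs}
        unmatched = [pl.intensity[i] for i in range(len(pl)) if i not in matched_peaks]
        noise = float(np.median(unmatched)) if unmatched else 0.0
    floor = ann_cfg.sn_threshold * noise

    taken_glycans: set[int] = set()
    taken_peaks: set[int] = set()
    for err, gmz, gi, pi in sorted(pairs):
        if gi in taken_glycans or pi in taken_peaks:
            continue
        if pl.intensity[pi] < floor:
            continue
        result[keys[gi]] = float(pl.intensity[pi])
        taken_glycans.add(gi)
        taken_peaks.add(pi)
    return result


def normalize_profile(raw: Mapping[str, float], sample_id: str = "") -> GlycanProfile:
    """Total-area normalization: each glycan as % of summed annotated signal."""
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError(f"no annotated signal for sample {sample_id!r}")
    return GlycanProfile(sample_id, {k: 100.0 * v / total for k, v in raw.items()})


def average_replicates(profiles: Sequence[GlycanProfile]) -> GlycanProfile:
    """Mean of replicate-spot profiles (on the % scale), renormalized to 100."""
    if not profiles:
        raise ValueError("no profiles to average")
    ids = {p.sample_id for p in profiles}
    if len(ids) != 1:
        raise ValueError(f"replicates from different samples: {sorted(ids)}")
    keys = sorted(set().union(*(p.abundances.keys() for p in profiles)))
    mean = {k: float(np.mean([p[k] for p in profiles])) for k in keys}
    return normalize_profile(mean, profiles[0].sample_id)


def profiles_to_frame(profiles: Sequence[GlycanProfile]) -> pd.DataFrame:
    """Samples x glycans matrix of percentages (missing glycans -> 0)."""
    keys = sorted(set().union(*(p.abundances.keys() for p in profiles))) if profiles else []
    data = {p.sample_id: [p[k] for k in keys] for p in profiles}
    return pd.DataFrame(data, index=keys).T
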