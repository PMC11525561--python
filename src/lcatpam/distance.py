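"""Residue-pair distance series and their summarization.

The conformational biomarker is the α-carbon distance between two residues of
LCAT's membrane-binding domain (CYS50 and ASN65 by default).  Two
summarization schemes are provided, matching the two ways replicate MD data
are reduced to a mean ± SEM:

* :func:`block_summary` — one long trajectory split into contiguous blocks
  (block averaging; e.g. a 1 µs run split into ten 100 ns blocks), where the
  spread of block means estimates the SEM of a correlated series;
* :func:`replicate_summary` — several independent replicate runs, each
  averaged over an analysis window (e.g. the last 100 ns of each 200 ns
  replicate), with the SEM taken across replicate means.

Both use the n−1 sample standard deviation of the member means divided by
√n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import TrajectoryFrames, get_alpha_carbon

__all__ = [
    "DistanceSeries",
    "ReplicateSummary",
    "distance_series",
    "window_select",
    "last_half_window",
    "block_summary",
    "replicate_summary",
]

#: Å per nm
_NM = 10.0


@dataclass
class DistanceSeries:
    """A per-frame scalar distance with its time axis.

    values carry the unit named in ``unit`` ("nm" or "angstrom").
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "nm"
    pair_label: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.unit not in ("nm", "angstrom"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if np.any(self.values < 0):
            raise ValueError("distances cannot be negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ReplicateSummary:
    """Mean ± SEM over block or replicate means."""

    mean: float
    sem: float
    n: int
    member_means: list[float]
    window: tuple[float, float] | None = None
    unit: str = "nm"
    pair_label: str = ""

    def __post_init__(self) -> None:
        if self.n != len(self.member_means):
            raise ValueError("n must equal the number of member means")
        if self.sem < 0:
            raise ValueError("sem cannot be negative")


def distance_series(
    frames: TrajectoryFrames,
    residue_a: int,
    residue_b: int,
    chain_a: str | None = None,
    chain_b: str | None = None,
    unit: str = "nm",
) -> DistanceSeries:
    """Per-frame Euclidean CA–CA distance between two residues.

    For single-atom groups this equals the minimum inter-group distance
    reported by standard MD analysis tools.  The reporting ``unit`` is nm by
    default (coordinates are Å internally).
    """
    a = get_alpha_carbon(frames, residue_a, chain_a)
    b = get_alpha_carbon(frames, residue_b, chain_b)
    d = np.linalg.norm(a - b, axis=1)  # Å
    if unit == "nm":
        d = d / _NM
    elif unit != "angstrom":
        raise ValueError(f"unknown unit {unit!r}")

    def _name(resnum: int) -> str:
        for key in frames.roster:
            if key.residue_number == resnum and key.atom_name == "CA":
                return f"{key.residue_name}{resnum}"
        return str(resnum)

    return DistanceSeries(
        times=frames.times.copy(),
        values=d,
        unit=unit,
        pair_label=f"{_name(residue_a)}-{_name(residue_b)}",
        replicate_id=frames.source_label,
    )


def window_select(series: DistanceSeries, t_start: float, t_end: float) -> DistanceSeries:
    """Restrict a series to the half-open time window [t_start, t_end).

    The half-open convention makes "the last 100 ns of a 200 ns run"
    unambiguous: ``window_select(s, 100, 200 + eps)`` keeps frames stamped
    100 ns onward including the final one (see :func:`last_half_window`).
    """
    if not t_start < t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    mask = (series.times >= t_start) & (series.times < t_end)
    if not mask.any():
        raise ValueError(
            f"window [{t_start}, {t_end}) selects no frames; series spans "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    return DistanceSeries(
        times=series.times[mask],
        values=series.values[mask],
        unit=series.unit,
        pair_label=series.pair_label,
        replicate_id=series.replicate_id,
    )


def last_half_window(series: DistanceSeries) -> tuple[float, float]:
    """Window covering the second half of the series' time span.

    The end is nudged past the final timestamp so the last frame is kept
    under the half-open convention.
    """
    t0, t1 = float(series.times[0]), float(series.times[-1])
    span = t1 - t0
    end = t1 + max(1e-9, 1e-9 * abs(t1))
    return (t0 + span / 2.0, end)


def _mean_sem(member_means: np.ndarray) -> tuple[float, float]:
    n = len(member_means)
    mean = float(np.mean(member_means))
    sem = float(np.std(member_means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


def block_summary(series: DistanceSeries, n_blocks: int = 10) -> ReplicateSummary:
    """Block-average a single series: mean and SEM of contiguous block means.

    The series is partitioned into ``n_blocks`` contiguous blocks of equal
    frame count; remainder frames go to the final block (so no frame is
    dropped).
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    n = len(series)
    if n_blocks > n:
        raise ValueError(f"n_blocks ({n_blocks}) exceeds frame count ({n})")
    size = n // n_blocks
    member_means = []
    for b in range(n_blocks):
        start = b * size
        stop = (b + 1) * size if b < n_blocks - 1 else n
        member_means.append(float(np.mean(series.values[start:stop])))
    mean, sem = _mean_sem(np.asarray(member_means))
    return ReplicateSummary(
        mean=mean,
        sem=sem,
        n=n_blocks,
        member_means=member_means,
        window=(float(series.times[0]), float(series.times[-1])),
        unit=series.unit,
        pair_label=series.pair_label,
    )


def replicate_summary(
    series_list: list[DistanceSeries],
    window: tuple[float, float] | None = None,
) -> ReplicateSummary:
    """Mean ± SEM across replicate runs, each averaged over a time window.

    ``window=None`` analyses the second half of each replicate (the
    "last 100 ns of 200 ns" protocol); an explicit ``(t_start, t_end)`` in ns
    is applied half-open to every replicate.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 replicates")
    units = {s.unit for s in series_list}
    if len(units) > 1:
        raise ValueError(f"replicates mix units: {sorted(units)}")
    member_means = []
    applied: tuple[float, float] | None = window
    for s in series_list:
        win = window if window is not None else last_half_window(s)
        try:
            sub = window_select(s, *win)
        except ValueError as exc:
            raise ValueError(
                f"replicate {s.replicate_id or '?'}: {exc}"
            ) from None
        member_means.append(sub.mean)
        if window is None:
            applied = win
    mean, sem = _mean_sem(np.asarray(member_means))
    return ReplicateSummary(
        mean=mean,
        sem=sem,
        n=len(member_means),
        member_means=member_means,
        window=applied,
        unit=series_list[0].unit,
        pair_label=series_list[0].pair_label,
    )
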