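"""Raw trace to calibrated, target-bound peaks.

Peak detection is deliberately simple (rolling-minimum baseline subtraction
followed by local-maximum picking): the assay's design rules guarantee that
same-dye amplicons are well separated, so no deconvolution is needed.  Size
calibration maps scan position to fragment length through the in-lane ladder
(piecewise-linear interpolation between matched ladder points), and binding
assigns each calibrated peak to at most one panel target by dye and size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .panel import PanelDefinition
from .peakio import Peak, SampleTrace

__all__ = [
    "SizeCalibration",
    "BindingResult",
    "LadderFailure",
    "detect_peaks",
    "fit_size_ladder",
    "assign_sizes",
    "bind_peaks",
]

ABSENT = None


class LadderFailure(RuntimeError):
    """Size-standard calibration failed; the sample is uninterpretable."""


@dataclass
class SizeCalibration:
    """Monotone scan -> bp mapping through matched ladder points."""

    ladder_points: list[tuple[float, float]]  # (scan_position, known size bp)
    residuals: np.ndarray                     # bp, versus a smooth global fit

    def __post_init__(self) -> None:
        scans = [s for s, _ in self.ladder_points]
        sizes = [b for _, b in self.ladder_points]
        if any(b <= a for a, b in zip(scans, scans[1:])):
            raise LadderFailure("ladder scan positions are not strictly increasing")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise LadderFailure("ladder sizes are not strictly increasing")
        self._scans = np.asarray(scans, dtype=float)
        self._sizes = np.asarray(sizes, dtype=float)

    def __call__(self, scan) -> np.ndarray | float:
        """Interpolate bp at scan position(s), linearly extrapolating at ends."""
        scan = np.asarray(scan, dtype=float)
        out = np.interp(scan, self._scans, self._sizes)
        lo_slope = (self._sizes[1] - self._sizes[0]) / (self._scans[1] - self._scans[0])
        hi_slope = (self._sizes[-1] - self._sizes[-2]) / (self._scans[-1] - self._scans[-2])
        out = np.where(
            scan < self._scans[0],
            self._sizes[0] + (scan - self._scans[0]) * lo_slope,
            out,
        )
        out = np.where(
            scan > self._scans[-1],
            self._sizes[-1] + (scan - self._scans[-1]) * hi_slope,
            out,
        )
        return out if out.ndim else float(out)

    def bp_range(self, extrapolation_bp: float = 0.0) -> tuple[float, float]:
        return (self._sizes[0] - extrapolation_bp, self._sizes[-1] + extrapolation_bp)


def detect_peaks(
    trace: SampleTrace,
    min_height: float = 200.0,
    min_prominence: float = 100.0,
    window: int = 51,
) -> list[Peak]:
    """Detect uncalibrated peaks per dye channel.

    Baseline is the rolling minimum over ``window`` scans, clamped so the
    corrected signal is non-negative.  A peak is a local maximum of the
    corrected signal with height >= ``min_height`` and prominence >=
    ``min_prominence``.
    """
    if window < 1 or window > trace.scan_count:
        raise ValueError(
            f"baseline window {window} outside 1..{trace.scan_count} scans"
        )
    peaks: list[Peak] = []
    for dye, signal in trace.signals.items():
        baseline = minimum_filter1d(signal, size=window, mode="nearest")
        corrected = np.clip(signal - baseline, 0.0, None)
        idx, props = find_peaks(corrected, height=min_height, prominence=min_prominence)
        for i, h in zip(idx, props["peak_heights"]):
            peaks.append(
                Peak(dye=dye, size=math.nan, height=float(h), scan_position=int(i))
            )
    return peaks


def _match_ladder(
    scans: np.ndarray, heights: np.ndarray, ladder_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match detected LIZ peaks to known ladder sizes.

    With at least as many peaks as ladder fragments, the tallest
    ``len(ladder)`` peaks are taken in scan order.  With fewer, every
    contiguous window of ladder sizes is tried and the one whose affine
    scan->bp fit has the smallest residual wins.
    """
    n = len(ladder_sizes)
    if len(scans) >= n:
        keep = np.sort(np.argsort(heights)[-n:])
        return scans[keep], ladder_sizes
    best = None
    for start in range(n - len(scans) + 1):
        candidate = ladder_sizes[start:start + len(scans)]
        coeffs = np.polyfit(scans, candidate, 1)
        resid = candidate - np.polyval(coeffs, scans)
        score = float(np.abs(resid).max())
        if best is None or score < best[0]:
            best = (score, candidate)
    return scans, best[1]


def fit_size_ladder(
    liz_peaks: list[Peak],
    ladder_sizes,
    min_ladder_points: int = 8,
    residual_tolerance: float = 1.0,
) -> SizeCalibration:
    """Calibrate scan -> bp from detected LIZ-channel peaks.

    Raises :class:`LadderFailure` when fewer than ``min_ladder_points`` peaks
    match or when residuals against a smooth (quadratic) migration fit exceed
    ``residual_tolerance`` bp.
    """
    ladder_sizes = np.asarray(sorted(float(s) for s in ladder_sizes))
    usable = [p for p in liz_peaks if p.scan_position is not None]
    if len(usable) < max(min_ladder_points, 4):
        raise LadderFailure(
            f"only {len(usable)} ladder peaks detected "
            f"(minimum {max(min_ladder_points, 4)})"
        )
    usable.sort(key=lambda p: p.scan_position)
    scans = np.array([p.scan_position for p in usable], dtype=float)
    heights = np.array([p.height for p in usable], dtype=float)
    matched_scans, matched_sizes = _match_ladder(scans, heights, ladder_sizes)
    if len(matched_scans) < min_ladder_points:
        raise LadderFailure(
            f"only {len(matched_scans)} ladder points matched "
            f"(minimum {min_ladder_points})"
        )
    coeffs = np.polyfit(matched_scans, matched_sizes, 2)
    residuals = matched_sizes - np.polyval(coeffs, matched_scans)
    if float(np.abs(residuals).max()) > residual_tolerance:
        raise LadderFailure(
            f"ladder residuals up to {np.abs(residuals).max():.2f} bp exceed "
            f"tolerance {residual_tolerance} bp"
        )
    return SizeCalibration(
        ladder_points=list(zip(matched_scans.tolist(), matched_sizes.tolist())),
        residuals=residuals,
    )


def assign_sizes(
    peaks: list[Peak],
    calibration: SizeCalibration,
    extrapolation_bp: float = 20.0,
) -> list[Peak]:
    """Return new peaks with ``size`` set from scan position.

    LIZ peaks are passed through unchanged.  Peaks sizing beyond the
    calibrated range plus ``extrapolation_bp`` are flagged OUT_OF_RANGE.
    """
    lo, hi = calibration.bp_range(extrapolation_bp)
    out: list[Peak] = []
    for p in peaks:
        if p.dye == "LIZ" or p.scan_position is None:
            out.append(p)
            continue
        size = float(calibration(p.scan_position))
        flags = set(p.flags)
        if not (lo <= size <= hi):
            flags.add("OUT_OF_RANGE")
        out.append(Peak(
            dye=p.dye, size=size, height=p.height, area=p.area,
            scan_position=p.scan_position, flags=flags,
        ))
    return out


@dataclass
class BindingResult:
    """Assignment of calibrated peaks to panel targets."""

    assignments: dict[str, Peak | None]
    orphans: list[Peak] = field(default_factory=list)

    def height(self, target_name: str) -> float:
        peak = self.assignments.get(target_name)
        return 0.0 if peak is None else peak.height

    def present(self, target_name: str, min_height: float = 0.0) -> bool:
        peak = self.assignments.get(target_name)
        return peak is not None and peak.height >= min_height


def bind_peaks(peaks: list[Peak], panel: PanelDefinition) -> BindingResult:
    """Bind each panel target to the best in-tolerance peak of its dye.

    Targets are processed in ascending expected size; each peak is assigned at
    most once.  The best candidate is the tallest in-tolerance peak, ties
    broken by smaller size error, then smaller size.  Absence is data, not an
    error.  The result is independent of the input peak ordering.
    """
    candidates = sorted(
        (p for p in peaks if p.dye != "LIZ" and p.calibrated),
        key=lambda p: (p.size, p.height),
    )
    assigned: set[int] = set()
    assignments: dict[str, Peak | None] = {}
    targets = sorted(
        (t for t in panel.targets), key=lambda t: (t.expected_size, t.name)
    )
    for target in targets:
        best = None
        best_key = None
        for i, p in enumerate(candidates):
            if i in assigned or p.dye != target.dye:
                continue
            err = abs(p.size - target.expected_size)
            if err > panel.size_tolerance:
                continue
            key = (-p.height, err, p.size)
            if best_key is None or key < best_key:
                best, best_key = i, key
        if best is None:
            assignments[target.name] = ABSENT
        else:
            assignments[target.name] = candidates[best]
            assigned.add(best)
    orphans = [p for i, p in enumerate(candidates) if i not in assigned]
    return BindingResult(assignments=assignments, orphans=orphans)
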