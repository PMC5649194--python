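"""From raw force-distance curves to the derived nanomechanical quantities.

The pipeline stages mirror a force-volume / single-molecule force
spectroscopy workflow: baseline correction, contact-point detection on
approach traces, adhesion-event detection on retract traces, routing of
curves to the FJC (single event) or WLC (multiple events) model, and the
summary statistics — modal Young's modulus with Gaussian σ, adhesion-event
frequency, and contour-length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .force_models import HertzFit, PolymerModelFit

__all__ = [
    "ForceCurve",
    "ForceVolumeMap",
    "AdhesionEvent",
    "ModulusDistribution",
    "correct_baseline",
    "find_contact_point",
    "detect_adhesion_events",
    "classify_curve",
    "segment_retract",
    "modal_modulus",
    "adhesion_frequency",
    "contour_length_distribution",
]

#: Fraction of the separation range (far side) treated as the non-contact region.
NONCONTACT_FRACTION = 0.30
#: Default minimum rupture distance (nm) for an event to count as specific.
MIN_SPECIFIC_DISTANCE_NM = 5.0


@dataclass
class ForceCurve:
    """One approach/retract pair of (separation_nm, force_pN) traces.

    Approach is ordered far→near (separation decreasing), retract near→far.
    ``meta`` carries acquisition metadata: spring constant (N/m), approach
    speed (µm/s) and the force-volume grid index when the curve belongs to a
    map.
    """

    approach: np.ndarray
    retract: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.approach = np.asarray(self.approach, dtype=float)
        self.retract = np.asarray(self.retract, dtype=float)
        for name, trace, sign in (("approach", self.approach, -1), ("retract", self.retract, +1)):
            if trace.ndim != 2 or trace.shape[1] != 2 or trace.shape[0] < 20:
                raise ValueError(f"{name} trace must be an (n>=20, 2) array")
            d = np.diff(trace[:, 0])
            if not (np.all(sign * d > 0)):
                raise ValueError(f"{name} separations must be strictly monotone "
                                 f"({'decreasing' if sign < 0 else 'increasing'})")
        k = self.meta.get("spring_constant_N_per_m")
        if k is not None and not (0.005 <= k <= 0.1):
            raise ValueError(f"spring constant {k} N/m outside [0.005, 0.1]")


@dataclass
class ForceVolumeMap:
    """Grid of force curves recorded over one cell (rows × cols)."""

    rows: int
    cols: int
    curves: list

    def __post_init__(self) -> None:
        if len(self.curves) != self.rows * self.cols:
            raise ValueError(f"expected {self.rows * self.cols} curves, got {len(self.curves)}")


@dataclass
class AdhesionEvent:
    """A single unbinding event on a retract trace.

    ``rupture_force_pN`` is the unsigned peak adhesion force;
    ``rupture_distance_nm`` the separation at which the force returns to
    baseline (the tether detaches).  Events closer than 5 nm to contact are
    nonspecific tip–surface snap-offs (``specific=False``).
    """

    rupture_force_pN: float
    rupture_distance_nm: float
    segment_span: tuple
    specific: bool


@dataclass
class ModulusDistribution:
    """Gaussian-mode summary of a set of fitted Young's moduli."""

    mode_kPa: float
    sigma_kPa: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_fits: int
    gaussian_ok: bool = True


# ---------------------------------------------------------------------------
# Trace conditioning
# ---------------------------------------------------------------------------

def _noncontact_mask(sep: np.ndarray, fraction: float = NONCONTACT_FRACTION) -> np.ndarray:
    """Outer (far-side) fraction of the separation range."""
    span = sep.max() - sep.min()
    if span <= 0:
        raise ValueError("trace has zero separation span")
    return sep >= sep.max() - fraction * span


def correct_baseline(trace: np.ndarray,
                     noncontact_fraction: float = NONCONTACT_FRACTION) -> np.ndarray:
    """Subtract a straight line fitted to the non-contact (far) region.

    Returns a new (n, 2) trace whose far-field mean force is ~0.  Raises on
    traces with zero separation span.  ``noncontact_fraction`` widens the
    fitted region; the default outer 30% is safe generally, but long retract
    traces whose fingerprints occupy only the near end benefit from a wider
    window — extrapolating a short far-end line across the whole trace adds
    a per-curve pN-scale offset that biases downstream polymer fits.
    """
    t = np.asarray(trace, dtype=float)
    sep, force = t[:, 0], t[:, 1]
    mask = _noncontact_mask(sep, noncontact_fraction)
    coef = np.polyfit(sep[mask], force[mask], 1)
    out = t.copy()
    out[:, 1] = force - np.polyval(coef, sep)
    return out


def noise_sd(trace: np.ndarray) -> float:
    """Robust force-noise SD from the non-contact region (MAD-based)."""
    t = np.asarray(trace, dtype=float)
    resid = t[:, 1][_noncontact_mask(t[:, 0])]
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def find_contact_point(curve_approach: np.ndarray,
                       min_run: int = 5) -> float | None:
    """Locate the tip–sample contact point on a baseline-corrected approach.

    Scanning far→near, returns the first separation at which the force
    exceeds 3×σ_noise and stays above it for at least ``min_run`` consecutive
    samples.  Returns ``None`` when no such crossing exists (no contact).
    """
    t = np.asarray(curve_approach, dtype=float)
    order = np.argsort(t[:, 0])[::-1]  # far → near
    sep, force = t[order, 0], t[order, 1]
    sigma = noise_sd(t)
    thresh = 3.0 * sigma if sigma > 0 else 0.0
    above = force > thresh if thresh > 0 else force > 0
    n = len(above)
    for i in range(n):
        if above[i] and np.all(above[i:min(i + min_run, n)]) and n - i >= min_run:
            return float(sep[i])
    return None


# ---------------------------------------------------------------------------
# Adhesion events
# ---------------------------------------------------------------------------

def detect_adhesion_events(curve_retract: np.ndarray,
                           min_force_pN: float | None = None,
                           min_distance_nm: float = MIN_SPECIFIC_DISTANCE_NM,
                           merge_gap_points: int = 10,
                           min_width_points: int = 3,
                           ) -> list[AdhesionEvent]:
    """Find unbinding events on a baseline-corrected retract trace.

    An event is a run of force below −``min_force_pN`` (default 3×σ_noise);
    its rupture force is the unsigned minimum of the run and its rupture
    distance the separation just past the run, where the force returns to
    baseline.  Two robustness controls handle noisy traces: below-threshold
    runs separated by fewer than ``merge_gap_points`` samples are merged
    (threshold chatter inside one tether), and merged runs with fewer than
    ``min_width_points`` below-threshold samples are discarded (isolated
    noise spikes).  Events with rupture distance below ``min_distance_nm``
    are marked nonspecific (tip–surface snap-off rather than a tether).
    """
    t = np.asarray(curve_retract, dtype=float)
    order = np.argsort(t[:, 0])  # near → far
    sep, force = t[order, 0], t[order, 1]
    if min_force_pN is None:
        sigma = noise_sd(t)
        min_force_pN = 3.0 * sigma if sigma > 0 else 1e-9
    below = force < -min_force_pN
    n = len(below)
    # raw below-threshold runs
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # Merge runs separated by short above-threshold gaps, but only when the
    # force stays clearly below baseline across the gap (threshold chatter on
    # a tether's rising flank).  After a genuine rupture the force returns to
    # ~0, so a deep peak followed by a baseline gap is never merged.
    merged: list[list[int]] = []
    for run in runs:
        if merged:
            gap = slice(merged[-1][1] + 1, run[0])
            if run[0] - merged[-1][1] - 1 < merge_gap_points and \
                    np.all(force[gap] < 0.0):
                merged[-1][1] = run[1]
                continue
        merged.append(run)
    events: list[AdhesionEvent] = []
    for i, j in merged:
        if int(below[i:j + 1].sum()) < min_width_points:
            continue
        peak = float(-force[i:j + 1].min())
        rupture_sep = float(sep[min(j + 1, n - 1)])
        events.append(AdhesionEvent(
            rupture_force_pN=peak,
            rupture_distance_nm=rupture_sep,
            segment_span=(int(i), int(j)),
            specific=rupture_sep >= min_distance_nm,
        ))
    return events


def classify_curve(events: list[AdhesionEvent]) -> str:
    """Route a retract curve by its specific-event count.

    0 → ``"none"``; 1 → ``"single"`` (FJC model); ≥2 → ``"multiple"`` (WLC).
    """
    n = sum(1 for e in events if e.specific)
    return "none" if n == 0 else ("single" if n == 1 else "multiple")


def segment_retract(curve_retract: np.ndarray,
                    events: list[AdhesionEvent]) -> list[np.ndarray]:
    """Cut a retract trace into per-event (extension, pulling-force) segments.

    Each segment runs from the previous rupture (or contact, x=0) to the
    event's own rupture, with the adhesive force sign flipped to positive
    pulling force — the form the polymer fitters consume.  Only specific
    events yield segments; shorter-than-5-point segments are dropped.
    """
    t = np.asarray(curve_retract, dtype=float)
    order = np.argsort(t[:, 0])
    sep, force = t[order, 0], t[order, 1]
    segments = []
    prev_rupture = 0.0
    for ev in sorted((e for e in events if e.specific),
                     key=lambda e: e.rupture_distance_nm):
        mask = (sep >= prev_rupture) & (sep < ev.rupture_distance_nm) & (force < 0)
        if int(mask.sum()) >= 5:
            segments.append(np.column_stack([sep[mask], -force[mask]]))
        prev_rupture = ev.rupture_distance_nm
    return segments


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def modal_modulus(fits: list[HertzFit]) -> ModulusDistribution:
    """Modal Young's modulus: Gaussian fitted to the modulus histogram.

    Builds a Freedman–Diaconis histogram of converged fits and least-squares
    fits a single Gaussian to the bin counts; the fitted mean is the reported
    mode (the position of the Gaussian's maximum) and the fitted σ its width.
    Falls back to the histogram argmax (ties broken toward lower modulus,
    σ=NaN) if the Gaussian fit fails.  Requires ≥30 converged fits.
    """
    values = np.array([f.youngs_modulus_kPa for f in fits if f.converged], dtype=float)
    if values.size < 30:
        raise ValueError(f"need >=30 converged fits, got {values.size}")
    if np.ptp(values) == 0:  # degenerate: all identical
        v = float(values[0])
        edges = np.array([v - 0.5, v + 0.5])
        return ModulusDistribution(v, 0.0, edges, np.array([values.size]), values.size)
    counts, edges = np.histogram(values, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gaussian, centers, counts,
            p0=[counts.max(), centers[np.argmax(counts)], values.std()],
            maxfev=10000,
        )
        mode, sigma = float(popt[1]), float(abs(popt[2]))
        ok = np.isfinite(mode) and np.isfinite(sigma) and edges[0] <= mode <= edges[-1]
    except RuntimeError:
        ok = False
    if not ok:
        mode = float(centers[np.argmax(counts)])  # argmax; ties -> lower modulus
        sigma = float("nan")
    return ModulusDistribution(mode, sigma, edges, counts, values.size, gaussian_ok=ok)


def adhesion_frequency(curves_events: list[list[AdhesionEvent]]) -> float:
    """Percent of curves with at least one specific adhesion event."""
    if not curves_events:
        raise ValueError("no curves provided")
    with_event = sum(1 for evs in curves_events
                     if any(e.specific for e in evs))
    return 100.0 * with_event / len(curves_events)


def contour_length_distribution(fits: list[PolymerModelFit],
                                bins="fd") -> tuple[np.ndarray, np.ndarray, float, float]:
    """Histogram plus mean ± SD of fitted contour lengths (converged fits only).

    Returns ``(bin_edges, counts, mean_nm, sd_nm)``.
    """
    values = np.array([f.contour_length_nm for f in fits if f.converged], dtype=float)
    if values.size == 0:
        raise ValueError("no converged polymer fits")
    if np.ptp(values) == 0:
        v = float(values[0])
        return np.array([v - 0.5, v + 0.5]), np.array([values.size]), v, 0.0
    counts, edges = np.histogram(values, bins=bins)
    return edges, counts, float(values.mean()), float(values.std(ddof=1))
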