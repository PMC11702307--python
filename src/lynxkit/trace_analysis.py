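"""Extraction of rupture events and dynamic force spectra from AFM pulling traces.

An AFM pulling cycle has four phases: approach of the functionalized
cantilever to the cell, a dwell during which a ligand–receptor bond may
form, retraction during which a bound complex is loaded at a constant rate,
and rupture.  This module turns calibrated traces (real or synthesized)
into :class:`RuptureEvent` records, builds rupture-force histograms whose
modes estimate the most probable unbinding force, and assembles grouped
dynamic-force-spectrum datasets ready for Bell–Evans fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bell_evans import DfsPoint
from .constants import DEFAULT_TEMPERATURE, thermal_energy

__all__ = [
    "ForceTrace",
    "RuptureEvent",
    "ForceHistogram",
    "DfsDataset",
    "calibrate_spring_constant",
    "detect_rupture",
    "build_force_histogram",
    "assemble_dfs",
]

PHASES = ("approach", "dwell", "retract")

#: A rupture is called when a single-step force drop exceeds this multiple
#: of the baseline noise SD.
RUPTURE_THRESHOLD_SD = 5.0

#: Fraction of the pre-rupture ramp used for the system-spring-constant fit.
RAMP_FIT_WINDOW = (0.50, 0.95)

#: Fraction of the retract phase (from its end) used for the post-rupture
#: baseline estimate.
BASELINE_TAIL_FRACTION = 0.25

DEFAULT_BIN_WIDTH = 5.0  # pN


@dataclass
class ForceTrace:
    """One force–displacement record with phase labels.

    ``displacement`` is the piezo position in nm (monotone non-decreasing
    during retraction), ``force`` the cantilever force in pN, and ``phase``
    a per-sample label in {approach, dwell, retract}.
    """

    displacement: np.ndarray  # nm
    force: np.ndarray  # pN
    phase: np.ndarray  # str labels
    retraction_speed: float  # nm/s
    sample_rate: float  # Hz
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.displacement)
        if len(self.force) != n or len(self.phase) != n:
            raise ValueError("displacement, force and phase must have equal length")
        if not self.retraction_speed > 0:
            raise ValueError("retraction_speed must be positive")
        bad = set(self.phase) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def retract_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phase == "retract")


@dataclass(frozen=True)
class RuptureEvent:
    """A single unbinding measurement extracted from one trace."""

    unbinding_force: float  # Fu, pN
    system_spring_constant: float  # ks, pN/nm
    loading_rate: float  # pN/s
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        if not self.unbinding_force > 0:
            raise ValueError("unbinding force must be positive")
        if not self.system_spring_constant > 0:
            raise ValueError("system spring constant must be positive")


@dataclass(frozen=True)
class ForceHistogram:
    """Fixed-width rupture-force histogram with its mode.

    The mode is the center of the maximal-count bin (ties broken toward the
    lowest-force bin); its uncertainty is half the bin width.
    """

    bin_edges: np.ndarray  # pN
    counts: np.ndarray
    mode: float  # pN
    uncertainty: float  # half bin width, pN


@dataclass(frozen=True)
class DfsDataset:
    """Grouped dynamic force spectrum: one DfsPoint per loading-rate group."""

    points: tuple
    group_sizes: tuple
    #: indices of groups with fewer than the minimum recommended event count
    sparse_groups: tuple = ()


def calibrate_spring_constant(
    thermal_deflection,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Equipartition estimate of cantilever stiffness from thermal noise.

    By equipartition, a cantilever in thermal equilibrium fluctuates with
    ⟨x²⟩ = kBT/k about its rest position, so ``k = kBT / var(deflection)``
    (variance about the series mean).  Deflections in nm, result in pN/nm.
    """
    x = np.asarray(thermal_deflection, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 samples, got {x.size}")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        raise ValueError("zero-variance deflection series: not a thermal trace")
    return thermal_energy(temperature) / var


def detect_rupture(trace: ForceTrace, noise_sd: float) -> RuptureEvent | None:
    """Locate the rupture step in the retract phase of a trace.

    The rupture is the largest single-step force drop between adjacent
    retract samples, provided it exceeds ``RUPTURE_THRESHOLD_SD × noise_sd``.
    The system spring constant is the slope of a linear fit of force
    against displacement over the 50%–95% window of the pre-rupture ramp.
    The unbinding force is the pre-rupture force minus the post-rupture
    baseline (median of the trailing portion of the retract phase); the
    pre-rupture force is read from the fitted ramp evaluated at the last
    loaded sample, which averages out single-sample noise while matching
    the raw reading exactly on clean traces.  The loading rate is
    ks × retraction speed.

    Returns None when no step exceeds the threshold (no adhesion).
    """
    idx = trace.retract_indices()
    if idx.size < 4:
        raise ValueError("trace has no usable retract phase")
    force = trace.force[idx]
    disp = trace.displacement[idx]

    drops = force[:-1] - force[1:]  # positive = force drop
    i_drop = int(np.argmax(drops))
    if drops[i_drop] <= RUPTURE_THRESHOLD_SD * noise_sd:
        return None

    n = force.size
    tail_start = max(i_drop + 1, int(np.floor((1.0 - BASELINE_TAIL_FRACTION) * n)))
    baseline = float(np.median(force[tail_start:]))

    lo = int(np.floor(RAMP_FIT_WINDOW[0] * (i_drop + 1)))
    hi = max(lo + 2, int(np.ceil(RAMP_FIT_WINDOW[1] * (i_drop + 1))))
    ramp = slice(lo, min(hi, i_drop + 1))
    ks, offset = np.polyfit(disp[ramp], force[ramp], 1)
    ks = float(ks)
    # pre-rupture force from the fitted ramp at the last loaded sample
    fu = float(ks * disp[i_drop] + offset - baseline)
    if fu <= 0 or ks <= 0:
        return None

    return RuptureEvent(
        unbinding_force=fu,
        system_spring_constant=ks,
        loading_rate=ks * trace.retraction_speed,
        trace_id=trace.trace_id,
    )


def build_force_histogram(forces, bin_width: float = DEFAULT_BIN_WIDTH) -> ForceHistogram:
    """Histogram of rupture forces in fixed-width bins anchored at 0 pN."""
    f = np.asarray(forces, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one force")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil((f.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, edges = np.histogram(f, bins=edges)
    i_mode = int(np.argmax(counts))  # argmax takes the first maximum: low-force tie-break
    return ForceHistogram(
        bin_edges=edges,
        counts=counts,
        mode=0.5 * (edges[i_mode] + edges[i_mode + 1]),
        uncertainty=bin_width / 2.0,
    )


def assemble_dfs(
    events,
    n_groups: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_group_events: int = 10,
) -> DfsDataset:
    """Group rupture events by loading rate into a dynamic force spectrum.

    Events are partitioned into ``n_groups`` equal-width bins in
    ln(loading rate) (default: the number of distinct loading rates).  Each
    non-empty group yields one :class:`~lynxkit.bell_evans.DfsPoint` whose
    loading rate is the geometric mean of member rates and whose f* is the
    mode of the member-force histogram at ``bin_width``.  Groups with fewer
    than ``min_group_events`` events are flagged in ``sparse_groups``.
    """
    events = list(events)
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    rates = np.array([e.loading_rate for e in events], dtype=float)
    forces = np.array([e.unbinding_force for e in events], dtype=float)
    if n_groups is None:
        n_groups = len(np.unique(rates))
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    log_r = np.log(rates)
    lo, hi = log_r.min(), log_r.max()
    if n_groups > 1 and lo == hi:
        raise ValueError("events span a single loading rate; use n_groups=1")
    if n_groups == 1:
        group_of = np.zeros(rates.size, dtype=int)
    else:
        edges = np.linspace(lo, hi, n_groups + 1)
        group_of = np.clip(np.searchsorted(edges, log_r, side="right") - 1, 0, n_groups - 1)

    points, sizes, sparse = [], [], []
    for g in range(n_groups):
        members = group_of == g
        m = int(members.sum())
        if m == 0:
            continue
        geo_rate = float(np.exp(log_r[members].mean()))
        hist = build_force_histogram(forces[members], bin_width=bin_width)
        points.append(DfsPoint(geo_rate, hist.mode, hist.uncertainty))
        sizes.append(m)
        if m < min_group_events:
            sparse.append(len(points) - 1)
    if len(points) < 2 and n_groups > 1:
        raise ValueError("grouping produced fewer than 2 non-empty groups")
    return DfsDataset(points=tuple(points), group_sizes=tuple(sizes), sparse_groups=tuple(sparse))
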