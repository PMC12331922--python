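"""Design of staggered-window DIA acquisition schemes.

A *staggered* (overlapping) DIA method acquires two interleaved banks of
isolation windows offset by half a window width.  After demultiplexing, the
effective precursor selectivity is half the nominal window width: the
half-width *demux bins* tile the target precursor range and every bin is
sampled by two distinct windows, one per bank.

The canonical method built here is the 24 m/z staggered scheme covering
400-1000 m/z (52 windows per cycle, 12 m/z effective bins) and its
gas-phase-fractionated (GPF) variant: six 102 m/z precursor segments with
2 m/z inter-segment overlap, each acquired with 52 staggered 4 m/z windows.

Window-count convention
-----------------------
For a target range ``[mz_min, mz_max]``, window width ``w`` and stagger
``s = w/2`` the scheme has ``n_bins = (mz_max - mz_min)/s`` demux bins and
``n_bins + 2`` windows with lower edges::

    lower_k = mz_min - s + k * s,   k = 0 .. n_bins + 1

Even ``k`` forms the *offset* bank (bank 0, shifted half a width below the
range), odd ``k`` the *aligned* bank (bank 1).  Every in-range demux bin is
covered by exactly two windows; exactly two windows (the lowest and the
second-highest) cover a single in-range bin, and the top edge window covers
none -- it exists so that both banks carry one edge window beyond the range.
Acquisition order alternates banks window-by-window, ascending in m/z.

All m/z intervals are half-open ``[lower, upper)``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

__all__ = [
    "AVERAGINE_SPACING",
    "IsolationWindow",
    "WindowScheme",
    "GPFPlan",
    "ConcatenationPlan",
    "build_staggered_scheme",
    "build_gpf_plan",
    "snap_to_forbidden_zone",
    "plan_concatenation",
    "fraction_count",
    "export_isolation_list",
    "read_isolation_list",
]

#: Average mass spacing (Th) between consecutive isotopic "allowed" zones of
#: tryptic peptides (averagine mass-defect periodicity).
AVERAGINE_SPACING = 1.00045475

_DIV_TOL = 1e-6


@dataclass(frozen=True)
class IsolationWindow:
    """One quadrupole isolation window within an acquisition cycle.

    ``bank`` is 0 for the offset bank (shifted half a width below the target
    range) and 1 for the aligned bank; ``order`` is the acquisition position
    of the window's MS2 scan within the cycle (MS1 scans not counted).
    """

    lower_mz: float
    upper_mz: float
    bank: int
    order: int

    @property
    def width(self) -> float:
        return self.upper_mz - self.lower_mz

    @property
    def center(self) -> float:
        return 0.5 * (self.lower_mz + self.upper_mz)

    def contains(self, mz: float) -> bool:
        return self.lower_mz <= mz < self.upper_mz


@dataclass
class WindowScheme:
    """Ordered staggered isolation windows for one acquisition cycle."""

    mz_min: float
    mz_max: float
    width: float
    ms1_every: int = 26
    windows: list[IsolationWindow] = field(default_factory=list)

    @property
    def stagger(self) -> float:
        return self.width / 2.0

    @property
    def span(self) -> float:
        return self.mz_max - self.mz_min

    @property
    def n_bins(self) -> int:
        return int(round(self.span / self.stagger))

    @property
    def demux_bins(self) -> list[tuple[float, float]]:
        """Half-width bins tiling ``[mz_min, mz_max)`` without gaps."""
        s = self.stagger
        return [
            (self.mz_min + j * s, self.mz_min + (j + 1) * s)
            for j in range(self.n_bins)
        ]

    def bin_index(self, mz: float) -> int | None:
        """Demux bin containing ``mz`` (nominal geometry), or None."""
        if not (self.mz_min <= mz < self.mz_max):
            return None
        return int((mz - self.mz_min) // self.stagger)

    def windows_covering(self, mz: float) -> list[IsolationWindow]:
        return [w for w in self.windows if w.contains(mz)]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mz_min": self.mz_min,
            "mz_max": self.mz_max,
            "width": self.width,
            "ms1_every": self.ms1_every,
            "windows": [
                [w.lower_mz, w.upper_mz, w.bank, w.order] for w in self.windows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowScheme":
        scheme = cls(d["mz_min"], d["mz_max"], d["width"], d.get("ms1_every", 26))
        scheme.windows = [
            IsolationWindow(lo, hi, int(b), int(o)) for lo, hi, b, o in d["windows"]
        ]
        return scheme

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "WindowScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GPFPlan:
    """Gas-phase fractionation plan: overlapping precursor segments, each
    acquired in a separate injection with its own staggered scheme."""

    segments: list[tuple[tuple[float, float], WindowScheme]]
    step: float
    overlap: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_for(self, mz: float) -> list[int]:
        """Indices of segments whose scheme isolates precursor ``mz``."""
        hits = []
        for k, (_rng, scheme) in enumerate(self.segments):
            if scheme.windows_covering(mz):
                hits.append(k)
        return hits

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "overlap": self.overlap,
            "segments": [
                {"range": list(rng), "scheme": scheme.to_dict()}
                for rng, scheme in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPFPlan":
        segs = [
            (tuple(s["range"]), WindowScheme.from_dict(s["scheme"]))
            for s in d["segments"]
        ]
        return cls(segs, d["step"], d["overlap"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GPFPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ConcatenationPlan:
    """Round-robin pooling of offline high-pH fractions.

    Fraction ``i`` goes to pool ``i mod n_pools`` so that each pool combines
    early, middle and late eluters -- maximizing orthogonality between the
    basic (high-pH) and acidic (low-pH) separations.
    """

    n_fractions: int
    n_pools: int
    assignment: dict[int, int]

    def pools(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_pools)]
        for frac, pool in sorted(self.assignment.items()):
            out[pool].append(frac)
        return out


def build_staggered_scheme(
    mz_min: float,
    mz_max: float,
    width: float,
    ms1_every: int = 26,
    snap_boundaries: bool = False,
    reference_charge: int = 2,
) -> WindowScheme:
    """Build a staggered-window scheme over ``[mz_min, mz_max]``.

    Produces ``(mz_max - mz_min)/(width/2) + 2`` windows in two interleaved
    banks (see module docstring).  With ``snap_boundaries`` the window edges
    are moved onto the peptide forbidden-zone grid (quarter-offset averagine
    grid at ``reference_charge``); the nominal geometry used for demux-bin
    mapping is kept unsnapped.

    Examples
    --------
    >>> len(build_staggered_scheme(400, 1000, 24).windows)
    52
    >>> len(build_staggered_scheme(400, 500, 4).windows)
    52
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if mz_max <= mz_min:
        raise ValueError("mz_max must exceed mz_min")
    span = mz_max - mz_min
    if span < width:
        raise ValueError(
            f"degenerate range: span {span} Th is smaller than one window ({width} Th)"
        )
    stagger = width / 2.0
    ratio = span / stagger
    if abs(ratio - round(ratio)) > _DIV_TOL:
        raise ValueError(
            f"span {span} Th is not divisible by the stagger {stagger} Th"
        )
    n_bins = int(round(ratio))

    scheme = WindowScheme(mz_min, mz_max, width, ms1_every)
    for k in range(n_bins + 2):
        lower = mz_min - stagger + k * stagger
        upper = lower + width
        if snap_boundaries:
            lower = snap_to_forbidden_zone(lower, reference_charge)
            upper = snap_to_forbidden_zone(upper, reference_charge)
        scheme.windows.append(IsolationWindow(lower, upper, bank=k % 2, order=k))
    return scheme


def build_gpf_plan(
    mz_min: float,
    mz_max: float,
    n_segments: int,
    overlap: float,
    window_width: float,
    ms1_every: int = 26,
) -> GPFPlan:
    """Plan gas-phase fractionation: ``n_segments`` precursor segments of
    width ``step + overlap`` (``step = span / n_segments``), each carrying a
    staggered scheme of ``window_width`` built on the segment's unique span.

    >>> plan = build_gpf_plan(400, 1000, 6, 2, 4)
    >>> plan.n_segments, plan.segments[0][0]
    (6, (400.0, 502.0))
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    span = mz_max - mz_min
    if span <= 0:
        raise ValueError("mz_max must exceed mz_min")
    step = span / n_segments
    if abs(span / n_segments - round(span / n_segments, 9)) > _DIV_TOL:
        raise ValueError("span must be divisible by the segment count")
    if n_segments > 1 and overlap >= step:
        raise ValueError("overlap must be smaller than the segment step")
    if window_width > step:
        raise ValueError("window width larger than segment span")

    segments = []
    for k in range(n_segments):
        lo = mz_min + k * step
        hi = lo + step + overlap
        scheme = build_staggered_scheme(lo, lo + step, window_width, ms1_every)
        segments.append(((float(lo), float(hi)), scheme))
    return GPFPlan(segments, step, overlap)


def snap_to_forbidden_zone(
    boundary: float,
    reference_charge: int = 2,
    spacing: float = AVERAGINE_SPACING,
) -> float:
    """Move ``boundary`` to the nearest peptide forbidden-zone grid point.

    Tryptic peptide precursor m/z values cluster near multiples of the
    averagine spacing divided by the charge; the quarter-offset points
    ``(k + 0.25) * spacing / z`` fall between those clusters, so window edges
    placed there cut through the fewest precursors.  The shift is bounded by
    half the grid pitch, ``spacing / (2 z)``.
    """
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    if reference_charge not in (2, 3):
        raise ValueError("reference charge must be 2 or 3")
    pitch = spacing / reference_charge
    k = round(boundary / pitch - 0.25)
    return (k + 0.25) * pitch


def plan_concatenation(n_fractions: int, n_pools: int) -> ConcatenationPlan:
    """Round-robin concatenation of ``n_fractions`` into ``n_pools`` pools.

    >>> plan_concatenation(18, 6).pools()[0]
    [0, 6, 12]
    """
    if n_pools < 1:
        raise ValueError("need at least one pool")
    if n_pools > n_fractions:
        raise ValueError("more pools than fractions")
    assignment = {i: i % n_pools for i in range(n_fractions)}
    return ConcatenationPlan(n_fractions, n_pools, assignment)


def fraction_count(collect_minutes: float, interval_seconds: float) -> int:
    """Number of fractions collected over ``collect_minutes`` at one fraction
    every ``interval_seconds`` (e.g. 42 min every 140 s -> 18 fractions)."""
    if interval_seconds <= 0:
        raise ValueError("collection interval must be positive")
    if collect_minutes < 0:
        raise ValueError("collection time must be non-negative")
    return int(math.floor(collect_minutes * 60.0 / interval_seconds))


def export_isolation_list(scheme: WindowScheme, path) -> None:
    """Write the scheme as an isolation-list CSV (center, width, bank, order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["center_mz", "width_mz", "bank", "order"])
        for w in scheme.windows:
            writer.writerow([repr(w.center), repr(w.width), w.bank, w.order])


def read_isolation_list(path, ms1_every: int = 26) -> WindowScheme:
    """Rebuild a scheme from an isolation-list CSV.

    The nominal range is re-derived from the window geometry; for schemes
    exported without forbidden-zone snapping the round-trip is lossless.
    ``ms1_every`` is not stored in the CSV (use the JSON scheme file to keep
    it).
    """
    windows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            center = float(row["center_mz"])
            width = float(row["width_mz"])
            windows.append(
                IsolationWindow(
                    center - width / 2.0,
                    center + width / 2.0,
                    int(row["bank"]),
                    int(row["order"]),
                )
            )
    if not windows:
        raise ValueError("empty isolation list")
    windows.sort(key=lambda w: w.order)
    width = windows[0].width
    stagger = width / 2.0
    mz_min = min(w.lower_mz for w in windows) + stagger
    mz_max = max(w.lower_mz for w in windows)
    scheme = WindowScheme(mz_min, mz_max, width, ms1_every)
    scheme.windows = windows
    return scheme
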