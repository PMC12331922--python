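"""Demultiplexing of staggered-window DIA spectra.

Each half-width demux bin of a staggered scheme is sampled by two isolation
windows (one per bank) acquired at slightly different retention times.  For
every acquisition cycle and every fragment m/z channel we solve the small
non-negative least-squares system

    min || A x - y ||^2   subject to  x >= 0

where ``A`` is the window-to-bin incidence matrix, ``y`` the (time-aligned)
window readings for that channel and ``x`` the per-bin channel intensities.
Window readings are linearly interpolated between that window's scans in
neighbouring cycles to the cycle's reference retention time, so banks
acquired at different phases of the duty cycle are compared at a common
time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .run_io import Run, Spectrum
from .scheme_design import WindowScheme

__all__ = ["BinMap", "DemuxSpectrum", "build_bin_map", "demultiplex_run", "group_channels"]


#: window acquisition order -> indices of in-range demux bins it covers
BinMap = dict[int, tuple[int, ...]]


@dataclass
class DemuxSpectrum:
    """Demultiplexed pseudo-spectrum for one demux bin at one cycle."""

    bin_index: int
    bin_range: tuple[float, float]
    rt: float
    cycle: int
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    flagged: bool = False

    def match(self, target_mz: float, tol_ppm: float) -> float:
        if self.mz.size == 0:
            return 0.0
        tol = target_mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.mz, target_mz - tol, side="left")
        hi = np.searchsorted(self.mz, target_mz + tol, side="right")
        return float(self.intensity[lo:hi].sum()) if hi > lo else 0.0


def build_bin_map(scheme: WindowScheme) -> BinMap:
    """Map each window (by acquisition order) to the in-range demux bins it
    covers under the nominal (unsnapped) geometry."""
    if not scheme.windows:
        raise ValueError("scheme has no windows")
    s = scheme.stagger
    n = scheme.n_bins
    bmap: BinMap = {}
    for w in scheme.windows:
        # nominal lower edge from the order index, robust to snapped edges
        lower = scheme.mz_min - s + w.order * s
        first = int(round((lower - scheme.mz_min) / s))
        bins = tuple(j for j in (first, first + 1) if 0 <= j < n)
        bmap[w.order] = bins
    return bmap


def group_channels(
    peaks_mz: np.ndarray, peaks_int: np.ndarray, tol_ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy 1-D clustering of peaks into fragment channels.

    Peaks sorted by m/z are swept once; a peak starts a new channel when it
    lies more than ``tol_ppm`` away from the running intensity-weighted
    centroid of the current channel.  Returns (centroids, labels).
    """
    order = np.argsort(peaks_mz, kind="stable")
    mz = peaks_mz[order]
    inten = peaks_int[order]
    labels_sorted = np.empty(mz.size, dtype=int)
    centroids: list[float] = []
    cur_w = 0.0
    cur_wm = 0.0
    for i in range(mz.size):
        if centroids:
            cen = cur_wm / cur_w if cur_w > 0 else centroids[-1]
            if abs(mz[i] - cen) <= cen * tol_ppm * 1e-6:
                labels_sorted[i] = len(centroids) - 1
                cur_w += max(inten[i], 1e-30)
                cur_wm += max(inten[i], 1e-30) * mz[i]
                centroids[-1] = cur_wm / cur_w
                continue
        centroids.append(mz[i])
        labels_sorted[i] = len(centroids) - 1
        cur_w = max(inten[i], 1e-30)
        cur_wm = cur_w * mz[i]
    labels = np.empty_like(labels_sorted)
    labels[order] = labels_sorted
    return np.asarray(centroids), labels


def _interpolated_reading(
    spec: Spectrum,
    neighbor: Spectrum | None,
    t_ref: float,
    channel_mz: float,
    tol_ppm: float,
) -> float:
    """Channel intensity of a window at ``t_ref``, linearly interpolating
    between the window's in-cycle scan and its bracketing neighbour."""
    y0 = spec.match(channel_mz, tol_ppm)
    if neighbor is None or abs(spec.rt - t_ref) < 1e-9:
        return y0
    y1 = neighbor.match(channel_mz, tol_ppm)
    dt = neighbor.rt - spec.rt
    if abs(dt) < 1e-12:
        return y0
    frac = (t_ref - spec.rt) / dt
    return (1.0 - frac) * y0 + frac * y1


def demultiplex_run(
    run: Run,
    scheme: WindowScheme,
    tol_ppm: float = 10.0,
    ridge_lambda: float = 1e-6,
    noise_floor: float = 0.0,
) -> list[DemuxSpectrum]:
    """Demultiplex all cycles of a staggered run onto half-width bins.

    Parameters
    ----------
    tol_ppm : fragment channel grouping tolerance.
    ridge_lambda : relative Tikhonov weight used only when a channel's
        system is underdetermined (e.g. missing scans); affected bins are
        flagged.
    noise_floor : solved intensities at or below this value are dropped.

    Returns one :class:`DemuxSpectrum` per (cycle, bin) with signal, plus
    empty spectra for signal-free bins omitted.
    """
    bmap = build_bin_map(scheme)
    n_windows = len(scheme.windows)
    bins = scheme.demux_bins
    bin_windows: dict[int, list[int]] = {}
    for order, covered in bmap.items():
        for b in covered:
            bin_windows.setdefault(b, []).append(order)

    ms2 = [s for s in run.ms2()]
    for s in ms2:
        if s.window_index is None or not (0 <= s.window_index < n_windows):
            raise ValueError("MS2 window annotation does not match the scheme")

    by_cycle: dict[int, dict[int, Spectrum]] = {}
    for s in ms2:
        by_cycle.setdefault(s.cycle, {})[s.window_index] = s
    cycle_ids = sorted(by_cycle)

    out: list[DemuxSpectrum] = []
    for ci, cyc in enumerate(cycle_ids):
        scans = by_cycle[cyc]
        if len(scans) < n_windows // 2:
            warnings.warn(
                f"cycle {cyc}: missing bank ({len(scans)}/{n_windows} scans); skipped",
                stacklevel=2,
            )
            continue
        rts = np.array([s.rt for s in scans.values()])
        t_ref = float(np.median(rts))

        # bracketing neighbour scan per window (for off-phase interpolation)
        neighbors: dict[int, Spectrum | None] = {}
        for order, spec in scans.items():
            nb = None
            if abs(spec.rt - t_ref) >= 1e-9:
                step = 1 if spec.rt < t_ref else -1
                j = ci + step
                if 0 <= j < len(cycle_ids):
                    nb = by_cycle[cycle_ids[j]].get(order)
            neighbors[order] = nb

        # fragment channels across the whole cycle
        mz_all = np.concatenate([s.mz for s in scans.values()]) if scans else np.empty(0)
        if mz_all.size == 0:
            continue
        int_all = np.concatenate([s.intensity for s in scans.values()])
        centroids, _ = group_channels(mz_all, int_all, tol_ppm)

        acc: dict[int, tuple[list[float], list[float], bool]] = {}
        for cmz in centroids:
            readings = {
                order: _interpolated_reading(
                    scans[order], neighbors[order], t_ref, cmz, tol_ppm
                )
                for order in scans
            }
            hot = [o for o, y in readings.items() if y > 0 and bmap[o]]
            if not hot:
                continue
            # a zero-reading window pins its bins to zero, so the unknowns
            # are the bins whose present covering windows all carry signal
            candidate = sorted({b for o in hot for b in bmap[o]})
            comp_bins = []
            for b in candidate:
                present = [o for o in bin_windows[b] if o in scans]
                if present and all(readings[o] > 0 for o in present):
                    comp_bins.append(b)
            if not comp_bins:
                continue
            comp_windows = sorted(
                {o for b in comp_bins for o in bin_windows[b] if o in scans}
            )
            col = {b: j for j, b in enumerate(comp_bins)}
            a = np.zeros((len(comp_windows), len(comp_bins)))
            y = np.zeros(len(comp_windows))
            for i, o in enumerate(comp_windows):
                y[i] = readings[o]
                for b in bmap[o]:
                    if b in col:  # other bins of this window are pinned to 0
                        a[i, col[b]] = 1.0
            flagged = False
            if a.shape[0] < a.shape[1]:
                lam = ridge_lambda * max(y.max(), 1.0)
                a = np.vstack([a, np.sqrt(lam) * np.eye(a.shape[1])])
                y = np.concatenate([y, np.zeros(a.shape[1])])
                flagged = True
            x, _ = nnls(a, y)
            for b, j in col.items():
                if x[j] > noise_floor and x[j] > 0:
                    mzs, ints, fl = acc.setdefault(b, ([], [], False))
                    mzs.append(float(cmz))
                    ints.append(float(x[j]))
                    if flagged:
                        acc[b] = (mzs, ints, True)

        for b in sorted(acc):
            mzs, ints, fl = acc[b]
            order_ = np.argsort(mzs)
            out.append(
                DemuxSpectrum(
                    bin_index=b,
                    bin_range=bins[b],
                    rt=t_ref,
                    cycle=cyc,
                    mz=np.asarray(mzs)[order_],
                    intensity=np.asarray(ints)[order_],
                    flagged=fl,
                )
            )
    return out
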