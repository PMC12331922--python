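"""In-memory DIA run container and (de)serialization.

A :class:`Run` is a time-ordered list of centroided MS1/MS2 spectra.  MS2
spectra carry the acquisition-order index of their isolation window within
the scheme and a cycle counter.  Runs round-trip through a plain JSON format;
mzML files (read-only, centroid spectra) are imported via pyteomics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .scheme_design import WindowScheme

__all__ = ["Spectrum", "Run", "read_mzml", "annotate_windows"]


@dataclass
class Spectrum:
    ms_level: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    window_index: int | None = None  # MS2 only: scheme window `order`
    cycle: int = 0

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def match(self, target_mz: float, tol_ppm: float) -> float:
        """Summed intensity of peaks within ``tol_ppm`` of ``target_mz``."""
        if self.mz.size == 0:
            return 0.0
        tol = target_mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.mz, target_mz - tol, side="left")
        hi = np.searchsorted(self.mz, target_mz + tol, side="right")
        if hi <= lo:
            return 0.0
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    run_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def cycles(self) -> dict[int, list[Spectrum]]:
        out: dict[int, list[Spectrum]] = {}
        for s in self.spectra:
            out.setdefault(s.cycle, []).append(s)
        return out

    def ms2_tic(self) -> float:
        return float(sum(s.tic for s in self.ms2()))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "meta": self.meta,
            "spectra": [
                {
                    "ms_level": s.ms_level,
                    "rt": s.rt,
                    "mz": [float(x) for x in s.mz],
                    "intensity": [float(x) for x in s.intensity],
                    "window_index": s.window_index,
                    "cycle": s.cycle,
                }
                for s in self.spectra
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Run":
        run = cls(d["run_id"], meta=d.get("meta", {}))
        for s in d["spectra"]:
            run.spectra.append(
                Spectrum(
                    ms_level=int(s["ms_level"]),
                    rt=float(s["rt"]),
                    mz=np.asarray(s["mz"], dtype=float),
                    intensity=np.asarray(s["intensity"], dtype=float),
                    window_index=s.get("window_index"),
                    cycle=int(s.get("cycle", 0)),
                )
            )
        return run

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Run":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def read_mzml(path, run_id: str | None = None) -> Run:
    """Import an mzML file (centroided spectra) as a :class:`Run`.

    Only scan level, retention time, peak lists and the isolation-window
    target m/z are read.  Window indices are left unset; call
    :func:`annotate_windows` with the matching scheme afterwards.
    """
    from pyteomics import mzml  # deferred: optional heavyweight parse

    run = Run(run_id or str(path))
    with mzml.MzML(str(path)) as reader:
        for spec in reader:
            level = int(spec.get("ms level", 1))
            rt = float(
                spec["scanList"]["scan"][0].get("scan start time", 0.0)
            )
            # mzML scan start time is conventionally minutes
            rt_s = rt * 60.0
            target = None
            if level == 2:
                try:
                    isol = spec["precursorList"]["precursor"][0][
                        "isolationWindow"
                    ]
                    target = float(isol["isolation window target m/z"])
                except (KeyError, IndexError):
                    target = None
            sp = Spectrum(
                ms_level=level,
                rt=rt_s,
                mz=np.asarray(spec["m/z array"], dtype=float),
                intensity=np.asarray(spec["intensity array"], dtype=float),
            )
            if target is not None:
                sp.window_index = -1  # placeholder until annotated
                sp.__dict__["_isolation_target"] = target
            run.spectra.append(sp)
    return run


def annotate_windows(run: Run, scheme: WindowScheme, cycle_from_order: bool = True) -> Run:
    """Assign scheme window indices (and cycles) to MS2 spectra in place.

    Matches each MS2 spectrum's isolation target (or window center stored at
    import) to the nearest window center.  Cycles are inferred by counting
    wrap-arounds of the acquisition order.
    """
    centers = np.array([w.center for w in scheme.windows])
    cycle = 0
    prev_order = -1
    for s in run.spectra:
        if s.ms_level != 2:
            continue
        target = s.__dict__.get("_isolation_target")
        if target is None:
            if s.window_index is None:
                raise ValueError("MS2 spectrum lacks isolation information")
            continue
        order = int(np.argmin(np.abs(centers - target)))
        if cycle_from_order and order <= prev_order:
            cycle += 1
        prev_order = order
        s.window_index = order
        s.cycle = cycle
    return run
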