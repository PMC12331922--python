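"""Ion-chromatogram libraries: assembly, iRT calibration, XIC extraction and
target-decoy scoring.

A library entry stores, per precursor (sequence, modification, charge): the
3-6 most intense b/y fragment coordinates with relative intensities, the
indexed retention time (iRT) and the protein mapping.  The library carries an
affine iRT-to-RT calibration with a residual scale from which the extracted
ion chromatogram (XIC) retention-time window is derived -- hybrid libraries
(fraction runs augmented with unfractionated mixed-sample runs) refit the
calibration on the mixed runs and therefore tighten the XIC windows.

Scoring is peptide-centric: library entries are queried against the run, each
candidate receives the cosine similarity between library and observed
fragment intensity patterns multiplied by a fragment co-elution term, and
q-values come from target-decoy competition with mass-shifted,
intensity-shuffled decoys.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demultiplex import DemuxSpectrum
from .run_io import Run
from .synthetic_data import Fragment, SyntheticPeptide

__all__ = [
    "LibraryEntry",
    "RtCalibration",
    "IonLibrary",
    "Identification",
    "XicSet",
    "entries_from_peptides",
    "calibrate_irt",
    "assemble_library",
    "extract_xics",
    "score_and_fdr",
    "write_library_tsv",
    "read_library_tsv",
    "identifications_to_frame",
]

Key = tuple[str, str, int]  # (sequence, modification, charge)


@dataclass
class LibraryEntry:
    sequence: str
    modification: str
    charge: int
    precursor_mz: float
    irt: float
    fragments: list[Fragment]
    protein_id: str
    provenance: set[str] = field(default_factory=set)

    @property
    def key(self) -> Key:
        return (self.sequence, self.modification, self.charge)


@dataclass
class RtCalibration:
    """Affine iRT -> RT (seconds) map with a residual scale."""

    slope: float
    intercept: float
    residual_sd: float

    def __call__(self, irt: float) -> float:
        return self.slope * irt + self.intercept


@dataclass
class IonLibrary:
    entries: dict[Key, LibraryEntry]
    rt_calibration: RtCalibration
    xic_window_minutes: float
    mode: str = "direct"  # 'HpH-hybrid' | 'GPF-hybrid' | 'direct' | ...
    provenance: dict = field(default_factory=dict)

    def proteins(self) -> set[str]:
        return {e.protein_id for e in self.entries.values()}


@dataclass
class Identification:
    key: Key
    run_id: str
    apex_rt: float
    score: float
    q_value: float
    fragment_areas: np.ndarray
    protein_id: str = ""


def entries_from_peptides(peptides: list[SyntheticPeptide]) -> dict[Key, LibraryEntry]:
    """Library entries from simulator ground-truth peptides (duplicate keys
    collapse to the first occurrence)."""
    out: dict[Key, LibraryEntry] = {}
    for p in peptides:
        key = (p.sequence, "", p.charge)
        if key in out:
            continue
        out[key] = LibraryEntry(
            sequence=p.sequence,
            modification="",
            charge=p.charge,
            precursor_mz=p.precursor_mz,
            irt=p.irt,
            fragments=list(p.fragments),
            protein_id=p.protein_id,
        )
    return out


def calibrate_irt(anchors: list[tuple[float, float]]) -> RtCalibration:
    """Robust affine fit of observed RT against iRT.

    Least absolute deviations (median regression) at five or more anchors,
    ordinary least squares below that.  Raises on fewer than three anchors or
    degenerate (constant-iRT) anchor sets.
    """
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors")
    irt = np.array([a[0] for a in anchors], dtype=float)
    rt = np.array([a[1] for a in anchors], dtype=float)
    if np.ptp(irt) < 1e-12:
        raise ValueError("degenerate anchors: no iRT spread")
    if len(anchors) >= 5:
        import statsmodels.api as sm

        x = sm.add_constant(irt)
        res = sm.QuantReg(rt, x).fit(q=0.5)
        intercept, slope = float(res.params[0]), float(res.params[1])
    else:
        slope, intercept = (float(v) for v in np.polyfit(irt, rt, 1))
    resid = rt - (slope * irt + intercept)
    sd = float(np.std(resid, ddof=min(2, len(anchors) - 1)))
    return RtCalibration(slope, intercept, sd)


def _apex_rt(source, entry: LibraryEntry, tol_ppm: float) -> tuple[float, float] | None:
    """(apex RT, apex summed fragment intensity) of an entry in a run or
    demultiplexed spectrum list; None when the precursor is never isolated or
    carries no signal."""
    spectra = _select_spectra(source, entry.precursor_mz)
    best_rt, best_val = None, 0.0
    for s in spectra:
        val = sum(s.match(f.mz, tol_ppm) for f in entry.fragments)
        if val > best_val:
            best_rt, best_val = s.rt, val
    if best_rt is None:
        return None
    return best_rt, best_val


def _select_spectra(source, precursor_mz: float):
    """Spectra of a Run (by covering window) or demuxed list (by bin) that
    isolate the given precursor."""
    if isinstance(source, Run):
        from .scheme_design import WindowScheme

        scheme = WindowScheme.from_dict(source.meta["scheme"])
        orders = {w.order for w in scheme.windows_covering(precursor_mz)}
        return [s for s in source.ms2() if s.window_index in orders]
    # list of DemuxSpectrum
    return [
        s
        for s in source
        if isinstance(s, DemuxSpectrum)
        and s.bin_range[0] <= precursor_mz < s.bin_range[1]
    ]


def assemble_library(
    fraction_runs: list[Run],
    mixed_runs: list[Run],
    entries: dict[Key, LibraryEntry] | list[SyntheticPeptide],
    mode: str = "GPF-hybrid",
    k_sigma: float = 3.0,
    tol_ppm: float = 10.0,
    min_window_minutes: float = 0.5,
) -> IonLibrary:
    """Assemble an ion-chromatogram library from fraction runs, optionally
    hybridized with unfractionated mixed-sample runs.

    Entries (simulator ground truth or an imported transition list) are kept
    when observed in at least one fraction run; duplicates across fractions
    collapse onto one key with pooled provenance.  The iRT calibration is fit
    on (iRT, apex RT) anchors -- taken from the mixed runs when present
    (hybrid mode), otherwise from the fraction runs -- and the XIC window is
    ``2 * k_sigma * residual SD`` of that fit, floored at
    ``min_window_minutes``.
    """
    if not fraction_runs and not mixed_runs:
        raise ValueError("need at least one source run")
    if not isinstance(entries, dict):
        entries = entries_from_peptides(entries)
    if not entries:
        raise ValueError("empty entry source")

    pooled: dict[Key, LibraryEntry] = {}
    frac_anchor: dict[Key, tuple[float, float]] = {}
    source_runs = fraction_runs if fraction_runs else mixed_runs
    for run in source_runs:
        for key, entry in entries.items():
            hit = _apex_rt(run, entry, tol_ppm)
            if hit is None:
                continue
            kept = pooled.setdefault(
                key,
                LibraryEntry(
                    entry.sequence,
                    entry.modification,
                    entry.charge,
                    entry.precursor_mz,
                    entry.irt,
                    list(entry.fragments),
                    entry.protein_id,
                ),
            )
            kept.provenance.add(run.run_id)
            prev = frac_anchor.get(key)
            if prev is None or hit[1] > prev[1]:
                frac_anchor[key] = hit
    if not pooled:
        raise ValueError("no library entries observed in the source runs")

    anchors: list[tuple[float, float]] = []
    if mixed_runs:
        for key, entry in pooled.items():
            obs = [
                h for run in mixed_runs if (h := _apex_rt(run, entry, tol_ppm))
            ]
            if obs:
                anchors.append((entry.irt, float(np.mean([o[0] for o in obs]))))
        used = "mixed"
    if not mixed_runs or len(anchors) < 3:
        anchors = [(pooled[k].irt, frac_anchor[k][0]) for k in pooled]
        used = "fractions"
    cal = calibrate_irt(anchors)
    xic_window = max(2.0 * k_sigma * cal.residual_sd / 60.0, min_window_minutes)

    return IonLibrary(
        entries=pooled,
        rt_calibration=cal,
        xic_window_minutes=xic_window,
        mode=mode,
        provenance={
            "fraction_runs": [r.run_id for r in fraction_runs],
            "mixed_runs": [r.run_id for r in mixed_runs],
            "anchors": used,
            "n_anchors": len(anchors),
        },
    )


@dataclass
class XicSet:
    """Per-entry, per-fragment chromatograms plus the source they came from
    (kept so decoy queries can be extracted from the same data)."""

    traces: dict[Key, tuple[np.ndarray, np.ndarray]]  # key -> (rts, frag x time)
    source: object
    library: IonLibrary
    tol_ppm: float
    run_id: str = "run"


def extract_xics(source, library: IonLibrary, tol_ppm: float = 10.0) -> XicSet:
    """Extract per-fragment intensity traces for every library entry.

    ``source`` is a :class:`Run` (multiplexed: scans of all windows covering
    the precursor are used) or a list of :class:`DemuxSpectrum`.  Traces are
    restricted to the calibrated RT window; entries whose precursor is never
    isolated get empty traces.
    """
    run_id = source.run_id if isinstance(source, Run) else "demuxed"
    half = library.xic_window_minutes * 60.0 / 2.0
    traces: dict[Key, tuple[np.ndarray, np.ndarray]] = {}
    for key, entry in library.entries.items():
        center = library.rt_calibration(entry.irt)
        spectra = [
            s
            for s in _select_spectra(source, entry.precursor_mz)
            if abs(s.rt - center) <= half
        ]
        spectra.sort(key=lambda s: s.rt)
        rts = np.array([s.rt for s in spectra])
        mat = np.zeros((len(entry.fragments), len(spectra)))
        for j, s in enumerate(spectra):
            for i, frag in enumerate(entry.fragments):
                mat[i, j] = s.match(frag.mz, tol_ppm)
        traces[key] = (rts, mat)
    return XicSet(traces, source, library, tol_ppm, run_id)


def _decoy_entry(entry: LibraryEntry, tag: int, mz_shift: float = 10.0) -> LibraryEntry:
    """Decoy: fragments shifted by a fixed m/z offset with shuffled relative
    intensities (deterministic per entry key and tag)."""
    seed = int.from_bytes(
        hashlib.sha256(
            f"{entry.sequence}/{entry.charge}#{tag}".encode()
        ).digest()[:4],
        "little",
    )
    rng = np.random.default_rng(seed)
    rels = np.array([f.rel_intensity for f in entry.fragments])
    rng.shuffle(rels)
    frags = [
        Fragment(f.ion_type, f.index, f.mz + mz_shift, float(r))
        for f, r in zip(entry.fragments, rels)
    ]
    return LibraryEntry(
        sequence=f"DECOY{tag}_{entry.sequence}",
        modification=entry.modification,
        charge=entry.charge,
        precursor_mz=entry.precursor_mz,
        irt=entry.irt,
        fragments=frags,
        protein_id=f"DECOY_{entry.protein_id}",
    )


def _score_traces(rts: np.ndarray, mat: np.ndarray, lib_rels: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(score, apex RT, fragment areas) for one candidate.

    Score = cosine(library pattern, fragment areas) x mean pairwise Pearson
    correlation of the fragment traces (co-elution), clipped to [0, 1].
    """
    if mat.size == 0 or mat.sum() <= 0:
        return 0.0, float("nan"), np.zeros(lib_rels.size)
    total = mat.sum(axis=0)
    apex = float(rts[int(np.argmax(total))])
    if mat.shape[1] > 1:
        areas = np.trapezoid(mat, rts, axis=1)
    else:
        areas = mat[:, 0].astype(float)
    na, nl = np.linalg.norm(areas), np.linalg.norm(lib_rels)
    cos = float(areas @ lib_rels / (na * nl)) if na > 0 and nl > 0 else 0.0
    nf = mat.shape[0]
    if nf < 2 or mat.shape[1] < 3:
        coel = 1.0 if cos > 0 else 0.0
    else:
        sd = mat.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            coel = 0.0
        else:
            c = np.corrcoef(mat[ok])
            iu = np.triu_indices_from(c, k=1)
            coel = float(np.nanmean(c[iu]))
    score = max(cos, 0.0) * max(coel, 0.0)
    return score, apex, areas


def score_and_fdr(
    xics: XicSet,
    library: IonLibrary | None = None,
    decoy_factor: int = 1,
    q_threshold: float = 0.01,
    report_all: bool = False,
) -> list[Identification]:
    """Score extracted chromatograms and assign target-decoy q-values.

    For each library entry, ``decoy_factor`` decoys (fragment m/z + 10 Th,
    shuffled intensities) are extracted from the same source and scored
    identically.  q(s) is the minimum over thresholds t <= s of
    ``#decoys(score >= t) / (decoy_factor * #targets(score >= t))``, so
    q-values increase monotonically as the score decreases.  Identifications
    at ``q <= q_threshold`` are returned (all targets with
    ``report_all=True``); ties break deterministically by entry key.
    """
    if decoy_factor < 1:
        raise ValueError("decoy_factor must be >= 1")
    library = library or xics.library

    records: list[tuple[float, int, tuple, Identification | None]] = []
    for key in sorted(library.entries):
        entry = library.entries[key]
        lib_rels = np.array([f.rel_intensity for f in entry.fragments])
        rts, mat = xics.traces[key]
        score, apex, areas = _score_traces(rts, mat, lib_rels)
        ident = Identification(
            key=key,
            run_id=xics.run_id,
            apex_rt=apex,
            score=score,
            q_value=1.0,
            fragment_areas=areas,
            protein_id=entry.protein_id,
        )
        records.append((score, 1, key, ident))
        center = library.rt_calibration(entry.irt)
        half = library.xic_window_minutes * 60.0 / 2.0
        for tag in range(decoy_factor):
            dec = _decoy_entry(entry, tag)
            spectra = [
                s
                for s in _select_spectra(xics.source, dec.precursor_mz)
                if abs(s.rt - center) <= half
            ]
            spectra.sort(key=lambda s: s.rt)
            drts = np.array([s.rt for s in spectra])
            dmat = np.zeros((len(dec.fragments), len(spectra)))
            for j, s in enumerate(spectra):
                for i, frag in enumerate(dec.fragments):
                    dmat[i, j] = s.match(frag.mz, xics.tol_ppm)
            dscore, _, _ = _score_traces(
                drts, dmat, np.array([f.rel_intensity for f in dec.fragments])
            )
            records.append((dscore, 0, (f"DECOY{tag}",) + key, None))

    # descending score; decoys outrank targets on exact ties (conservative)
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    n_t = n_d = 0
    raw_fdr: list[float] = []
    target_rows: list[int] = []
    for i, (score, is_target, _, ident) in enumerate(records):
        if is_target:
            n_t += 1
            target_rows.append(i)
        else:
            n_d += 1
        raw_fdr.append(n_d / (decoy_factor * max(n_t, 1)))
    # q-value: reverse cumulative minimum
    qs = np.minimum.accumulate(np.asarray(raw_fdr)[::-1])[::-1]

    out: list[Identification] = []
    for i in target_rows:
        ident = records[i][3]
        ident.q_value = float(min(qs[i], 1.0))
        if report_all or ident.q_value <= q_threshold:
            out.append(ident)
    out.sort(key=lambda d: (-d.score, d.key))
    return out


# -- serialization ---------------------------------------------------------

def write_library_tsv(library: IonLibrary, path) -> None:
    """Transition-list style TSV (one row per fragment)."""
    rows = []
    for entry in library.entries.values():
        for f in entry.fragments:
            rows.append(
                {
                    "sequence": entry.sequence,
                    "modification": entry.modification,
                    "charge": entry.charge,
                    "precursor_mz": entry.precursor_mz,
                    "irt": entry.irt,
                    "protein_id": entry.protein_id,
                    "fragment_type": f.ion_type,
                    "fragment_ordinal": f.index,
                    "fragment_mz": f.mz,
                    "relative_intensity": f.rel_intensity,
                    "provenance": ";".join(sorted(entry.provenance)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(
    path,
    rt_calibration: RtCalibration | None = None,
    xic_window_minutes: float = 2.0,
    mode: str = "imported",
) -> IonLibrary:
    df = pd.read_csv(path, sep="\t")
    df["modification"] = df["modification"].fillna("")
    entries: dict[Key, LibraryEntry] = {}
    for (seq, mod, z), grp in df.groupby(
        ["sequence", "modification", "charge"], sort=True
    ):
        frags = [
            Fragment(r.fragment_type, int(r.fragment_ordinal), float(r.fragment_mz),
                     float(r.relative_intensity))
            for r in grp.itertuples()
        ]
        frags.sort(key=lambda f: f.mz)
        first = grp.iloc[0]
        prov = set()
        if "provenance" in grp and isinstance(first.get("provenance"), str):
            prov = set(p for p in first["provenance"].split(";") if p)
        entries[(seq, str(mod), int(z))] = LibraryEntry(
            seq, str(mod), int(z), float(first.precursor_mz), float(first.irt),
            frags, str(first.protein_id), prov,
        )
    cal = rt_calibration or RtCalibration(1.0, 0.0, 0.0)
    return IonLibrary(entries, cal, xic_window_minutes, mode=mode)


def identifications_to_frame(idents: list[Identification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [i.key[0] for i in idents],
            "modification": [i.key[1] for i in idents],
            "charge": [i.key[2] for i in idents],
            "protein_id": [i.protein_id for i in idents],
            "run_id": [i.run_id for i in idents],
            "apex_rt": [i.apex_rt for i in idents],
            "score": [i.score for i in idents],
            "q_value": [i.q_value for i in idents],
        }
    )
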