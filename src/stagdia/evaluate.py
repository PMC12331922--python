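"""Library- and method-comparison metrics.

Implements the metric suite used to compare ion-chromatogram libraries and
acquisition strategies: per-run completeness, library recovery, explained
TIC, peptide physicochemical properties (length, monoisotopic mass, GRAVY,
hydrophobicity index), multi-way overlap (Venn) counts, protein abundance
rank curves and cross-method Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from pyteomics import mass as _mass
from scipy import stats

from .libraries import Identification, IonLibrary
from .run_io import Run

__all__ = [
    "KYTE_DOOLITTLE",
    "PeptideProperties",
    "completeness",
    "library_recovery",
    "explained_tic",
    "peptide_properties",
    "overlap_sets",
    "rank_distribution",
    "cross_method_correlation",
    "property_radar",
]

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PeptideProperties:
    length: int
    monoisotopic_mass: float
    gravy: float
    hydrophobicity_index: float


def completeness(per_run_protein_sets: dict[str, set]) -> dict[str, float]:
    """Per-run percentage of the replicate-union proteome found in that run."""
    if len(per_run_protein_sets) < 2:
        raise ValueError("need at least two runs")
    union = set().union(*per_run_protein_sets.values())
    if not union:
        raise ValueError("empty union of protein sets")
    return {
        run: 100.0 * len(prots & union) / len(union)
        for run, prots in per_run_protein_sets.items()
    }


def library_recovery(identified_proteins: set, library_proteins: set) -> float:
    """Percentage of library proteins recovered among the identifications."""
    if not library_proteins:
        raise ValueError("empty library")
    return 100.0 * len(set(identified_proteins) & set(library_proteins)) / len(
        set(library_proteins)
    )


def explained_tic(
    run: Run,
    identifications: list[Identification],
    library: IonLibrary,
    tol_ppm: float = 10.0,
) -> float:
    """Percentage of total MS2 ion current matched (within ``tol_ppm``) to
    the fragment channels of the accepted identifications."""
    ms2 = run.ms2()
    total = sum(s.tic for s in ms2)
    if total <= 0:
        raise ValueError("run has no MS2 intensity")
    frag_mzs = np.unique(
        np.array(
            [
                f.mz
                for ident in identifications
                if ident.key in library.entries
                for f in library.entries[ident.key].fragments
            ]
        )
    )

    matched = 0.0
    for s in ms2:
        if s.mz.size == 0 or frag_mzs.size == 0:
            continue
        hit = np.zeros(s.mz.size, dtype=bool)
        for fmz in frag_mzs:
            tol = fmz * tol_ppm * 1e-6
            lo = np.searchsorted(s.mz, fmz - tol, side="left")
            hi = np.searchsorted(s.mz, fmz + tol, side="right")
            hit[lo:hi] = True
        matched += float(s.intensity[hit].sum())
    return 100.0 * matched / total


def peptide_properties(
    sequence: str, hydrophobicity_scale: dict[str, float] | None = None
) -> PeptideProperties:
    """Length, monoisotopic mass, GRAVY and hydrophobicity index.

    GRAVY is the mean Kyte-Doolittle hydropathy; the hydrophobicity index is
    the *sum* of per-residue coefficients (default: the same KD scale, so the
    index is length-sensitive where GRAVY is not; pass any published
    retention-coefficient table to swap the scale).
    """
    scale = hydrophobicity_scale or KYTE_DOOLITTLE
    if not sequence:
        raise ValueError("empty sequence")
    try:
        kd = [KYTE_DOOLITTLE[a] for a in sequence]
        coeffs = [scale[a] for a in sequence]
    except KeyError as err:
        raise ValueError(f"unknown residue {err.args[0]!r}") from None
    return PeptideProperties(
        length=len(sequence),
        monoisotopic_mass=float(_mass.fast_mass(sequence)),
        gravy=float(np.mean(kd)),
        hydrophobicity_index=float(np.sum(coeffs)),
    )


def overlap_sets(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive Venn region counts for 2+ named sets.

    Keys are frozensets of method names; the value is the number of elements
    belonging to exactly those methods.  Region counts sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named_sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set().union(
                *(set(named_sets[n]) for n in names if n not in combo)
            ) if len(combo) < len(names) else set()
            out[frozenset(combo)] = len(inside - outside)
    return out


def rank_distribution(matrix: pd.DataFrame) -> pd.DataFrame:
    """Protein abundance rank curve: proteins sorted by mean log10 intensity,
    descending.  Columns: rank (1-based), protein, mean_log10_intensity."""
    mean = np.log10(matrix.where(matrix > 0)).mean(axis=1).dropna()
    mean = mean.sort_values(ascending=False)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(mean) + 1),
            "protein": mean.index,
            "mean_log10_intensity": mean.to_numpy(),
        }
    )


def cross_method_correlation(quant_a: pd.Series, quant_b: pd.Series) -> float:
    """Pearson r of log10 quantities over the shared keys of two methods."""
    a = pd.Series(quant_a).dropna()
    b = pd.Series(quant_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least three shared keys")
    return float(
        stats.pearsonr(
            np.log10(a.loc[shared].to_numpy()),
            np.log10(b.loc[shared].to_numpy()),
        ).statistic
    )


def property_radar(method_peptides: dict[str, list[str]]) -> pd.DataFrame:
    """Per-method mean peptide properties, z-scored across methods (the
    radar-plot export).  Rows: methods; columns: properties."""
    rows = {}
    for name, seqs in method_peptides.items():
        props = [peptide_properties(s) for s in seqs]
        rows[name] = {
            "length": np.mean([p.length for p in props]),
            "monoisotopic_mass": np.mean([p.monoisotopic_mass for p in props]),
            "gravy": np.mean([p.gravy for p in props]),
            "hydrophobicity_index": np.mean(
                [p.hydrophobicity_index for p in props]
            ),
        }
    df = pd.DataFrame(rows).T
    sd = df.std(ddof=0)
    sd = sd.replace(0, 1.0)
    return (df - df.mean()) / sd
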