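"""Label-free quantification and the differential-expression filter cascade.

Fragment areas are normalized at the MS2 level (per-sample log-intensity
medians equalized), rolled up to peptide quantities (mean of the 3 largest
fragment areas) and protein quantities (mean of the top 3 peptides), and
tested between two groups with a Welch t-test on log2 intensities plus
Benjamini-Hochberg correction.  A protein is called significant when it
passes, in order: presence in >= 50 % of samples in both groups, >= 2 unique
peptides, BH q < 0.05 and |log2 fold change| >= 0.585 (a 50 % expression
difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantMatrix",
    "normalize_ms2",
    "rollup_top3",
    "differential_expression",
    "cv_distribution",
    "FC_THRESHOLD_LOG2",
]

#: default fold-change cutoff: a 50 % expression difference, log2(1.5)
FC_THRESHOLD_LOG2 = math.log2(1.5)


@dataclass
class QuantMatrix:
    """Protein x sample intensities with peptide support."""

    intensities: pd.DataFrame  # protein x sample
    peptide_counts: pd.DataFrame  # peptides quantified per cell
    unique_peptides: pd.Series  # distinct peptides per protein (any sample)
    provenance: dict = field(default_factory=dict)


def normalize_ms2(
    table: pd.DataFrame,
    sample_col: str = "sample",
    area_col: str = "area",
) -> tuple[pd.DataFrame, pd.Series]:
    """Global MS2-level signal normalization on a long fragment table.

    Each sample is rescaled so its median log2 fragment area equals the grand
    median (median of the per-sample medians).  Missing/non-positive areas
    are untouched; a sample with no usable areas is left unscaled (factor 1).
    Returns the normalized table and the per-sample linear scale factors.
    """
    if table.empty:
        raise ValueError("need at least one sample")
    out = table.copy()
    logs = np.log2(out[area_col].where(out[area_col] > 0))
    med = logs.groupby(out[sample_col]).median()
    grand = med.median()
    factors = (2.0 ** (grand - med)).fillna(1.0)
    factors.name = "scale"
    out[area_col] = out[area_col] * out[sample_col].map(factors)
    return out, factors


def _top_n_mean(values: np.ndarray, n: int = 3) -> float:
    v = np.sort(values)[::-1]
    return float(v[:n].mean())


def rollup_top3(
    table: pd.DataFrame,
    sample_col: str = "sample",
    protein_col: str = "protein",
    peptide_col: str = "peptide",
    area_col: str = "area",
) -> QuantMatrix:
    """Fragment -> peptide -> protein top-3 roll-up.

    Peptide quantity is the mean of its 3 largest fragment areas (all areas
    when fewer than 3); protein quantity the mean of its top 3 peptide
    quantities.  Scale-equivariant: scaling all areas by c scales every
    protein quantity by c.
    """
    if (table[area_col] < 0).any():
        raise ValueError("fragment areas must be non-negative")
    pep = (
        table.groupby([sample_col, protein_col, peptide_col])[area_col]
        .agg(lambda v: _top_n_mean(v.to_numpy()))
        .rename("pep_quantity")
        .reset_index()
    )
    prot = (
        pep.groupby([sample_col, protein_col])["pep_quantity"]
        .agg(quantity=lambda v: _top_n_mean(v.to_numpy()), n_peptides="size")
        .reset_index()
    )
    intensities = prot.pivot(index=protein_col, columns=sample_col, values="quantity")
    counts = prot.pivot(index=protein_col, columns=sample_col, values="n_peptides")
    unique = pep.groupby(protein_col)[peptide_col].nunique()
    return QuantMatrix(intensities, counts, unique.reindex(intensities.index))


def differential_expression(
    matrix: QuantMatrix,
    groups,
    fc_threshold_log2: float = FC_THRESHOLD_LOG2,
    q_threshold: float = 0.05,
    min_peptides: int = 2,
    min_presence: float = 0.5,
    group_a: str | None = None,
    group_b: str | None = None,
    subjects=None,
) -> pd.DataFrame:
    """Two-group differential expression with the ordered filter cascade.

    Welch's t-test on log2 intensities (missing values ignored), BH q-values
    across all testable proteins, then the filters presence -> peptides ->
    q -> fold change.  ``log2fc`` is group B minus group A.  Proteins absent
    from a whole group (or with fewer than two values in either group) are
    excluded and flagged.  ``subjects`` (sample -> subject id) optionally
    averages replicate samples per subject before testing.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    ga = group_a or labels[0]
    gb = group_b or labels[1]

    data = matrix.intensities
    if subjects is not None:
        subjects = pd.Series(subjects)
        logd = np.log2(data.where(data > 0))
        logd = logd.T.groupby(subjects).mean().T
        groups = groups.groupby(subjects).first()
        log_data = logd
    else:
        log_data = np.log2(data.where(data > 0))

    a_cols = groups.index[groups == ga]
    b_cols = groups.index[groups == gb]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least two samples")

    rows = []
    for protein, row in log_data.iterrows():
        va = row[a_cols].dropna().to_numpy()
        vb = row[b_cols].dropna().to_numpy()
        pres_a = len(va) / len(a_cols)
        pres_b = len(vb) / len(b_cols)
        excluded = len(va) < 2 or len(vb) < 2
        if excluded:
            lfc, p = np.nan, np.nan
        else:
            lfc = float(vb.mean() - va.mean())
            p = float(stats.ttest_ind(vb, va, equal_var=False).pvalue)
        rows.append(
            {
                "protein": protein,
                "log2fc": lfc,
                "p_value": p,
                "unique_peptides": int(matrix.unique_peptides.get(protein, 0)),
                "presence_a": pres_a,
                "presence_b": pres_b,
                "excluded": excluded,
            }
        )
    res = pd.DataFrame(rows).set_index("protein")

    res["q_value"] = np.nan
    tested = res.index[~res["p_value"].isna()]
    if len(tested):
        res.loc[tested, "q_value"] = multipletests(
            res.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]

    res["pass_presence"] = (res["presence_a"] >= min_presence) & (
        res["presence_b"] >= min_presence
    )
    res["pass_peptides"] = res["unique_peptides"] >= min_peptides
    res["pass_q"] = res["q_value"] < q_threshold
    res["pass_fc"] = res["log2fc"].abs() >= fc_threshold_log2
    res["significant"] = (
        res["pass_presence"]
        & res["pass_peptides"]
        & res["pass_q"]
        & res["pass_fc"]
        & ~res["excluded"]
    )
    return res


def cv_distribution(
    matrix: pd.DataFrame, cv_cutoff_pct: float = 20.0
) -> tuple[float, float, pd.Series]:
    """Per-protein CV% over replicate columns.

    Returns (median CV%, fraction of proteins with CV below the cutoff,
    per-protein CV series).  Proteins with zero or undefined mean are
    excluded.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two replicates")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    cv = (100.0 * sd / mean).replace([np.inf, -np.inf], np.nan).dropna()
    cv = cv[mean.reindex(cv.index) != 0]
    if cv.empty:
        raise ValueError("no proteins with a usable mean")
    return float(cv.median()), float((cv < cv_cutoff_pct).mean()), cv
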