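"""Ground-truthed synthetic peptides, DIA runs and two-group study designs.

The generator emulates the features of a staggered-window DIA experiment that
the downstream stages exercise: tryptic peptides with b/y fragment patterns,
Gaussian elution peaks on an indexed-retention-time (iRT) scale, staggered
MS2 cycles with interleaved MS1 scans, gas-phase-fractionated injections and
a two-group (normal vs impaired glucose tolerance-like) abundance design with
planted fold changes.  Every operation is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta
from pyteomics import mass as _mass
from pyteomics import parser as _parser

from .run_io import Run, Spectrum
from .scheme_design import GPFPlan, WindowScheme

__all__ = [
    "Fragment",
    "SyntheticPeptide",
    "NoiseModel",
    "GroundTruth",
    "random_proteome",
    "generate_peptides",
    "peptide_mz",
    "simulate_run",
    "simulate_gpf_runs",
    "simulate_two_group_study",
    "fragment_tables",
]

PROTON = 1.00727646688
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# Approximate residue frequencies of the human proteome, used to draw random
# protein sequences with realistic tryptic cleavage-site density.
_AA_FREQ = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # 'b' or 'y'
    index: int  # ordinal (b2, y5, ...)
    mz: float
    rel_intensity: float


@dataclass
class SyntheticPeptide:
    sequence: str
    charge: int
    precursor_mz: float
    irt: float
    fragments: list[Fragment]
    protein_id: str
    abundance: float

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sequence, "", self.charge)


@dataclass
class NoiseModel:
    """Shot noise (variance proportional to the mean) plus uniform chemical
    background peaks."""

    shot_scale: float = 0.0  # Var[I] = shot_scale * E[I]
    chem_rate: float = 0.0  # expected background peaks per MS2 scan
    chem_intensity: float = 50.0  # exponential scale of background peaks
    chem_mz_range: tuple[float, float] = (300.0, 1800.0)


@dataclass
class GroundTruth:
    """Planted truth of a synthetic two-group study."""

    peptides: list[SyntheticPeptide]
    sample_abundances: pd.DataFrame  # peptide key (index) x sample
    group_labels: pd.Series  # sample -> 'A' | 'B'
    de_proteins: dict[str, float]  # protein -> planted log2 fold change
    seed: int
    peptide_info: pd.DataFrame = field(default_factory=pd.DataFrame)


def peptide_mz(sequence: str, charge: int) -> float:
    """Monoisotopic precursor m/z of an unmodified peptide."""
    return _mass.fast_mass(sequence, charge=charge)


def random_proteome(
    n_proteins: int, seed: int = 0, mean_length: int = 320
) -> dict[str, str]:
    """Random protein sequences with human-like residue frequencies."""
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    aas = np.array(list(_AA_FREQ))
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    out = {}
    for i in range(n_proteins):
        length = max(50, int(rng.normal(mean_length, mean_length / 4)))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        out[f"PROT{i:04d}"] = seq
    return out


def _fragment_mzs(sequence: str) -> list[tuple[str, int, float]]:
    """Singly charged b/y fragment m/z values (ordinals 2 .. len-1)."""
    frags = []
    n = len(sequence)
    for i in range(2, n):
        frags.append(("b", i, _mass.fast_mass(sequence[:i], ion_type="b", charge=1)))
        frags.append(("y", i, _mass.fast_mass(sequence[n - i:], ion_type="y", charge=1)))
    return frags


def generate_peptides(
    source="random",
    n_proteins: int = 50,
    seed: int = 0,
    cleave_before_proline: bool = True,
    max_missed_cleavages: int = 2,
    min_length: int = 7,
    max_length: int = 35,
    charges: tuple[int, ...] = (2, 3),
    fragment_mz_range: tuple[float, float] = (300.0, 1800.0),
    min_fragments: int = 3,
    max_fragments: int = 6,
    abundance_log10_mean: float = 6.0,
    abundance_log10_sd: float = 0.5,
) -> list[SyntheticPeptide]:
    """In-silico tryptic digestion into library-ready synthetic peptides.

    ``source`` is ``"random"`` (draws ``n_proteins`` random sequences), a
    mapping of protein id to sequence, or a FASTA path.  Cleavage is after
    K/R with up to ``max_missed_cleavages`` missed sites; by default the
    proline suppression rule is disabled (Trypsin/LysC "with P").  Each
    peptide keeps its 3-6 most intense b/y fragments inside
    ``fragment_mz_range``; relative fragment intensities are drawn once from
    a symmetric Dirichlet and fixed thereafter.  Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(source, str) and source == "random":
        proteome = random_proteome(n_proteins, seed=seed)
    elif isinstance(source, dict):
        proteome = dict(source)
    else:
        proteome = {
            (header.split()[0] if header else f"PROT{i}"): seq
            for i, (header, seq) in enumerate(_fasta.read(str(source)))
        }
    if not proteome:
        raise ValueError("empty protein source")

    rule = r"[KR]" if cleave_before_proline else _parser.expasy_rules["trypsin"]
    seen: set[str] = set()
    peptides: list[SyntheticPeptide] = []
    for protein_id in sorted(proteome):
        seq = proteome[protein_id]
        cuts = sorted(
            _parser.cleave(seq, rule, missed_cleavages=max_missed_cleavages)
        )
        for pep in cuts:
            if not (min_length <= len(pep) <= max_length):
                continue
            if pep in seen:  # keep protein mapping unambiguous
                continue
            seen.add(pep)
            charge = int(rng.choice(charges))
            cand = [
                (t, i, mz)
                for t, i, mz in _fragment_mzs(pep)
                if fragment_mz_range[0] <= mz <= fragment_mz_range[1]
            ]
            if len(cand) < min_fragments:
                continue
            rel = rng.dirichlet(np.ones(len(cand)))
            order = np.argsort(rel)[::-1][:max_fragments]
            frags = sorted(
                (Fragment(cand[j][0], cand[j][1], cand[j][2], float(rel[j])) for j in order),
                key=lambda f: f.mz,
            )
            peptides.append(
                SyntheticPeptide(
                    sequence=pep,
                    charge=charge,
                    precursor_mz=peptide_mz(pep, charge),
                    irt=float(rng.uniform(0.0, 100.0)),
                    fragments=frags,
                    protein_id=protein_id,
                    abundance=float(10 ** rng.normal(abundance_log10_mean, abundance_log10_sd)),
                )
            )
    return peptides


def default_irt_map(gradient_minutes: float) -> tuple[float, float]:
    """Affine iRT->RT map placing iRT 0..100 on 10-90 % of the gradient."""
    total = gradient_minutes * 60.0
    return 0.008 * total, 0.1 * total  # slope (s per iRT unit), intercept (s)


def _cycle_scan_orders(n_windows: int, ms1_every: int) -> list[int | None]:
    """Scan sequence of one cycle: window orders with None marking MS1."""
    seq: list[int | None] = []
    for k in range(n_windows):
        if k % ms1_every == 0:
            seq.append(None)
        seq.append(k)
    return seq


def simulate_run(
    peptides: list[SyntheticPeptide],
    scheme: WindowScheme,
    abundances: dict | None = None,
    run_id: str = "run",
    gradient_minutes: float = 20.0,
    cycle_ms: float = 3180.0,
    peak_fwhm_s: float = 17.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    irt_slope: float | None = None,
    irt_intercept: float | None = None,
    rt_shift_s: float = 0.0,
    rt_jitter_s: float = 0.0,
    ms1_range: tuple[float, float] = (385.0, 1015.0),
    min_intensity: float = 0.0,
    sigma_cutoff: float = 5.0,
    stagger_scan_times: bool = False,
) -> Run:
    """Simulate one staggered-window DIA run.

    Elution peaks are Gaussian with the stated FWHM, centred at the
    iRT-mapped retention time (optionally shifted per run and jittered per
    peptide).  Each MS2 scan contains the retained fragments of every peptide
    whose precursor falls inside that isolation window at that time; MS1
    scans with precursor peaks are inserted after every ``scheme.ms1_every``
    MS2 scans.  By default all scans of a cycle share the cycle start time
    (the 3.18 s cycle is short against the 17 s peaks);
    ``stagger_scan_times=True`` spreads scan times across the cycle instead.
    Peptides whose precursor is outside every window are excluded and counted
    in ``run.meta['excluded_peptides']``.
    """
    if cycle_ms <= 0:
        raise ValueError("cycle time must be positive")
    rng = np.random.default_rng(seed)
    if irt_slope is None or irt_intercept is None:
        irt_slope, irt_intercept = default_irt_map(gradient_minutes)
    sigma = peak_fwhm_s * FWHM_TO_SIGMA

    per_window: dict[int, list[int]] = {w.order: [] for w in scheme.windows}
    apex: list[float] = []
    kept: list[int] = []
    excluded = 0
    for idx, pep in enumerate(peptides):
        covering = scheme.windows_covering(pep.precursor_mz)
        t0 = irt_slope * pep.irt + irt_intercept + rt_shift_s
        if rt_jitter_s > 0:
            t0 += rng.normal(0.0, rt_jitter_s)
        apex.append(t0)
        if not covering:
            excluded += 1
            continue
        kept.append(idx)
        for w in covering:
            per_window[w.order].append(idx)

    amounts = np.array(
        [
            (abundances.get(p.key, p.abundance) if abundances else p.abundance)
            for p in peptides
        ]
    )

    run = Run(
        run_id,
        meta={
            "scheme": scheme.to_dict(),
            "gradient_minutes": gradient_minutes,
            "cycle_ms": cycle_ms,
            "peak_fwhm_s": peak_fwhm_s,
            "irt_slope": irt_slope,
            "irt_intercept": irt_intercept,
            "excluded_peptides": excluded,
        },
    )

    cycle_s = cycle_ms / 1000.0
    n_cycles = int(gradient_minutes * 60.0 / cycle_s)
    scan_seq = _cycle_scan_orders(len(scheme.windows), scheme.ms1_every)
    dt_scan = cycle_s / len(scan_seq)
    cut = sigma_cutoff * sigma

    for c in range(n_cycles):
        t_c = c * cycle_s
        for slot, order in enumerate(scan_seq):
            rt = t_c + (slot * dt_scan if stagger_scan_times else 0.0)
            if order is None:  # MS1 survey scan
                mzs, ints = [], []
                for idx in kept:
                    pep = peptides[idx]
                    if not (ms1_range[0] <= pep.precursor_mz < ms1_range[1]):
                        continue
                    if abs(rt - apex[idx]) >= cut:
                        continue
                    g = math.exp(-0.5 * ((rt - apex[idx]) / sigma) ** 2)
                    mzs.append(pep.precursor_mz)
                    ints.append(amounts[idx] * g)
                spec = Spectrum(1, rt, np.asarray(mzs), np.asarray(ints), None, c)
            else:
                mzs, ints = [], []
                for idx in per_window[order]:
                    pep = peptides[idx]
                    if abs(rt - apex[idx]) >= cut:
                        continue
                    g = math.exp(-0.5 * ((rt - apex[idx]) / sigma) ** 2)
                    base = amounts[idx] * g
                    for frag in pep.fragments:
                        mzs.append(frag.mz)
                        ints.append(base * frag.rel_intensity)
                mz_arr = np.asarray(mzs)
                int_arr = np.asarray(ints)
                if noise is not None:
                    if noise.shot_scale > 0 and int_arr.size:
                        int_arr = np.clip(
                            rng.normal(int_arr, np.sqrt(noise.shot_scale * int_arr)),
                            0.0,
                            None,
                        )
                    if noise.chem_rate > 0:
                        k = rng.poisson(noise.chem_rate)
                        if k:
                            mz_arr = np.concatenate(
                                [mz_arr, rng.uniform(*noise.chem_mz_range, size=k)]
                            )
                            int_arr = np.concatenate(
                                [int_arr, rng.exponential(noise.chem_intensity, size=k)]
                            )
                spec = Spectrum(2, rt, mz_arr, int_arr, order, c)
            if min_intensity > 0 and spec.mz.size:
                keep = spec.intensity > min_intensity
                spec.mz, spec.intensity = spec.mz[keep], spec.intensity[keep]
            if spec.mz.size:
                srt = np.argsort(spec.mz)
                spec.mz, spec.intensity = spec.mz[srt], spec.intensity[srt]
            run.spectra.append(spec)
    return run


def simulate_gpf_runs(
    peptides: list[SyntheticPeptide],
    plan: GPFPlan,
    seed: int = 0,
    **kwargs,
) -> list[Run]:
    """One run per gas-phase fraction; only precursors isolated by the
    segment's windows are sampled.  The elution model (iRT map) is shared
    across fractions."""
    runs = []
    for k, (_rng, scheme) in enumerate(plan.segments):
        subset = [p for p in peptides if scheme.windows_covering(p.precursor_mz)]
        runs.append(
            simulate_run(
                subset,
                scheme,
                run_id=f"gpf-{k}",
                seed=seed + k,
                **kwargs,
            )
        )
    return runs


def simulate_two_group_study(
    n_samples_a: int = 26,
    n_samples_b: int = 22,
    frac_de: float = 0.1,
    log2fc: float = 0.585,
    cv_within: float = 0.2,
    n_proteins: int = 200,
    seed: int = 0,
    max_peptides_per_protein: int = 8,
    detection_floor_quantile: float = 0.03,
    make_runs: bool = False,
    scheme: WindowScheme | None = None,
    **run_kwargs,
) -> tuple[list[Run] | None, GroundTruth]:
    """Two-group study with planted differential expression.

    Between-sample biological variation is log-normal with the stated
    within-group CV and is applied per protein per sample, identically to all
    of that protein's peptides; proteins in the planted DE set are shifted by
    ``log2fc`` (multiplicatively) in group B.  Peptides whose abundance in a
    sample falls below the detection floor (a low quantile of the overall
    abundance distribution) are missing in that sample.  Returns
    ``(runs, GroundTruth)``; runs are materialized only with
    ``make_runs=True`` (requires ``scheme``).
    """
    if n_samples_a < 1 or n_samples_b < 1:
        raise ValueError("both groups need samples")
    if not (0.0 <= frac_de <= 1.0):
        raise ValueError("frac_de must be a proportion")
    rng = np.random.default_rng(seed)
    peptides = generate_peptides(n_proteins=n_proteins, seed=seed)
    if max_peptides_per_protein:
        by_prot: dict[str, list[SyntheticPeptide]] = {}
        for p in peptides:
            by_prot.setdefault(p.protein_id, []).append(p)
        peptides = [
            p
            for prot in sorted(by_prot)
            for p in by_prot[prot][:max_peptides_per_protein]
        ]

    proteins = sorted({p.protein_id for p in peptides})
    n_de = int(round(frac_de * len(proteins)))
    de_proteins = {
        prot: float(log2fc)
        for prot in rng.choice(proteins, size=n_de, replace=False)
    }

    samples = [f"A{i:02d}" for i in range(n_samples_a)] + [
        f"B{i:02d}" for i in range(n_samples_b)
    ]
    groups = pd.Series(
        ["A"] * n_samples_a + ["B"] * n_samples_b, index=samples, name="group"
    )
    sigma_ln = math.sqrt(math.log(1.0 + cv_within**2))

    # protein-level sample factors, shared by all peptides of the protein
    factors = pd.DataFrame(
        np.exp(rng.normal(0.0, sigma_ln, size=(len(proteins), len(samples)))),
        index=proteins,
        columns=samples,
    )
    for prot, lfc in de_proteins.items():
        factors.loc[prot, groups == "B"] *= 2.0**lfc

    keys = [f"{p.protein_id}|{p.sequence}/{p.charge}" for p in peptides]
    base = np.array([p.abundance for p in peptides])
    mat = base[:, None] * factors.loc[[p.protein_id for p in peptides]].to_numpy()
    abund = pd.DataFrame(mat, index=keys, columns=samples)

    floor = float(np.quantile(mat, detection_floor_quantile))
    abund = abund.where(abund >= floor)

    info = pd.DataFrame(
        {
            "protein": [p.protein_id for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "charge": [p.charge for p in peptides],
        },
        index=keys,
    )
    truth = GroundTruth(
        peptides=peptides,
        sample_abundances=abund,
        group_labels=groups,
        de_proteins=de_proteins,
        seed=seed,
        peptide_info=info,
    )

    runs = None
    if make_runs:
        if scheme is None:
            raise ValueError("make_runs requires a scheme")
        runs = []
        for j, sample in enumerate(samples):
            ab = {
                p.key: abund.at[keys[i], sample]
                for i, p in enumerate(peptides)
                if pd.notna(abund.at[keys[i], sample])
            }
            kept = [p for p in peptides if p.key in ab]
            runs.append(
                simulate_run(
                    kept, scheme, abundances=ab, run_id=sample, seed=seed * 1000 + j,
                    **run_kwargs,
                )
            )
    return runs, truth


def fragment_tables(truth: GroundTruth, frag_noise_cv: float = 0.05) -> pd.DataFrame:
    """Long-format per-sample fragment areas implied by the ground truth.

    Fragment area = sample peptide abundance x fixed relative fragment
    intensity x multiplicative log-normal measurement noise (CV
    ``frag_noise_cv``).  Deterministic given ``truth.seed``.  Columns:
    sample, protein, peptide, fragment, area.
    """
    rng = np.random.default_rng(truth.seed + 777)
    sigma = math.sqrt(math.log(1.0 + frag_noise_cv**2)) if frag_noise_cv > 0 else 0.0
    rows = []
    keys = truth.sample_abundances.index
    ab = truth.sample_abundances.to_numpy()
    for i, pep in enumerate(truth.peptides):
        rels = np.array([f.rel_intensity for f in pep.fragments])
        noise = (
            np.exp(rng.normal(0.0, sigma, size=(ab.shape[1], rels.size)))
            if sigma > 0
            else np.ones((ab.shape[1], rels.size))
        )
        for j, sample in enumerate(truth.sample_abundances.columns):
            a = ab[i, j]
            if np.isnan(a):
                continue
            for f, frag in enumerate(pep.fragments):
                rows.append(
                    (
                        sample,
                        pep.protein_id,
                        f"{pep.sequence}/{pep.charge}",
                        f"{frag.ion_type}{frag.index}",
                        a * rels[f] * noise[j, f],
                    )
                )
        _ = keys
    return pd.DataFrame(
        rows, columns=["sample", "protein", "peptide", "fragment", "area"]
    )
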