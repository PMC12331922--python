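import numpy as np
import pytest

import stagdia as sd


def pick_resolvable(peptides, scheme, n, min_sep_ppm=30.0):
    """Peptides inside the demux-bin range whose retained fragment channels
    are mutually separated by at least ``min_sep_ppm`` (no interference)."""
    sel, mzs = [], []
    for p in peptides:
        if scheme.bin_index(p.precursor_mz) is None:
            continue
        frs = [f.mz for f in p.fragments]
        if any(abs(a - b) <= min_sep_ppm * 1e-6 * b for a in frs for b in mzs):
            continue
        sel.append(p)
        mzs.extend(frs)
        if len(sel) == n:
            break
    return sel


def make_run(scheme, cycle_readings, rt0=0.0, cycle_s=3.18, scan_rts=None):
    """Hand-built staggered run: ``cycle_readings`` is a list (one per cycle)
    of {window order: [(mz, intensity), ...]}.  All scans of a cycle share the
    cycle time unless ``scan_rts`` gives per-order offsets."""
    run = sd.Run("manual", meta={"scheme": scheme.to_dict()})
    for c, readings in enumerate(cycle_readings):
        t = rt0 + c * cycle_s
        for w in scheme.windows:
            peaks = readings.get(w.order, [])
            mz = np.array([p[0] for p in peaks], dtype=float)
            inten = np.array([p[1] for p in peaks], dtype=float)
            order_ = np.argsort(mz)
            rt = t + (scan_rts[w.order] if scan_rts else 0.0)
            run.spectra.append(
                sd.Spectrum(2, rt, mz[order_], inten[order_], w.order, c)
            )
    return run


@pytest.fixture(scope="session")
def scheme52():
    return sd.build_staggered_scheme(400, 1000, 24)


@pytest.fixture(scope="session")
def tiny_scheme():
    return sd.build_staggered_scheme(400, 412, 12)


@pytest.fixture(scope="session")
def chain_scheme():
    # 4 demux bins over 400-424: 6 windows forming one overlap chain
    return sd.build_staggered_scheme(400, 424, 12)


@pytest.fixture(scope="session")
def peptide_pool():
    return sd.generate_peptides(n_proteins=6, seed=11)


@pytest.fixture(scope="session")
def planted(scheme52, peptide_pool):
    return pick_resolvable(peptide_pool, scheme52, 20)


@pytest.fixture(scope="session")
def noiseless_run(scheme52, planted):
    return sd.simulate_run(planted, scheme52, gradient_minutes=4.0, seed=11)


@pytest.fixture(scope="session")
def demuxed(noiseless_run, scheme52):
    return sd.demultiplex_run(noiseless_run, scheme52)
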