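import numpy as np
import pytest

import stagdia as sd
from stagdia.libraries import XicSet, _score_traces

from conftest import pick_resolvable


# -- iRT calibration -------------------------------------------------------


def test_calibration_exact_line_zero_residual():
    anchors = [(i, 2.5 * i + 40.0) for i in range(0, 110, 10)]
    cal = sd.calibrate_irt(anchors)
    assert cal.slope == pytest.approx(2.5, abs=1e-9)
    assert cal.intercept == pytest.approx(40.0, abs=1e-8)
    assert cal.residual_sd == pytest.approx(0.0, abs=1e-8)


def test_calibration_recovers_affine_map_under_jitter():
    rng = np.random.default_rng(0)
    irts = np.linspace(0, 100, 11)
    rts = 3.0 * irts + 120.0 + rng.normal(0, 2.0, irts.size)
    cal = sd.calibrate_irt(list(zip(irts, rts)))
    assert cal.slope == pytest.approx(3.0, rel=0.01)
    assert cal.intercept == pytest.approx(120.0, rel=0.01)
    assert 0.0 < cal.residual_sd < 6.0


def test_calibration_rejects_too_few_or_degenerate_anchors():
    with pytest.raises(ValueError):
        sd.calibrate_irt([(0, 0), (1, 1)])
    with pytest.raises(ValueError, match="degenerate"):
        sd.calibrate_irt([(5, 0), (5, 1), (5, 2)])


# -- library assembly ------------------------------------------------------


@pytest.fixture(scope="module")
def gpf_setup(peptide_pool):
    plan = sd.build_gpf_plan(400, 1000, 6, 2, 20)
    peps = [
        p
        for p in peptide_pool
        if any(s.windows_covering(p.precursor_mz) for _, s in plan.segments)
    ][:40]
    runs = sd.simulate_gpf_runs(peps, plan, gradient_minutes=3.0, seed=2)
    return plan, peps, runs


def test_gpf_library_covers_planted_peptides(gpf_setup):
    plan, peps, runs = gpf_setup
    lib = sd.assemble_library(runs, [], peps)
    assert set(lib.entries) == {p.key for p in peps}


def test_duplicate_entries_collapse_across_fractions(gpf_setup):
    plan, peps, runs = gpf_setup
    lib = sd.assemble_library(runs, [], peps)
    overlap_peps = [p for p in peps if len(plan.segment_for(p.precursor_mz)) == 2]
    assert overlap_peps, "need at least one peptide in a segment overlap"
    for p in overlap_peps:
        entry = lib.entries[p.key]
        assert len(entry.provenance) == 2  # seen in two fraction runs, one key


def test_hybrid_library_tightens_xic_window(peptide_pool):
    """Mixed-sample runs refit the calibration, so hybrid windows are never
    wider than fraction-only windows; with per-fraction RT distortion they
    are strictly narrower."""
    plan = sd.build_gpf_plan(400, 1000, 6, 2, 20)
    peps = [
        p
        for p in peptide_pool
        if any(s.windows_covering(p.precursor_mz) for _, s in plan.segments)
    ][:30]
    scheme = sd.build_staggered_scheme(400, 1000, 24)
    for seed in range(10):
        frac_runs = [
            sd.simulate_run(
                [p for p in peps if s.windows_covering(p.precursor_mz)],
                s,
                run_id=f"gpf-{k}",
                gradient_minutes=3.0,
                seed=seed * 10 + k,
                rt_shift_s=(k - 2.5) * 12.0,  # per-fraction RT distortion
                rt_jitter_s=3.0,
            )
            for k, (_, s) in enumerate(plan.segments)
        ]
        mixed = [
            sd.simulate_run(
                peps, scheme, run_id="mixed", gradient_minutes=3.0, seed=seed
            )
        ]
        lib_frac = sd.assemble_library(frac_runs, [], peps)
        lib_hybrid = sd.assemble_library(frac_runs, mixed, peps, mode="GPF-hybrid")
        assert lib_hybrid.xic_window_minutes <= lib_frac.xic_window_minutes


def test_hybrid_never_wider_on_noiseless_runs(gpf_setup):
    plan, peps, runs = gpf_setup
    scheme = sd.build_staggered_scheme(400, 1000, 24)
    mixed = [sd.simulate_run(peps, scheme, run_id="mixed", gradient_minutes=3.0, seed=3)]
    lib_frac = sd.assemble_library(runs, [], peps)
    lib_hybrid = sd.assemble_library(runs, mixed, peps)
    assert lib_hybrid.xic_window_minutes <= lib_frac.xic_window_minutes


def test_assembly_requires_sources_and_entries(gpf_setup):
    _, peps, runs = gpf_setup
    with pytest.raises(ValueError):
        sd.assemble_library([], [], peps)
    with pytest.raises(ValueError, match="empty entry source"):
        sd.assemble_library(runs, [], [])


# -- extraction and scoring ------------------------------------------------


def test_planted_peptide_apex_within_one_cycle(noiseless_run, scheme52, planted):
    lib = sd.assemble_library([noiseless_run], [], planted)
    xics = sd.extract_xics(noiseless_run, lib)
    slope, inter = noiseless_run.meta["irt_slope"], noiseless_run.meta["irt_intercept"]
    cycle_s = noiseless_run.meta["cycle_ms"] / 1000.0
    idents = sd.score_and_fdr(xics, report_all=True)
    for ident in idents:
        entry = lib.entries[ident.key]
        assert abs(ident.apex_rt - (slope * entry.irt + inter)) <= cycle_s + 1e-9


def test_out_of_segment_peptide_has_empty_trace(peptide_pool):
    plan = sd.build_gpf_plan(400, 1000, 6, 2, 20)
    seg0 = plan.segments[0][1]
    peps = pick_resolvable(peptide_pool, sd.build_staggered_scheme(400, 1000, 24), 10)
    inside = [p for p in peps if seg0.windows_covering(p.precursor_mz)]
    outside = [p for p in peps if not seg0.windows_covering(p.precursor_mz)]
    assert inside and outside
    run = sd.simulate_run(inside, seg0, gradient_minutes=2.0, seed=1)
    lib = sd.assemble_library([run], [], inside)
    # inject an out-of-segment entry
    from stagdia.libraries import entries_from_peptides

    lib.entries.update(entries_from_peptides(outside[:1]))
    xics = sd.extract_xics(run, lib)
    rts, mat = xics.traces[outside[0].key]
    assert rts.size == 0 and mat.sum() == 0.0


def test_self_score_is_unity():
    rels = np.array([0.5, 0.3, 0.2])
    rts = np.linspace(0, 30, 11)
    profile = np.exp(-0.5 * ((rts - 15) / 5) ** 2)
    mat = np.outer(rels, profile)
    score, apex, areas = _score_traces(rts, mat, rels)
    assert score == pytest.approx(1.0, abs=1e-9)
    assert apex == pytest.approx(15.0, abs=1.6)


def test_q_values_monotone_in_score(noiseless_run, planted):
    lib = sd.assemble_library([noiseless_run], [], planted)
    xics = sd.extract_xics(noiseless_run, lib)
    idents = sd.score_and_fdr(xics, decoy_factor=2, report_all=True)
    scores = [i.score for i in idents]
    qs = [i.q_value for i in idents]
    assert scores == sorted(scores, reverse=True)
    assert qs == sorted(qs)  # q never decreases as score drops


def test_narrower_window_keeps_precision(noiseless_run, planted):
    lib = sd.assemble_library([noiseless_run], [], planted)
    wide = sd.extract_xics(noiseless_run, lib)
    accepted_wide = {
        i.key for i in sd.score_and_fdr(wide, report_all=True) if i.score >= 0.9
    }
    lib.xic_window_minutes /= 2.0
    narrow = sd.extract_xics(noiseless_run, lib)
    accepted_narrow = {
        i.key for i in sd.score_and_fdr(narrow, report_all=True) if i.score >= 0.9
    }
    assert accepted_narrow <= accepted_wide


def test_library_tsv_roundtrip(noiseless_run, planted, tmp_path):
    lib = sd.assemble_library([noiseless_run], [], planted)
    path = tmp_path / "library.tsv"
    sd.write_library_tsv(lib, path)
    back = sd.read_library_tsv(path)
    assert set(back.entries) == set(lib.entries)
    for key, entry in lib.entries.items():
        b = back.entries[key]
        assert b.protein_id == entry.protein_id
        assert [f.mz for f in b.fragments] == pytest.approx(
            [f.mz for f in entry.fragments]
        )
        assert b.provenance == entry.provenance
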