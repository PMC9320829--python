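import numpy as np
import pytest

from antdiv.coalescent import MU, ExpectedSFS, expected_sfs
from antdiv.inference import (
    SCENARIOS,
    FitResult,
    FitSettings,
    build_model,
    compare_models,
    composite_loglik,
    fit_model,
    generations_to_years,
    scale_parameters,
)
from antdiv.sfs import Folded2DSFS


def _expected_from_matrix(probs, p_mono, n1, n2):
    return ExpectedSFS(
        probs=np.asarray(probs, dtype=float),
        p_mono=p_mono,
        n1=n1,
        n2=n2,
        n_genealogies=1,
        mu=MU,
        mean_total_length=0.0,
    )


def _obs(counts, mono=0, n1=None, n2=None):
    counts = np.asarray(counts, dtype=np.int64)
    return Folded2DSFS(
        counts=counts,
        monomorphic=mono,
        n1=counts.shape[0] - 1 if n1 is None else n1,
        n2=counts.shape[1] - 1 if n2 is None else n2,
    )


# ----------------------------------------------------------------------
# composite likelihood
# ----------------------------------------------------------------------


def test_loglik_zero_when_all_mass_in_one_entry():
    probs = np.zeros((3, 3))
    probs[1, 0] = 1.0
    exp = _expected_from_matrix(probs, 0.0, 2, 2)
    counts = np.zeros((3, 3), dtype=int)
    counts[1, 0] = 37
    assert composite_loglik(_obs(counts), exp) == 0.0


def test_loglik_uniform_closed_form():
    """M sites over k equiprobable entries: lnCL = M log10(1/k)."""
    entries = [(1, 0), (0, 1), (1, 1), (0, 2)]  # folded domain for n1=n2=2
    probs = np.zeros((3, 3))
    for e in entries:
        probs[e] = 0.25
    exp = _expected_from_matrix(probs, 0.0, 2, 2)
    counts = np.zeros((3, 3), dtype=int)
    for e in entries:
        counts[e] = 25
    assert composite_loglik(_obs(counts), exp) == pytest.approx(
        100 * np.log10(0.25), abs=1e-9
    )
    assert composite_loglik(_obs(counts), exp) == pytest.approx(-60.206, abs=1e-3)


def test_loglik_matches_direct_sum_oracle():
    rng = np.random.default_rng(14)
    from antdiv.sfs import fold_counts
    from antdiv.coalescent import fold_joint

    raw = rng.random((5, 5))
    raw[0, 0] = raw[4, 4] = 0.0
    probs = raw / raw.sum() * 0.1
    p_mono = 1 - probs.sum()
    exp = _expected_from_matrix(probs, p_mono, 4, 4)
    counts = fold_counts(rng.integers(0, 40, size=(5, 5)))
    mono = 5_000
    obs = _obs(counts, mono=mono)
    got = composite_loglik(obs, exp)
    pf = fold_joint(probs)
    pf[0, 0] += p_mono
    m = counts.astype(float).copy()
    m[0, 0] += mono
    manual = sum(
        m[i, j] * np.log10(max(pf[i, j], 1e-20))
        for i in range(5)
        for j in range(5)
        if m[i, j] > 0
    )
    assert got == pytest.approx(manual, abs=1e-10)


def test_loglik_floors_unrepresented_entries():
    probs = np.zeros((3, 3))
    probs[1, 0] = 1.0
    exp = _expected_from_matrix(probs, 0.0, 2, 2)
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 1] = 1  # observed but never simulated
    assert composite_loglik(_obs(counts), exp) == pytest.approx(-20.0)


def test_loglik_sample_size_mismatch():
    exp = _expected_from_matrix(np.zeros((3, 3)), 1.0, 2, 2)
    with pytest.raises(ValueError, match="mismatch"):
        composite_loglik(_obs(np.zeros((4, 3), dtype=int)), exp)


# ----------------------------------------------------------------------
# scenario constructors
# ----------------------------------------------------------------------


ALLO_P = dict(N_ANC=5e4, N1_ANC=2e4, N2_ANC=2e4, N1=5e3, N2=5e3,
              T_DIV=4e3, T_RESIZE=4e2)


def test_every_scenario_builds_a_valid_model():
    rng = np.random.default_rng(15)
    for sid, tmpl in SCENARIOS.items():
        for _ in range(5):
            params = tmpl.sample(rng)
            model = build_model(sid, params, 4, 4)
            assert model.n_samples == 8
            assert len(tmpl.param_names) == len(params)


def test_scenario_parameter_counts():
    expected = {
        "ALLO": 7, "SYM": 9, "SYM_ASYM": 11, "IAM": 9, "MAI": 9,
        "ALLO10": 10, "GHOST_F": 10, "GHOST_G": 10, "GHOST_H": 10,
        "GHOST_I": 10,
    }
    assert {k: len(t.param_names) for k, t in SCENARIOS.items()} == expected


def test_constraint_violation_names_constraint():
    bad = dict(ALLO_P, T_RESIZE=5e3)  # resize after divergence
    with pytest.raises(ValueError, match="T_RESIZE < T_DIV"):
        build_model("ALLO", bad, 4, 4)


def test_sym_asym_with_zero_migration_matches_allo():
    """Nesting: negligible migration reproduces the allopatry spectrum
    (extra migration-switch events shift the random stream, so equality
    holds to Monte-Carlo error, not bit-for-bit)."""
    sym = dict(ALLO_P, M_ANC_AP=1e-10, M_ANC_PA=1e-10,
               M_REC_AP=1e-10, M_REC_PA=1e-10)
    pa = np.array([
        expected_sfs(build_model("ALLO", ALLO_P, 4, 4), 10_000, 70 + i).probs
        for i in range(8)
    ])
    ps = np.array([
        expected_sfs(build_model("SYM_ASYM", sym, 4, 4), 10_000, 80 + i).probs
        for i in range(8)
    ])
    diff = ps.mean(axis=0) - pa.mean(axis=0)
    se = np.sqrt(
        ps.std(axis=0, ddof=1) ** 2 / 8 + pa.std(axis=0, ddof=1) ** 2 / 8
    )
    assert (np.abs(diff) <= 3 * se + 1e-12).all()


def test_deep_divergence_removes_shared_polymorphism():
    deep = dict(ALLO_P, T_DIV=1e6, N_ANC=1e4, T_RESIZE=4e2)
    e = expected_sfs(build_model("ALLO", deep, 4, 4), 20_000, 78)
    p = e.probs / e.probs.sum()
    shared = p[1:4, 1:4].sum()  # polymorphic in both demes simultaneously
    assert shared < 0.01


def test_ghost_with_no_migration_marginalises_away():
    """A ghost deme that never exchanges migrants leaves the joint
    spectrum of the sampled pair unchanged (Monte-Carlo tolerance)."""
    gp = dict(N_ANC=5e4, N1_ANC=2e4, N2_ANC=2e4, N1=5e3, N2=5e3,
              N_GHOST=1e4, T_DIV=4e3, T_RESIZE=4e2, T_DG=2e3, M_GHOST=1e-10)
    batches_g = [
        expected_sfs(build_model("GHOST_F", gp, 4, 4), 10_000, 200 + i)
        for i in range(8)
    ]
    batches_a = [
        expected_sfs(build_model("ALLO", ALLO_P, 4, 4), 10_000, 300 + i)
        for i in range(8)
    ]
    pg = np.array([e.probs for e in batches_g])
    pa = np.array([e.probs for e in batches_a])
    diff = pg.mean(axis=0) - pa.mean(axis=0)
    se = np.sqrt(
        pg.std(axis=0, ddof=1) ** 2 / 8 + pa.std(axis=0, ddof=1) ** 2 / 8
    )
    assert (np.abs(diff) <= 3 * se + 1e-12).all()


def test_ghost_topologies_join_correct_sister():
    gp = dict(N_ANC=5e4, N1_ANC=2e4, N2_ANC=2e4, N1=5e3, N2=5e3,
              N_GHOST=1e4, T_DIV=4e3, T_RESIZE=4e2, T_DG=2e3, M_GHOST=0.5)
    for sid, sister in [("GHOST_F", "pol"), ("GHOST_G", "pol"),
                        ("GHOST_H", "aq"), ("GHOST_I", "aq")]:
        model = build_model(sid, gp, 4, 4)
        joins = [e for e in model.events if type(e).__name__ == "Join"]
        assert joins[0].source == "ghost" and joins[0].dest == sister


# ----------------------------------------------------------------------
# fitting machinery
# ----------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_obs():
    model = build_model("ALLO", ALLO_P, 4, 4)
    e = expected_sfs(model, 50_000, 99)
    pf = e.folded()
    pf[0, 0] += e.p_mono
    L = 2e8
    counts = np.rint(pf * L).astype(np.int64)
    mono = int(counts[0, 0])
    counts[0, 0] = 0
    return Folded2DSFS(counts=counts, monomorphic=mono, n1=4, n2=4)


def test_fit_is_deterministic_given_seed(tiny_obs):
    settings = FitSettings(n_runs=2, n_iters=3, n_sims=2_000, rng_seed=5)
    a = fit_model(tiny_obs, "ALLO", settings)
    b = fit_model(tiny_obs, "ALLO", settings)
    assert a.lnCL == b.lnCL
    assert a.params == b.params
    assert [r.lnCL for r in a.runs] == [r.lnCL for r in b.runs]


def test_fit_result_json_round_trip(tiny_obs, tmp_path):
    settings = FitSettings(n_runs=1, n_iters=2, n_sims=1_000, rng_seed=6)
    fit = fit_model(tiny_obs, "ALLO", settings)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = FitResult.from_json(str(path))
    assert back.params == fit.params
    assert back.lnCL == fit.lnCL
    assert back.obs_signature == fit.obs_signature


def test_compare_models_ranking_and_provenance(tiny_obs):
    settings = FitSettings(n_runs=1, n_iters=2, n_sims=1_000, rng_seed=7)
    fa = fit_model(tiny_obs, "ALLO", settings)
    fb = fit_model(tiny_obs, "SYM", settings)
    table = compare_models([fa, fb])
    assert list(table.columns) == ["scenario", "lnCL", "delta_lnCL", "n_params"]
    assert table["delta_lnCL"].iloc[0] == 0.0
    assert table["lnCL"].is_monotonic_decreasing
    # identical fits tie stably by scenario id
    tie = compare_models([fa, fa])
    assert list(tie["scenario"]) == ["ALLO", "ALLO"]
    other = Folded2DSFS(
        counts=tiny_obs.counts.copy(), monomorphic=tiny_obs.monomorphic + 1,
        n1=4, n2=4,
    )
    fc = fit_model(other, "ALLO", settings)
    with pytest.raises(ValueError, match="different observed"):
        compare_models([fa, fc])


# ----------------------------------------------------------------------
# natural-unit scaling
# ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "generations, years",
    [(209_560, 523_900), (224_698, 561_745), (213_277, 533_193), (0, 0)],
)
def test_generation_to_year_scaling(generations, years):
    assert generations_to_years(generations) == years


def test_scale_parameters_units(tiny_obs):
    fit = FitResult(
        scenario="SYM_ASYM",
        params=dict(N_ANC=431_527.0, N1_ANC=208_665.0, N2_ANC=309_413.0,
                    N1=279_462.0, N2=51_724.0, T_DIV=224_698.0,
                    T_RESIZE=7_520.0, M_ANC_AP=1.25, M_ANC_PA=1e-9,
                    M_REC_AP=3.19, M_REC_PA=0.21),
        lnCL=-1.0, runs=[], settings={}, n1=4, n2=4,
        obs_signature=(4, 4, 0, 0),
    )
    scaled = scale_parameters(fit)
    assert scaled.times_years["T_DIV"] == 561_745
    assert scaled.times_years["T_RESIZE"] == 18_800
    for name, gens in scaled.times_generations.items():
        assert scaled.times_years[name] == round(gens * 2.5)
    assert scaled.mig_2nm["M_ANC_AP"] == 1.25
    assert scaled.sizes_haploid["N_ANC"] == 431_527.0
    frame = scaled.to_frame()
    assert set(frame["unit"]) == {"haploids", "generations", "years", "2Nm"}
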