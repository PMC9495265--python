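import numpy as np
import pandas as pd
import pytest

from metacomm.core_io import EnvironmentTable, ValidationError
from metacomm.rda_varpart import (collinearity_screen, marginal_env_screen,
                                  partial_rda, rda, reduce_connectivity,
                                  sweep_frame, alpha_sweep_varpart,
                                  variation_partition)
from metacomm.spatial_mem import build_mem
from metacomm.synthetic_data import generate, scenario_config

from conftest import random_community, random_geometry


def _env(values, names=None):
    names = names or [f"v{k}" for k in range(values.shape[1])]
    ids = tuple(f"s{i}" for i in range(values.shape[0]))
    return EnvironmentTable(ids, pd.DataFrame(values, columns=names))


# ---------------------------------------------------------------------------
# collinearity screen
# ---------------------------------------------------------------------------

def test_duplicated_column_dropped(rng):
    x = rng.normal(size=30)
    env = _env(np.column_stack([x, x, rng.normal(size=30)]))
    report, reduced = collinearity_screen(env, threshold=0.9)
    assert len(report.dropped) == 1
    assert len(reduced.variables) == 2
    assert report.dropped.iloc[0]["rho"] == pytest.approx(1.0)


def test_sign_symmetric_drop(rng):
    x = rng.normal(size=30)
    env = _env(np.column_stack([x, -x, rng.normal(size=30)]))
    report, reduced = collinearity_screen(env, threshold=0.9)
    assert len(report.dropped) == 1
    assert report.dropped.iloc[0]["rho"] == pytest.approx(-1.0)


def test_monotone_nonlinear_detected(rng):
    x = rng.normal(size=50)
    env = _env(np.column_stack([x, x ** 3, rng.normal(size=50)]))
    report, _ = collinearity_screen(env, threshold=0.9)
    # Spearman sees the monotone cube as rho = 1 even though Pearson < 1
    assert report.rho.iloc[0, 1] == pytest.approx(1.0)
    assert len(report.dropped) == 1


def test_no_drop_below_threshold(rng):
    env = _env(rng.normal(size=(40, 4)))
    report, reduced = collinearity_screen(env, threshold=0.9)
    assert report.dropped.empty
    assert reduced.variables == env.variables


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def test_rda_single_pair_equals_squared_correlation(rng):
    x = rng.normal(size=25)
    y = 0.6 * x + rng.normal(size=25)
    res = rda(y[:, None], x[:, None], n_perm=0)
    assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)


def test_rda_orthogonal_predictor_null(rng):
    y = rng.normal(size=(30, 4))
    x = rng.normal(size=30)
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    # residualize x against every species column -> orthogonal predictor
    coef, *_ = np.linalg.lstsq(yc, xc, rcond=None)
    x_orth = xc - yc @ coef
    res = rda(yc, x_orth[:, None], n_perm=0)
    assert res.r2 < 1e-10


def test_rda_saturated_r2_one(rng):
    y = rng.normal(size=(20, 5))
    yc = y - y.mean(axis=0)
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    res = rda(yc, u[:, :5], n_perm=0)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)


def test_rda_rank_guard(rng):
    y = rng.normal(size=(10, 3))
    x = rng.normal(size=(10, 9))
    with pytest.raises(ValidationError, match="rank"):
        rda(y, x, n_perm=0)


def test_rda_matches_per_species_ols_oracle(rng):
    for _ in range(100):
        y = rng.normal(size=(15, 8))
        x = rng.normal(size=(15, 3))
        res = rda(y, x, n_perm=0)
        yc = y - y.mean(axis=0)
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        fit_ss = 0.0
        for k in range(8):
            beta, *_ = np.linalg.lstsq(xs, yc[:, k], rcond=None)
            fit_ss += ((xs @ beta) ** 2).sum()
        assert res.r2 == pytest.approx(fit_ss / (yc ** 2).sum(), abs=1e-10)


def test_rda_permutation_p_significant_signal(rng):
    x = rng.normal(size=40)
    y = np.column_stack([x + rng.normal(0, 0.3, 40) for _ in range(4)])
    res = rda(y, x[:, None], n_perm=199, seed=0)
    assert res.p_perm == pytest.approx(1 / 200)


def test_partial_rda_removes_shared_signal(rng):
    z = rng.normal(size=(30, 2))
    y = z @ rng.normal(size=(2, 5)) + rng.normal(0, 0.1, size=(30, 5))
    res = partial_rda(y, z[:, ::-1] * 2.0, z, n_perm=99, seed=0)
    assert res.r2 == pytest.approx(0.0, abs=1e-12)  # x spans the same space as z
    assert res.rank == 0


# ---------------------------------------------------------------------------
# marginal screen
# ---------------------------------------------------------------------------

def test_marginal_screen_finds_signal(rng):
    v = rng.normal(size=40)
    y = np.column_stack([v + rng.normal(0, 0.5, 40) for _ in range(6)])
    env = _env(np.column_stack([v, rng.normal(size=40), rng.normal(size=40)]),
               names=["signal", "noise1", "noise2"])
    df = marginal_env_screen(y, env, n_perm=199, seed=0)
    assert df.iloc[0]["variable"] == "signal"
    assert bool(df.iloc[0]["retained"])


def test_marginal_screen_type_one_rate(rng):
    retained = 0
    n_rep = 400
    for rep in range(n_rep):
        y = rng.normal(size=(20, 3))
        env = _env(rng.normal(size=(20, 1)), names=["noise"])
        df = marginal_env_screen(y, env, n_perm=99, seed=rep)
        retained += int(df["retained"].iloc[0])
    rate = retained / n_rep
    assert 0.02 <= rate <= 0.08


def test_marginal_screen_duplicate_symmetry(rng):
    v = rng.normal(size=30)
    y = np.column_stack([v + rng.normal(0, 0.4, 30) for _ in range(4)])
    env = _env(np.column_stack([v, v]), names=["a", "b"])
    df = marginal_env_screen(y, env, n_perm=199, seed=0)
    assert df["r2"].iloc[0] == pytest.approx(df["r2"].iloc[1], abs=1e-12)
    assert df["retained"].all()


# ---------------------------------------------------------------------------
# connectivity reduction
# ---------------------------------------------------------------------------

def test_reduce_rank_one_single_axis(rng):
    u = rng.normal(size=20)
    c = np.outer(u, rng.uniform(1, 2, size=7))
    axes = reduce_connectivity(c, variance_kept=0.9)
    assert axes.shape == (20, 1)


def test_reduce_orthogonal_axes_variance(rng):
    c = rng.normal(size=(30, 12))
    axes = reduce_connectivity(c, variance_kept=0.9)
    gram = axes.T @ axes
    off = gram - np.diag(np.diag(gram))
    assert np.allclose(off, 0.0, atol=1e-8)
    cs = (c - c.mean(0)) / c.std(0)
    kept = (axes ** 2).sum() / (cs ** 2).sum()
    cap = 30 // 3
    assert kept >= 0.9 or axes.shape[1] == cap


def test_reduce_matches_eigendecomposition(rng):
    c = rng.normal(size=(25, 6))
    axes = reduce_connectivity(c, variance_kept=0.99)
    cs = (c - c.mean(0)) / c.std(0)
    vals, vecs = np.linalg.eigh(cs.T @ cs)
    order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    for k in range(axes.shape[1]):
        corr = abs(np.corrcoef(axes[:, k], cs @ vecs[:, k])[0, 1])
        assert corr == pytest.approx(1.0, abs=1e-8)


def test_reduce_all_constant_error():
    with pytest.raises(ValidationError, match="constant"):
        reduce_connectivity(np.ones((10, 3)))


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

def test_identical_blocks_share_everything(rng):
    y = rng.normal(size=(25, 6))
    e = rng.normal(size=(25, 2))
    c = rng.normal(size=(25, 2))
    vp = variation_partition(y, e, e * 3.0, c, n_perm=0)
    assert vp.unique_e == pytest.approx(0.0, abs=1e-10)
    assert vp.unique_s == pytest.approx(0.0, abs=1e-10)
    # everything E explains is shared with its duplicate block (up to the
    # incidental overlap with the unrelated C block)
    assert vp.shared_es + vp.shared_esc == pytest.approx(vp.r2_e, abs=1e-10)


def test_environment_only_generator(rng):
    e = rng.normal(size=(40, 2))
    y = e @ rng.normal(size=(2, 8)) + rng.normal(0, 0.2, size=(40, 8))
    s = rng.normal(size=(40, 2))
    c = rng.normal(size=(40, 2))
    vp = variation_partition(y, e, s, c, n_perm=0)
    e_related = vp.unique_e + vp.shared_es + vp.shared_ec + vp.shared_esc
    assert e_related > 0.8 * vp.total
    assert vp.unique_c < 0.1
    assert vp.dominant() == "environment"


def test_fraction_sum_identity_random_instances(rng):
    for _ in range(100):
        n = rng.integers(15, 30)
        y = rng.normal(size=(n, 5))
        blocks = [rng.normal(size=(n, rng.integers(1, 4))) for _ in range(3)]
        vp = variation_partition(y, *blocks, n_perm=0)
        assert sum(vp.fractions().values()) == pytest.approx(vp.total, abs=1e-10)
        assert vp.residual == pytest.approx(1 - vp.total, abs=1e-12)


def test_varpart_block_order_invariant(rng):
    y = rng.normal(size=(25, 6))
    e, s, c = (rng.normal(size=(25, 2)) for _ in range(3))
    vp1 = variation_partition(y, e, s, c, n_perm=0)
    vp2 = variation_partition(y, s, c, e, n_perm=0)
    # relabelled blocks swap roles but totals and the fraction multiset agree
    assert vp1.total == pytest.approx(vp2.total, abs=1e-12)
    assert sorted([vp1.unique_e, vp1.unique_s, vp1.unique_c]) == \
        pytest.approx(sorted([vp2.unique_e, vp2.unique_s, vp2.unique_c]), abs=1e-10)


def test_varpart_combined_rank_guard(rng):
    y = rng.normal(size=(10, 4))
    blocks = [rng.normal(size=(10, 3)) for _ in range(3)]
    with pytest.raises(ValidationError, match="rank"):
        variation_partition(y, *blocks, n_perm=0)


def test_varpart_deterministic_with_seed(rng):
    y = rng.normal(size=(25, 6))
    e, s, c = (rng.normal(size=(25, 2)) for _ in range(3))
    vp1 = variation_partition(y, e, s, c, n_perm=99, seed=42)
    vp2 = variation_partition(y, e, s, c, n_perm=99, seed=42)
    assert vp1 == vp2


# ---------------------------------------------------------------------------
# alpha sweep
# ---------------------------------------------------------------------------

def _sweep_setup(seed=0):
    cfg = scenario_config("dispersal", seed=seed)
    cm, geom, env, part, truth = generate(cfg)
    memb = build_mem(geom)
    s_axes = memb.eigenvectors[:, :8]
    e_axes = env.data.to_numpy(float)[:, :3]
    return cm, geom, e_axes, s_axes


def test_sweep_metric_n_alpha_invariant():
    cm, geom, e_axes, s_axes = _sweep_setup()
    from metacomm.connectivity import metric_N
    from metacomm.rda_varpart import variation_partition as vp_fn
    n_mat = metric_N(cm, geom)[0]
    y = cm.incidence()
    c_axes = reduce_connectivity(None, n_mat)
    results = [vp_fn(y, e_axes, s_axes, c_axes, n_perm=0) for _ in range(2)]
    assert results[0] == results[1]  # nothing depends on alpha without metric C


def test_sweep_deterministic():
    cm, geom, e_axes, s_axes = _sweep_setup(seed=1)
    grid = [30.0, 100.0, 300.0]
    r1 = alpha_sweep_varpart(cm, geom, e_axes, s_axes, alpha_grid=grid, n_perm=0)
    r2 = alpha_sweep_varpart(cm, geom, e_axes, s_axes, alpha_grid=grid, n_perm=0)
    assert r1 == r2


def test_sweep_dispersal_generator_connectivity_peaks():
    cm, geom, e_axes, s_axes = _sweep_setup(seed=2)
    grid = [20.0, 100.0, 500.0]
    res = alpha_sweep_varpart(cm, geom, e_axes, s_axes, alpha_grid=grid, n_perm=0)
    uc = [r.unique_c for r in res]
    ue = [r.unique_e for r in res]
    assert all(c > e for c, e in zip(uc, ue))
    df = sweep_frame(res)
    assert set(df["fraction"]) == {"total", "unique_e", "unique_s", "unique_c"}
    assert len(df) == 12
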