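"""DD-SIMCA tests: distances, moment DoF estimation, acceptance calibration."""

import numpy as np
import pytest
from scipy.stats import chi2

from nirsimca import (
    dd_decide,
    distances,
    estimate_dof,
    fit_ddsimca,
    fit_pca,
    total_distance,
)
from nirsimca.ddsimca import DOF_CEILING, DDSIMCAModel
from conftest import make_spectrum_set


# ------------------------------------------------------------ distances

def test_distances_at_training_mean():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 40))
    pca = fit_pca(X, 3)
    h, v = distances(pca, X.mean(axis=0)[None, :])
    assert h[0] == pytest.approx(0.0, abs=1e-12)
    assert v[0] == pytest.approx(0.0, abs=1e-12)


def test_full_rank_orthogonal_distance_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 40))
    pca = fit_pca(X, 14)
    _, v = distances(pca, X)
    assert np.allclose(v, 0.0, atol=1e-10)


def test_score_distance_matches_mahalanobis_oracle():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 40)) * np.linspace(3, 0.1, 40)
    pca = fit_pca(X, 4)
    h, _ = distances(pca, X)
    T = (X - pca.center) @ pca.loadings
    inv = np.linalg.inv(np.cov(T, rowvar=False))
    oracle = np.einsum("ij,jk,ik->i", T, inv, T)
    assert np.allclose(h, oracle, rtol=1e-8)


def test_score_distance_rotation_invariant_via_full_covariance():
    """The Mahalanobis score distance does not depend on which orthonormal
    basis spans the PC subspace, provided the full score covariance is used."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 40)) * np.linspace(2, 0.2, 40)
    pca = fit_pca(X, 3)
    h, v = distances(pca, X)
    theta = 0.7
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    L_rot = pca.loadings @ R
    T_rot = (X - pca.center) @ L_rot
    inv = np.linalg.inv(np.cov(T_rot, rowvar=False))
    h_rot = np.einsum("ij,jk,ik->i", T_rot, inv, T_rot)
    assert np.allclose(h_rot, h, rtol=1e-8)
    resid = (X - pca.center) - T_rot @ L_rot.T
    assert np.allclose(np.einsum("ij,ij->i", resid, resid), v, rtol=1e-8)


# ------------------------------------------------------------ DoF estimation

@pytest.mark.parametrize("dof", [1, 4])
def test_estimate_dof_recovers_chi2(dof):
    rng = np.random.default_rng(100 + dof)
    d0 = 2.5
    draws = d0 * rng.chisquare(dof, size=100_000) / dof
    scaling, n = estimate_dof(draws)
    assert n == dof
    assert scaling == pytest.approx(d0, rel=0.02)


def test_estimate_dof_degenerate():
    _, n = estimate_dof(np.full(10, 3.0))
    assert n == DOF_CEILING
    with pytest.raises(ValueError, match="at least 5"):
        estimate_dof(np.ones(3))


def test_effective_dof_recovered_from_pca_scores():
    """h of an A=2 Gaussian class is ~chi2(2): the moment estimator
    recovers N_h = 2 (+-1) at large n."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(100_000, 34)) * np.concatenate([[5, 3], 0.05 * np.ones(32)])
    pca = fit_pca(X, 2)
    h, _ = distances(pca, X)
    _, n_h = estimate_dof(h)
    assert abs(n_h - 2) <= 1


# ------------------------------------------------------------ fitting/decide

def test_alpha_monotonicity_of_c_crit():
    rng = np.random.default_rng(5)
    data = make_spectrum_set(rng.normal(size=(30, 40)))
    crits = [
        fit_ddsimca(data, "TestBrand", A=2, alpha=a, preprocess=None).c_crit
        for a in (1e-7, 1e-6, 1e-2, 0.05)
    ]
    assert np.all(np.diff(crits) < 0)


def test_refit_on_permuted_rows_identical():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(25, 40))
    m1 = fit_ddsimca(make_spectrum_set(X), "TestBrand", A=2, preprocess=None)
    m2 = fit_ddsimca(
        make_spectrum_set(X[rng.permutation(25)]), "TestBrand", A=2, preprocess=None
    )
    assert np.allclose(m1.pca.center, m2.pca.center)
    assert np.allclose(np.abs(m1.pca.loadings), np.abs(m2.pca.loadings), atol=1e-8)
    assert m1.h0 == pytest.approx(m2.h0, rel=1e-9)
    assert (m1.n_h, m1.n_v, m1.c_crit) == (m2.n_h, m2.n_v, m2.c_crit)


def test_n_exceeding_components_required():
    rng = np.random.default_rng(7)
    data = make_spectrum_set(rng.normal(size=(3, 40)))
    with pytest.raises(ValueError, match="more training samples"):
        fit_ddsimca(data, "TestBrand", A=3, preprocess=None)


def test_boundary_sample_accepted():
    """A sample with c exactly equal to c_crit is accepted (inclusive rule)."""
    rng = np.random.default_rng(8)
    data = make_spectrum_set(rng.normal(size=(30, 40)))
    model = fit_ddsimca(data, "TestBrand", A=2, alpha=0.05, preprocess=None)
    # a synthetic sample along the first loading, roughly on the boundary
    t = np.sqrt(model.c_crit / model.n_h * model.h0 * model.pca.component_variances[0])
    x = model.pca.center + t * model.pca.loadings[:, 0]
    probe = make_spectrum_set(x[None, :])
    c = float(dd_decide(model, probe).table["c"].iloc[0])
    assert c == pytest.approx(model.c_crit, rel=1e-9)
    # pin the threshold exactly at the computed c: the tie must be accepted
    from dataclasses import replace

    exact = replace(model, c_crit=c)
    assert bool(dd_decide(exact, probe).table["accepted"].iloc[0])
    below = replace(model, c_crit=np.nextafter(c, 0.0))
    assert not bool(dd_decide(below, probe).table["accepted"].iloc[0])


def test_acceptance_region_monotone():
    rng = np.random.default_rng(9)
    data = make_spectrum_set(rng.normal(size=(40, 40)))
    model = fit_ddsimca(data, "TestBrand", A=2, alpha=0.05, preprocess=None)
    dec = dd_decide(model, data)
    acc = dec.table[dec.table["accepted"]]
    rej = dec.table[~dec.table["accepted"]]
    for _, r in rej.iterrows():
        dominated = (acc["h"] >= r["h"]) & (acc["v"] >= r["v"])
        assert not dominated.any()


@pytest.mark.parametrize("alpha", [0.05, 0.01])
def test_acceptance_calibration(alpha):
    """In-model Gaussian data: acceptance fraction is at least 1 - 2*alpha
    (and near 1 - alpha) at significance alpha."""
    rng = np.random.default_rng(10)
    X = rng.normal(size=(10_000, 34)) * np.concatenate([[4, 2], 0.3 * np.ones(32)])
    data = make_spectrum_set(X)
    model = fit_ddsimca(data, "TestBrand", A=2, alpha=alpha, preprocess=None)
    dec = dd_decide(model, data)
    frac = dec.table["accepted"].mean()
    assert frac >= 1 - 2 * alpha
    assert frac == pytest.approx(1 - alpha, abs=0.02)


def test_total_distance_combination():
    rng = np.random.default_rng(11)
    data = make_spectrum_set(rng.normal(size=(30, 40)))
    model = fit_ddsimca(data, "TestBrand", A=2, alpha=1e-6, preprocess=None)
    h = np.array([model.h0])
    v = np.array([model.v0])
    c = total_distance(model, h, v)
    assert c[0] == pytest.approx(model.n_h + model.n_v, rel=1e-12)
    assert model.c_crit == pytest.approx(
        chi2.ppf(1 - 1e-6, model.n_h + model.n_v), rel=1e-12
    )


def test_foreign_brands_rejected_end_to_end(study_data, study_split):
    """Study-scale check: DD-SIMCA at alpha=1e-6 rejects every spectrum of
    every other brand and every falsified tablet."""
    from nirsimca.study import DD_BRANDS

    pool = study_data.by_sample_ids(study_split["__test_pool__"]["test"])
    for brand in DD_BRANDS:
        training = study_data.by_sample_ids(study_split[brand]["train"])
        model = fit_ddsimca(training, brand, A=2, alpha=1e-6)
        dec = dd_decide(model, pool)
        merged = dec.table.merge(pool.metadata, on="sample_id")
        foreign = merged[(merged["brand"] != brand) | merged["falsified"]]
        assert not foreign["accepted"].any()
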