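"""Beta-regression projection, distances, staging and PCA display.

The maximum-likelihood fit is validated against an independent
grid-search oracle that scans (β, log φ) and evaluates the beta
log-likelihood directly through scipy's density.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from splicestage.datamodel import PsiMatrix, ReferenceAtlas
from splicestage.staging import (
    SplicescopeStager,
    _shrink_boundary,
    stage_accuracy,
)
from splicestage.synthetic import simulate_query, simulate_sensory_query


def beta_loglik(y, X, beta, phi):
    """Direct log-likelihood under the mean/precision parameterization."""
    mu = expit(X @ np.asarray(beta))
    return float(
        np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))
    )


def toy_stager(n_exons=10, n_ref=2, seed=0, min_exons=3):
    rng = np.random.default_rng(seed)
    ref = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n_exons, n_ref)),
        index=[f"e{i}" for i in range(n_exons)],
        columns=[f"r{j}" for j in range(n_ref)],
    )
    stage_map = {f"r{j}": j + 1 for j in range(n_ref)}
    atlas = ReferenceAtlas(PsiMatrix(ref), stage_map)
    return SplicescopeStager(min_exons=min_exons).fit(atlas), ref


# ----------------------------------------------------------- projection

def test_self_projection_reproduces_reference_column(stager, atlas):
    # the logit-link projection cannot reproduce a reference column
    # cell-by-cell (logit(x_j) is not in the span of the columns), but it
    # must track it closely on average and rank it nearest by distance
    for col in atlas.timepoints[:3]:
        y = atlas.psi_ref.psi[col]
        proj = stager.project_sample(y)
        err = (proj.mu_hat - y.loc[proj.mu_hat.index]).abs().mean()
        assert err < 0.06
        D = stager.sample_distances(proj)
        assert D.idxmin() == col


def test_ml_fit_attains_grid_search_likelihood_maximum():
    # grid-search oracle over (beta1, beta2, log phi) on toy instances
    for seed in range(3):
        st_, ref = toy_stager(seed=seed)
        rng = np.random.default_rng(100 + seed)
        beta_true = rng.normal(0, 1.2, 2)
        phi_true = 30.0
        mu = expit(ref.to_numpy() @ beta_true)
        y = rng.beta(mu * phi_true, (1 - mu) * phi_true)
        ys = pd.Series(y, index=ref.index)
        proj = st_.project_sample(ys)
        yv = _shrink_boundary(y, len(y))
        X = ref.to_numpy()
        # two-stage zoomed grid around the ML solution-independent center
        center = np.array([0.0, 0.0, np.log(20.0)])
        width = np.array([4.0, 4.0, 3.0])
        best = -np.inf
        for _ in range(3):
            axes = [np.linspace(c - w, c + w, 13)
                    for c, w in zip(center, width)]
            for b1, b2, lp in itertools.product(*axes):
                ll = beta_loglik(yv, X, [b1, b2], np.exp(lp))
                if ll > best:
                    best = ll
                    argbest = np.array([b1, b2, lp])
            center, width = argbest, width / 4
        assert proj.loglik >= best - 1e-4
        ml_ll = beta_loglik(yv, X, proj.beta, proj.phi)
        assert ml_ll == pytest.approx(proj.loglik, abs=1e-6)


def test_boundary_psi_values_fit_without_error():
    st_, ref = toy_stager(seed=3)
    y = ref.iloc[:, 0].copy()
    y.iloc[0] = 0.0
    y.iloc[1] = 1.0
    proj = st_.project_sample(y)
    assert np.isfinite(proj.loglik)
    assert ((proj.mu_hat > 0) & (proj.mu_hat < 1)).all()


def test_insufficient_exons_raises():
    st_, ref = toy_stager(min_exons=50)
    with pytest.raises(ValueError, match="insufficient module-exon coverage"):
        st_.project_sample(ref.iloc[:, 0])


# ------------------------------------------------------------ distances

def test_squared_distance_hand_value():
    st_, _ = toy_stager()
    mu = pd.Series([0.5, 0.5], index=["e0", "e1"])
    st_.X_ref_ = pd.DataFrame({"r1": [0.4, 0.6]}, index=["e0", "e1"])
    from splicestage.staging import BetaProjection

    proj = BetaProjection(beta=np.zeros(1), phi=1.0, mu_hat=mu,
                          n_exons_used=2, loglik=0.0, converged=True)
    D = st_.sample_distances(proj)
    assert D["r1"] == pytest.approx(0.02)


def test_distance_invariant_to_exon_order(stager, atlas):
    y = atlas.psi_ref.psi.iloc[:, 2]
    D1 = stager.sample_distances(stager.project_sample(y))
    D2 = stager.sample_distances(
        stager.project_sample(y.sample(frac=1, random_state=1))
    )
    np.testing.assert_allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-6)


# ---------------------------------------------------------- stage calls

def test_stage_six_grouping_of_late_reference_samples(stager, atlas):
    # nearest reference P30 (or any P15+ column) must map to stage 6
    for col in ["P15", "P30", "4mo", "21mo"]:
        D = pd.Series(1.0, index=atlas.timepoints)
        D[col] = 0.0
        stage, S = stager.assign_stage(D)
        assert stage == 6
        assert S == 1.0


def test_confidence_extremes():
    st_, _ = toy_stager()
    D0 = pd.Series([0.0, 1.0], index=["r0", "r1"])
    stage, S = st_.assign_stage(D0)
    assert (stage, S) == (1, 1.0)
    Deq = pd.Series([0.3, 0.3], index=["r0", "r1"])
    stage, S = st_.assign_stage(Deq)
    assert S == 0.0
    assert stage == 1  # tie breaks toward the younger stage


def test_stage_accuracy_counts():
    acc = stage_accuracy([3, 4], [3, 3])
    assert acc == {"exact": 0.5, "within_one": 1.0}
    with pytest.raises(ValueError):
        stage_accuracy([], [])
    preds = [1, 2, 6, 4]
    truths = [2, 5, 6, 3]
    acc = stage_accuracy(preds, truths)
    assert acc["within_one"] >= acc["exact"]


# ------------------------------------------------------------------ PCA

def test_pca_matches_explicit_eigendecomposition():
    rng = np.random.default_rng(8)
    ref = pd.DataFrame(rng.uniform(0.2, 0.8, (5, 4)),
                       index=[f"e{i}" for i in range(5)],
                       columns=["r1", "r2", "r3", "r4"])
    atlas = ReferenceAtlas(PsiMatrix(ref),
                           {"r1": 1, "r2": 2, "r3": 3, "r4": 4})
    st_ = SplicescopeStager(min_exons=3).fit(atlas)
    coords = st_.pca_project()
    # oracle: eigen-decomposition of the sample covariance of columns
    M = ref.to_numpy().T
    C = M - M.mean(axis=0)
    cov = C.T @ C
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    proj = C @ v[:, order[:2]]
    for j in range(2):
        got = coords.iloc[:, j].to_numpy()
        want = proj[:, j]
        sign = np.sign(np.dot(got, want)) or 1.0
        np.testing.assert_allclose(got, sign * want, atol=1e-8)


def test_reference_mean_profile_projects_to_origin(stager, atlas):
    mean = atlas.psi_ref.psi.mean(axis=1)
    coords = stager.pca_project(mean.to_frame("mean_profile"))
    np.testing.assert_allclose(
        coords.loc["mean_profile"].to_numpy(), 0.0, atol=1e-8
    )


def test_reference_sample_projection_is_its_own_score(stager, atlas):
    col = atlas.timepoints[4]
    coords = stager.pca_project(atlas.psi_ref.psi[[col]].rename(
        columns={col: "asquery"}))
    np.testing.assert_allclose(
        coords.loc["asquery"].to_numpy(), coords.loc[col].to_numpy(),
        atol=1e-8,
    )


# -------------------------------------------------------------- predict

def test_subset_equal_to_all_exons_is_identity(stager, atlas, truth):
    q, _ = simulate_query(truth, "P4", seed=5)
    q = q.reindex(atlas.exon_ids).dropna()
    full = stager.predict_detail(q.to_frame("q"), with_pca=False)[0]
    sub = stager.predict_detail(q.to_frame("q"), subset=list(atlas.exon_ids),
                                with_pca=False)[0]
    assert full.stage == sub.stage
    np.testing.assert_allclose(full.distances.to_numpy(),
                               sub.distances.to_numpy(), rtol=1e-6)


def test_query_generated_at_reference_age_recovers_its_stage(
        stager, atlas, truth):
    q, st_true = simulate_query(truth, "P4", coverage_mean=100,
                                noise_sd=0.05, seed=11)
    pred = stager.predict_detail(
        q.reindex(atlas.exon_ids).to_frame("q"), with_pca=False)[0]
    assert st_true == 4
    assert pred.stage == 4


def test_empty_subset_intersection_raises(stager, atlas, truth):
    q, _ = simulate_query(truth, "P4", seed=5)
    with pytest.raises(ValueError, match="does not intersect"):
        stager.predict_detail(q.to_frame("q"), subset=["nope"])


def test_sensory_query_dissociates_module_subsets(stager, atlas, truth):
    q, _ = simulate_sensory_query(truth, seed=3)
    mod = truth.module_of()
    m1 = mod[mod.str.startswith("M1")].index
    m2 = mod[mod.str.startswith("M2")].index
    p_m2 = stager.predict_detail(q.to_frame("s"), subset=m2,
                                 with_pca=False)[0]
    p_m1 = stager.predict_detail(q.to_frame("s"), subset=m1,
                                 with_pca=False)[0]
    assert p_m2.stage <= 2
    assert p_m1.stage >= 5


def test_monotone_degradation_of_confidence_with_noise(stager, atlas, truth):
    mean_conf = []
    for noise in [0.0, 0.1, 0.25]:
        confs = []
        for seed in range(4):
            q, _ = simulate_query(truth, "P7", coverage_mean=None,
                                  noise_sd=noise, seed=seed)
            p = stager.predict_detail(
                q.reindex(atlas.exon_ids).to_frame("q"), with_pca=False)[0]
            confs.append(p.confidence)
        mean_conf.append(np.mean(confs))
    assert mean_conf[0] >= mean_conf[1] >= mean_conf[2]
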