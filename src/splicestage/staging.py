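"""Splicescope: stage a sample's neuronal maturation from its Ψ profile.

A query sample's module-exon inclusion vector ``y`` is modeled with a
beta regression on the reference profiles:

    y_i ~ Beta(mu_i, phi)   with  E(y_i) = mu_i,
                                  var(y_i) = mu_i (1 − mu_i)/(1 + phi)
    logit(mu_i) = Σ_j x_ij β_j          (no intercept)

where ``x_ij`` is exon i's inclusion level in reference time point j.
The maximum-likelihood fit projects the query into the subspace spanned
by the reference columns. The distance to each reference sample j is
the sum of squared differences

    D_j = Σ_i (x_ij − mu_hat_i)²

(as printed — not rooted), the stage is the 1-nearest-neighbor's stage,
and the prediction confidence is S = 1 − min(D)/max(D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA

from .datamodel import PsiMatrix, ReferenceAtlas

__all__ = [
    "BetaProjection",
    "StagePrediction",
    "SplicescopeStager",
    "project_sample",
    "sample_distances",
    "assign_stage",
    "stage_accuracy",
    "pca_project",
    "predict",
]


def _shrink_boundary(y: np.ndarray, n: int) -> np.ndarray:
    """Pull exact 0/1 values into (0, 1): y' = (y (n−1) + 0.5)/n."""
    return (y * (n - 1) + 0.5) / n


def _beta_negloglik_grad(theta, X, y):
    """Negative beta log-likelihood and gradient wrt (beta, log phi)."""
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    eta = X @ beta
    mu = expit(eta)
    p = mu * phi
    q = (1.0 - mu) * phi
    logy = np.log(y)
    log1my = np.log1p(-y)
    ll = np.sum(
        gammaln(phi) - gammaln(p) - gammaln(q)
        + (p - 1.0) * logy + (q - 1.0) * log1my
    )
    ystar = logy - log1my
    mustar = digamma(p) - digamma(q)
    dmu = phi * (ystar - mustar) * mu * (1.0 - mu)
    gbeta = X.T @ dmu
    gphi = np.sum(
        digamma(phi) - mu * digamma(p) - (1.0 - mu) * digamma(q)
        + mu * logy + (1.0 - mu) * log1my
    )
    grad = np.concatenate([gbeta, [gphi * phi]])
    return -ll, -grad


@dataclass
class BetaProjection:
    """ML beta-regression projection of one query onto the reference."""

    beta: np.ndarray
    phi: float
    mu_hat: pd.Series
    n_exons_used: int
    loglik: float
    converged: bool


@dataclass
class StagePrediction:
    """Stage call for one query sample."""

    sample: str
    stage: int
    confidence: float
    distances: pd.Series
    pca_xy: tuple[float, float] | None = None
    subset_tag: str = "all"
    n_exons_used: int = 0

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "stage": int(self.stage),
            "confidence": float(self.confidence),
            "distances": {k: float(v) for k, v in self.distances.items()},
            "pca_xy": None if self.pca_xy is None else
            [float(self.pca_xy[0]), float(self.pca_xy[1])],
            "subset_tag": self.subset_tag,
            "n_exons_used": int(self.n_exons_used),
        }


class SplicescopeStager(BaseEstimator, ClassifierMixin):
    """Beta-regression 1-NN stage classifier against a developmental reference.

    Fit on a reference atlas (exon × time-point Ψ profiles with a
    time-point → stage map); predict projects each query by maximum
    likelihood, compares squared distances to every reference column
    and returns the nearest reference's stage.

    Parameters
    ----------
    min_exons : int
        Minimum exons jointly quantified in query and reference.
    max_restarts : int
        Optimizer restarts with damped steps on non-convergence.
    intercept : bool
        Add an intercept column to the regression design (off by
        default; the canonical model has none).

    Attributes
    ----------
    atlas_ : ReferenceAtlas — the fitted reference.
    X_ref_ : DataFrame, complete exon × time-point reference profiles.
    classes_ : sorted unique stages.
    """

    def __init__(self, min_exons: int = 50, max_restarts: int = 3,
                 intercept: bool = False):
        self.min_exons = min_exons
        self.max_restarts = max_restarts
        self.intercept = intercept

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None):
        """``X`` is a ReferenceAtlas, or an exon × time-point DataFrame
        with ``y`` the per-column stages (then a stage map is built)."""
        if isinstance(X, ReferenceAtlas):
            atlas = X
        else:
            X = X.psi if isinstance(X, PsiMatrix) else pd.DataFrame(X)
            if y is None:
                raise ValueError("supply per-timepoint stages y or a ReferenceAtlas")
            stage_map = {str(c): int(s) for c, s in zip(X.columns, y)}
            atlas = ReferenceAtlas(PsiMatrix(X), stage_map)
        ref = atlas.psi_ref.complete_rows()
        self.atlas_ = ReferenceAtlas(ref, dict(atlas.stage_map))
        self.X_ref_ = ref.psi
        self.classes_ = np.unique(self.atlas_.stages())
        self._pca = None
        return self

    # -- core steps ------------------------------------------------------
    def project_sample(self, y: pd.Series) -> BetaProjection:
        """ML beta regression of a query Ψ vector on the reference columns."""
        common = self.X_ref_.index.intersection(y.dropna().index)
        if len(common) < self.min_exons:
            raise ValueError(
                f"insufficient module-exon coverage: {len(common)} usable exons "
                f"(< {self.min_exons})"
            )
        Xd = self.X_ref_.loc[common].to_numpy(dtype=float)
        if self.intercept:
            Xd = np.hstack([np.ones((len(Xd), 1)), Xd])
        n = len(common)
        yv = _shrink_boundary(
            np.clip(y.loc[common].to_numpy(dtype=float), 0.0, 1.0), n
        )

        # init: OLS on the logit scale, method-of-moments phi
        eta0 = logit(yv)
        beta0, *_ = np.linalg.lstsq(Xd, eta0, rcond=None)
        mu0 = expit(Xd @ beta0)
        resid_var = max(np.var(yv - mu0), 1e-6)
        phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)

        theta0 = np.concatenate([beta0, [np.log(phi0)]])
        best = None
        for attempt in range(self.max_restarts + 1):
            res = optimize.minimize(
                _beta_negloglik_grad, theta0, args=(Xd, yv),
                jac=True, method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
            theta0 = theta0 * 0.5  # damped restart toward the origin
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("beta regression failed to converge: "
                               f"{getattr(best, 'message', 'no result')}")
        beta_hat = best.x[:-1]
        phi_hat = float(np.exp(best.x[-1]))
        mu_hat = pd.Series(expit(Xd @ beta_hat), index=common)
        return BetaProjection(
            beta=beta_hat, phi=phi_hat, mu_hat=mu_hat,
            n_exons_used=n, loglik=-float(best.fun),
            converged=bool(best.success),
        )

    def sample_distances(self, proj: BetaProjection) -> pd.Series:
        """Squared distance to each reference column over the exons used."""
        ref = self.X_ref_.loc[proj.mu_hat.index]
        diff = ref.sub(proj.mu_hat, axis=0)
        return (diff**2).sum(axis=0)

    def assign_stage(self, D: pd.Series) -> tuple[int, float]:
        """1-NN stage with confidence S = 1 − min(D)/max(D).

        Ties at the minimum break toward the younger (earlier) stage.
        """
        dmin, dmax = float(D.min()), float(D.max())
        S = 0.0 if dmax == 0 else 1.0 - dmin / dmax
        at_min = [lb for lb in D.index if D[lb] <= dmin + 1e-300]
        stage = min(self.atlas_.stage_map[lb] for lb in at_min)
        return stage, float(S)

    def pca_project(self, queries: pd.DataFrame | None = None) -> pd.DataFrame:
        """2-D PCA coordinates of the reference columns plus any queries.

        The PCA is fit on the reference only (exon-wise centered by the
        reference mean); queries are projected, with missing exons
        imputed by the reference mean. Display only.
        """
        ref = self.X_ref_
        if self._pca is None:
            self._pca = PCA(n_components=2, svd_solver="full")
            self._pca.fit(ref.to_numpy(dtype=float).T)
        coords = {
            lb: xy for lb, xy in zip(
                ref.columns, self._pca.transform(ref.to_numpy(float).T)
            )
        }
        if queries is not None:
            mean = ref.mean(axis=1)
            for col in queries.columns:
                q = queries[col].reindex(ref.index)
                q = q.fillna(mean)
                coords[col] = self._pca.transform(
                    q.to_numpy(dtype=float)[None, :]
                )[0]
        out = pd.DataFrame(coords, index=["pc1", "pc2"]).T
        return out

    # -- public API ------------------------------------------------------
    def predict_detail(self, Y, subset=None, with_pca: bool = True,
                       subset_tag: str | None = None
                       ) -> list[StagePrediction]:
        """Full predictions for queries ``Y`` (exon × sample DataFrame)."""
        if isinstance(Y, PsiMatrix):
            Y = Y.psi
        if isinstance(Y, pd.Series):
            Y = Y.to_frame("query")
        stager = self
        tag = "all"
        if subset is not None:
            subset = pd.Index(subset)
            keep = self.X_ref_.index.intersection(subset)
            if len(keep) == 0:
                raise ValueError("exon subset does not intersect the reference")
            stager = SplicescopeStager(
                min_exons=min(self.min_exons, max(len(keep) // 2, 3)),
                max_restarts=self.max_restarts, intercept=self.intercept,
            ).fit(ReferenceAtlas(
                PsiMatrix(self.X_ref_.loc[keep]), dict(self.atlas_.stage_map)
            ))
            tag = subset_tag or "subset"
        preds = []
        pca_coords = stager.pca_project(Y) if with_pca else None
        for col in Y.columns:
            proj = stager.project_sample(Y[col])
            D = stager.sample_distances(proj)
            stage, S = stager.assign_stage(D)
            xy = None
            if pca_coords is not None:
                xy = (pca_coords.loc[col, "pc1"], pca_coords.loc[col, "pc2"])
            preds.append(
                StagePrediction(
                    sample=str(col), stage=stage, confidence=S,
                    distances=D, pca_xy=xy, subset_tag=tag,
                    n_exons_used=proj.n_exons_used,
                )
            )
        return preds

    def predict(self, Y, subset=None) -> np.ndarray:
        """Predicted stage per query column."""
        return np.array(
            [p.stage for p in self.predict_detail(Y, subset=subset,
                                                  with_pca=False)]
        )

    def score(self, Y, y_true) -> float:
        """Exact-stage accuracy (sklearn convention)."""
        return stage_accuracy(self.predict(Y), y_true)["exact"]


# -- functional wrappers -------------------------------------------------

def _stager(atlas: ReferenceAtlas, **kw) -> SplicescopeStager:
    return SplicescopeStager(**kw).fit(atlas)


def project_sample(y: pd.Series, atlas: ReferenceAtlas,
                   min_exons: int = 50) -> BetaProjection:
    return _stager(atlas, min_exons=min_exons).project_sample(y)


def sample_distances(proj: BetaProjection, atlas: ReferenceAtlas) -> pd.Series:
    return _stager(atlas).sample_distances(proj)


def assign_stage(D: pd.Series, atlas: ReferenceAtlas) -> tuple[int, float]:
    return _stager(atlas).assign_stage(D)


def pca_project(atlas: ReferenceAtlas, queries=None) -> pd.DataFrame:
    return _stager(atlas).pca_project(queries)


def predict(query, atlas: ReferenceAtlas, subset=None,
            min_exons: int = 50) -> list[StagePrediction]:
    """One-shot staging of query Ψ profiles against a reference atlas."""
    return _stager(atlas, min_exons=min_exons).predict_detail(query, subset=subset)


def stage_accuracy(predictions, truths) -> dict[str, float]:
    """Exact and adjacency-tolerant (|Δstage| ≤ 1) stage accuracy."""
    pred = np.asarray(
        [p.stage if isinstance(p, StagePrediction) else p for p in predictions],
        dtype=float,
    )
    true = np.asarray(truths, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be non-empty and paired")
    delta = np.abs(pred - true)
    return {
        "exact": float(np.mean(delta == 0)),
        "within_one": float(np.mean(delta <= 1)),
    }
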