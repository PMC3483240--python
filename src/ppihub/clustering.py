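"""Model-based clustering of centrality profiles with BIC model selection.

Nodes are clustered on their normalized (0-100) centrality columns by
Gaussian mixtures fitted with EM over a small family of covariance
constraints, and the number of components G is chosen by the Bayesian
information criterion in the higher-is-better convention

    BIC = 2 * logL - m * log(n)

(m = number of free parameters). Each EM iteration is stepped explicitly so
the per-iteration log-likelihood trajectory is available — the trajectory
must be non-decreasing, a useful health check on any EM fit.

Covariance families (sklearn naming): ``spherical`` (per-component isotropic),
``diag`` (per-component axis-aligned), ``tied`` (one full covariance shared by
all components) and ``full`` (per-component full covariance; this is the
family that can express ellipsoidal clusters with variable orientation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "COVARIANCE_MODELS",
    "MixtureFit",
    "fit_mixture",
    "select_model",
    "summarize_clusters",
]

COVARIANCE_MODELS = ("spherical", "diag", "tied", "full")


@dataclass
class MixtureFit:
    """A converged Gaussian-mixture fit plus its selection statistics."""

    n_components: int
    covariance_model: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float
    n_parameters: int
    converged: bool
    assignments: dict = field(default_factory=dict)
    log_likelihood_path: list = field(default_factory=list)


def fit_mixture(
    data: pd.DataFrame | np.ndarray,
    G: int,
    covariance_model: str = "full",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg_covar: float = 1e-6,
) -> MixtureFit:
    """Fit a G-component Gaussian mixture by EM (k-means initialization).

    EM is run one iteration at a time until the total log-likelihood
    increases by less than ``tol`` (or ``max_iter`` is reached); the
    trajectory is recorded in ``log_likelihood_path``. Deterministic for a
    fixed seed.
    """
    X, index = _as_matrix(data)
    n = X.shape[0]
    if not (n > G >= 1):
        raise ValueError(f"need n > G >= 1, got n={n}, G={G}")
    if covariance_model not in COVARIANCE_MODELS:
        raise ValueError(f"unknown covariance model: {covariance_model!r}")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")

    gm = GaussianMixture(
        n_components=G,
        covariance_type=covariance_model,
        tol=tol,
        reg_covar=reg_covar,
        max_iter=1,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
        warm_start=True,
    )
    path: list[float] = []
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            ll = float(gm.score(X) * n)
            if path and ll - path[-1] < tol:
                path.append(ll)
                converged = True
                break
            path.append(ll)

    labels = gm.predict(X)
    m = int(gm._n_parameters())
    logl = path[-1]
    return MixtureFit(
        n_components=G,
        covariance_model=covariance_model,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=np.asarray(gm.covariances_).copy(),
        log_likelihood=logl,
        bic=2.0 * logl - m * np.log(n),
        n_parameters=m,
        converged=converged,
        assignments={node: int(c) for node, c in zip(index, labels)},
        log_likelihood_path=path,
    )


def select_model(
    data: pd.DataFrame | np.ndarray,
    G_range=range(1, 13),
    models=COVARIANCE_MODELS,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit every (G, covariance model) combination and keep the best BIC.

    Returns the winning fit and the full BIC table (one row per attempted
    combination; failed fits are kept in the table, flagged, and excluded
    from selection). Raises if every fit failed.
    """
    G_range = list(G_range)
    if not G_range:
        raise ValueError("G_range is empty")
    rows = []
    best: MixtureFit | None = None
    for model in models:
        for G in G_range:
            try:
                fit = fit_mixture(data, G, covariance_model=model, seed=seed, **fit_kwargs)
                ok = np.isfinite(fit.bic)
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {"G": G, "model": model, "bic": np.nan, "converged": False,
                     "error": str(exc)}
                )
                continue
            rows.append(
                {"G": G, "model": model, "bic": fit.bic,
                 "converged": fit.converged, "error": ""}
            )
            if ok and (best is None or fit.bic > best.bic):
                best = fit
    if best is None:
        raise RuntimeError("all mixture fits failed")
    return best, pd.DataFrame(rows)


def summarize_clusters(fit: MixtureFit, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster size, mean composite score and members.

    Clusters are relabelled C1..CG in ascending order of mean score, so the
    highest-scoring (most hub-like) cluster always carries the largest label.
    ``scores`` must cover exactly the nodes that were clustered and contain a
    ``score_i`` column.
    """
    from .scoring import SCORE_COLUMN

    nodes = set(fit.assignments)
    if nodes != set(scores.index):
        raise ValueError("fit and score table cover different node sets")
    s = scores[SCORE_COLUMN]
    groups: dict[int, list] = {}
    for node, comp in fit.assignments.items():
        groups.setdefault(comp, []).append(node)
    rows = []
    for comp, members in groups.items():
        members = sorted(members, key=str)
        rows.append(
            {
                "size": len(members),
                "mean_score": float(np.mean([s[m] for m in members])),
                "members": members,
            }
        )
    rows.sort(key=lambda r: r["mean_score"])
    for i, row in enumerate(rows, 1):
        row["cluster"] = f"C{i}"
    df = pd.DataFrame(rows, columns=["cluster", "size", "mean_score", "members"])
    return df.set_index("cluster")


def _as_matrix(data):
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, list(range(X.shape[0]))
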