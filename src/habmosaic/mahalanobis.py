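"""Mahalanobis-distance habitat suitability.

The presence sample defines an 'ideal' multivariate environment (mean mu,
covariance Sigma). Each cell's squared Mahalanobis distance

    D^2 = (x - mu)^T Sigma^{-1} (x - mu)

is mapped to a suitability in [0, 1] as the upper-tail probability of a
chi-square distribution with df = number of variables, so a cell at the
presence centroid scores exactly 1 and suitability decreases strictly with
D^2. A PCA of the standardized presence matrix supplies per-variable
contributions used for iterative variable removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from .covariates import CovariateStack
from .raster import Raster


@dataclass
class MahalanobisModel:
    mu: np.ndarray
    sigma: np.ndarray
    names: list[str]
    _cho: tuple | None = None

    @property
    def df(self) -> int:
        return len(self.mu)

    def _factor(self):
        if self._cho is None:
            self._cho = linalg.cho_factor(self.sigma, lower=True)
        return self._cho

    def d2(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance via a Cholesky solve (no explicit inverse)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X - self.mu
        solved = linalg.cho_solve(self._factor(), diff.T)
        return np.einsum("ij,ji->i", diff, solved)

    def suitability(self, X: np.ndarray) -> np.ndarray:
        """Upper-tail chi-square probability of D^2; 1 at x = mu."""
        return chi2.sf(self.d2(X), df=self.df)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "names": self.names,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MahalanobisModel":
        d = json.loads(Path(path).read_text())
        return cls(mu=np.array(d["mu"]), sigma=np.array(d["sigma"]),
                   names=d["names"])


def fit_mahalanobis(
    presence: np.ndarray, names: Sequence[str] | None = None,
    min_eig: float = 1e-10,
) -> MahalanobisModel:
    """Fit mu and Sigma (sample covariance, denominator n-1) at presences.

    Raises when Sigma is not positive-definite, naming the most collinear
    columns so the caller can drop one.
    """
    X = np.atleast_2d(np.asarray(presence, dtype=float))
    n, p = X.shape
    if names is None:
        names = [f"v{j}" for j in range(p)]
    names = list(names)
    if n <= p:
        raise ValueError("need more presences than variables")
    sd = X.std(axis=0)
    constant = [names[j] for j in range(p) if sd[j] == 0]
    if constant:
        raise ValueError(f"constant columns: {constant}")
    mu = X.mean(axis=0)
    sigma = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() <= min_eig:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"singular covariance; most collinear columns: "
            f"{names[i]!r} and {names[j]!r} (r={corr[i, j]:.3f})"
        )
    return MahalanobisModel(mu=mu, sigma=sigma, names=names)


def predict_mahalanobis(model: MahalanobisModel, stack: CovariateStack) -> Raster:
    """Suitability raster: chi-square upper-tail probability of D^2 per cell."""
    missing = set(model.names) - set(stack.names)
    if missing:
        raise KeyError(f"stack is missing variables: {sorted(missing)}")
    mask = stack.valid_mask()
    X = np.column_stack([stack.rasters[n].values[mask] for n in model.names])
    out = np.full(stack.grid.shape, np.nan)
    out[mask] = model.suitability(X)
    return stack.grid.with_values(out)


def pca_contribution(
    covariate_matrix: np.ndarray, names: Sequence[str] | None = None,
    variance_target: float = 0.80,
) -> dict[str, float]:
    """Per-variable PCA contribution for ranking in iterative removal.

    PCA on standardized columns; a variable's contribution is the sum over
    the components retained to reach ``variance_target`` cumulative variance
    of (squared loading x component variance share). Contributions sum to
    the retained variance share.
    """
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two variables")
    if names is None:
        names = [f"v{j}" for j in range(p)]
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [list(names)[j] for j in range(p) if sd[j] == 0]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    var = svals**2
    share = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(share), variance_target) + 1)
    contrib = (vt[:n_keep] ** 2 * share[:n_keep, None]).sum(axis=0)
    return dict(zip(names, contrib.tolist()))


def limiting_contribution(
    covariate_matrix: np.ndarray, names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-variable loading on the niche-compressed (limiting) dimensions.

    A species' habitat requirements show up as the principal components
    whose variance at presences falls *below* the standardized average: the
    combinations of covariates the animals hold nearly constant. Each
    component is weighted by its variance deficit ``max(0, 1 - lam/mean)``
    and a variable's contribution is its squared loading summed over these
    weighted components. Variables irrelevant to selection (free to vary at
    presences) score near zero.
    """
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two variables")
    if names is None:
        names = [f"v{j}" for j in range(p)]
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [list(names)[j] for j in range(p) if sd[j] == 0]
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    lam = svals**2
    weight = np.maximum(0.0, 1.0 - lam / lam.mean())
    contrib = (vt**2 * weight[:, None]).sum(axis=0)
    return dict(zip(names, contrib.tolist()))


def iterative_removal(
    presence: np.ndarray,
    names: Sequence[str],
    contribution_floor: float = 0.05,
    min_variables: int = 2,
) -> tuple[list[str], MahalanobisModel]:
    """Iteratively drop the variable contributing least to the presence niche.

    Each round runs a PCA of the standardized presence matrix, scores
    variables by :func:`limiting_contribution`, and removes the lowest
    scorer whenever its share of the total falls below
    ``contribution_floor``; stops when all survivors clear the floor or
    ``min_variables`` remain, then fits the final model.
    """
    X = np.atleast_2d(np.asarray(presence, dtype=float))
    keep = list(names)
    while True:
        contrib = limiting_contribution(
            X[:, [list(names).index(v) for v in keep]], keep)
        total = sum(contrib.values())
        rel = {v: c / total if total > 0 else 1.0 / len(keep)
               for v, c in contrib.items()}
        worst = min(rel, key=rel.get)
        if rel[worst] >= contribution_floor or len(keep) <= min_variables:
            break
        keep.remove(worst)
    model = fit_mahalanobis(X[:, [list(names).index(v) for v in keep]], keep)
    return keep, model
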