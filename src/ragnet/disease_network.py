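"""Disease-specific gene network prior and propagation.

A weighted undirected gene-interaction network is combined with gene-disease
association (GDA) scores and disease-similarity (DS) scores to seed a prior
relevance Y(v) = max_d GDA(v, d) * DS(d, target) per gene.  The prior is then
diffused over the degree-normalized adjacency by iterating

    F <- alpha * W' F + (1 - alpha) * Y,     W'_ij = W_ij / sqrt(D_i D_j)

to the fixed point F = (1 - alpha) (I - alpha W')^-1 Y, giving each gene a
smoothed disease correlation score that blends its own prior with the priors
of its interaction neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NetworkValidationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class DiseaseNetwork:
    """Gene interaction graph plus prior tables for the target disease.

    ``adjacency`` is a symmetric nonnegative matrix with zero diagonal over
    ``genes``; ``gda`` has columns (gene, disease, score) with scores in
    [0, 1]; ``ds`` has columns (disease, score) holding similarity of each
    disease to ``target_disease`` (the target itself at 1.0).
    """

    genes: list[str]
    adjacency: np.ndarray
    gda: pd.DataFrame
    ds: pd.DataFrame
    target_disease: str = "RA"

    def __post_init__(self) -> None:
        W = np.asarray(self.adjacency, dtype=float)
        if W.shape != (len(self.genes), len(self.genes)):
            raise NetworkValidationError("adjacency shape mismatch")
        if not np.allclose(W, W.T):
            raise NetworkValidationError("adjacency must be symmetric")
        if (W < 0).any():
            raise NetworkValidationError("edge weights must be nonnegative")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise NetworkValidationError("self-loops are not allowed")
        for df, col in ((self.gda, "score"), (self.ds, "score")):
            s = df[col].to_numpy(dtype=float)
            if ((s < 0) | (s > 1)).any():
                raise NetworkValidationError(f"{col}s must lie in [0, 1]")
        self.adjacency = W

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def normalized(self) -> np.ndarray:
        return normalize_adjacency(self.adjacency)


def normalize_adjacency(W: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization W'_ij = W_ij / sqrt(D_i D_j).

    Isolated nodes (zero degree) get all-zero rows/columns.  The spectral
    radius of the result is at most 1, which makes the propagation iteration
    a contraction for any restart parameter alpha < 1.
    """
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise NetworkValidationError("adjacency must be symmetric")
    if (W < 0).any():
        raise NetworkValidationError("edge weights must be nonnegative")
    d = W.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    nz = d > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    return W * inv_sqrt[:, None] * inv_sqrt[None, :]


def assign_prior(
    gda: pd.DataFrame,
    ds: pd.DataFrame,
    target_disease: str = "RA",
    genes: list[str] | None = None,
) -> pd.Series:
    """Prior disease relevance Y(v) = max_d GDA(v, d) * DS(d, target).

    The max runs over every disease associated with the gene; diseases
    missing from the DS table contribute similarity 0.  Genes without any
    GDA entry (or absent from the table) get Y = 0.
    """
    for df, name in ((gda, "GDA"), (ds, "DS")):
        s = df["score"].to_numpy(dtype=float)
        if ((s < 0) | (s > 1)).any():
            raise NetworkValidationError(f"{name} scores must lie in [0, 1]")
    ds_map = dict(zip(ds["disease"], ds["score"].astype(float)))
    if ds_map.get(target_disease) != 1.0:
        raise NetworkValidationError(
            f"DS table must contain {target_disease!r} with similarity 1.0")
    merged = gda.assign(
        weighted=gda["score"].astype(float)
        * gda["disease"].map(ds_map).fillna(0.0)
    )
    y = merged.groupby("gene")["weighted"].max()
    if genes is not None:
        y = y.reindex(genes).fillna(0.0)
    y.name = "Y"
    return y


@dataclass
class CorrelationScores:
    """Propagated per-gene disease correlation scores F(v)."""

    scores: pd.Series
    alpha: float
    iterations: int
    residual: float

    def __getitem__(self, gene: str) -> float:
        return float(self.scores.get(gene, 0.0))


def propagate(
    W_norm: np.ndarray,
    prior: pd.Series,
    alpha: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> CorrelationScores:
    """Diffuse the prior over the normalized network to the fixed point.

    Iterates F <- alpha W' F + (1 - alpha) Y from F_0 = Y until the max-abs
    update falls below ``tol``.  The limit solves
    (I - alpha W') F = (1 - alpha) Y, so F is nonnegative, bounded below by
    (1 - alpha) Y elementwise, and reduces to Y as alpha -> 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    Y = prior.to_numpy(dtype=float)
    if (Y < 0).any():
        raise ValueError("prior must be nonnegative")
    if W_norm.shape[0] != len(Y):
        raise ValueError("prior length must match network size")
    F = Y.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        F_new = alpha * (W_norm @ F) + (1.0 - alpha) * Y
        residual = float(np.abs(F_new - F).max(initial=0.0))
        F = F_new
        if residual < tol:
            return CorrelationScores(
                scores=pd.Series(F, index=prior.index, name="F"),
                alpha=alpha, iterations=it, residual=residual)
    raise ConvergenceError(
        f"propagation did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})", residual=residual, iterations=max_iter)


def alpha_sensitivity(
    W_norm: np.ndarray,
    prior: pd.Series,
    alphas: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9),
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Per-gene propagated scores across a grid of restart parameters."""
    cols = {f"alpha={a}": propagate(W_norm, prior, a, tol, max_iter).scores
            for a in alphas}
    return pd.DataFrame(cols)


def logistic_prior_transform(prior: pd.Series, c: float = -15.0,
                             d: float = np.log(9999.0)) -> pd.Series:
    """Optional logistic squashing of the raw prior before propagation.

    Maps y to 1 / (1 + exp(c*y + d)); with the defaults, y = 0 maps to about
    1e-4 and y = 1 close to 1.  Off by default: the pipeline propagates the
    literal max-product prior.
    """
    y = prior.to_numpy(dtype=float)
    return pd.Series(1.0 / (1.0 + np.exp(c * y + d)), index=prior.index,
                     name=prior.name)
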