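"""Connectivity matrices and tangent-space embedding.

A subject's functional connectivity is summarized as a symmetric positive
definite (SPD) matrix. Group statistics on edges are taken not on the raw
correlations but in the tangent plane of the SPD manifold at the reference
cohort's geometric (Frechet) mean G under the affine-invariant metric:

    T_s = logm( G^{-1/2} C_s G^{-1/2} )

which whitens each subject by the cohort reference before the matrix
logarithm. The matrix logarithm needs strictly positive definite input, so
sample covariances are shrunk toward a scaled identity first.
"""

from __future__ import annotations

import numpy as np

from .preprocess import TimeSeriesMatrix


class ConnectivityError(ValueError):
    pass


def _check_symmetric(m, tol=1e-10, name="matrix"):
    m = np.asarray(m, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectivityError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=tol * max(1.0, np.abs(m).max())):
        raise ConnectivityError(f"{name} not symmetric")
    return 0.5 * (m + m.T)


def correlation_matrix(ts: TimeSeriesMatrix) -> np.ndarray:
    """Pearson correlation over retained frames (P x P, diagonal 1).

    A P-parcel matrix carries P^2 entries, of which P(P-1)/2 are unique
    unordered off-diagonal pairs.
    """
    if ts.n_retained < 3:
        raise ConnectivityError("need at least 3 retained frames")
    data = ts.retained()
    sd = data.std(axis=1, ddof=1)
    # near-zero variance (constant up to rounding) is as degenerate
    tol = 1e-10 * max(1.0, float(np.abs(data).max()))
    if (sd <= tol).any():
        bad = [ts.parcel_ids[i] for i in np.flatnonzero(sd <= tol)]
        raise ConnectivityError(f"zero-variance parcel(s): {bad}")
    c = np.atleast_2d(np.corrcoef(data))
    np.fill_diagonal(c, 1.0)
    return 0.5 * (c + c.T)


def covariance_matrix(ts: TimeSeriesMatrix) -> np.ndarray:
    """Sample covariance over retained frames (ddof=1)."""
    if ts.n_retained < 3:
        raise ConnectivityError("need at least 3 retained frames")
    c = np.atleast_2d(np.cov(ts.retained(), ddof=1))
    return 0.5 * (c + c.T)


def regularize(cov: np.ndarray, shrinkage: float = 0.1) -> np.ndarray:
    """Shrink toward the scaled identity: (1-s) C + s (tr C / P) I.

    Preserves the trace and certifies strict positive definiteness for
    s > 0 whenever C is positive semidefinite.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ConnectivityError("shrinkage must be in [0, 1]")
    c = _check_symmetric(cov, name="covariance")
    p = c.shape[0]
    mu = np.trace(c) / p
    return (1.0 - shrinkage) * c + shrinkage * mu * np.eye(p)


def _eigh_checked(m, name="matrix"):
    w, v = np.linalg.eigh(m)
    if w[0] <= 0:
        raise ConnectivityError(
            f"{name} not positive definite (min eigenvalue {w[0]:.3e}); "
            "apply regularize() first")
    return w, v


def _spd_power(m, power, name="matrix"):
    w, v = _eigh_checked(m, name)
    return (v * w ** power) @ v.T


def _spd_logm(m, name="matrix"):
    w, v = _eigh_checked(m, name)
    return (v * np.log(w)) @ v.T


def _spd_expm(m):
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    return (v * np.exp(w)) @ v.T


def tangent_embed(c: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Embed SPD matrix *c* in the tangent plane at *mean*.

    Returns ``logm(mean^{-1/2} c mean^{-1/2})`` computed by symmetric
    eigendecomposition; symmetric output, zero matrix when c == mean.
    """
    c = _check_symmetric(c, name="connectivity")
    mean = _check_symmetric(mean, name="reference mean")
    if c.shape != mean.shape:
        raise ConnectivityError("shape mismatch between matrix and mean")
    whitener = _spd_power(mean, -0.5, name="reference mean")
    inner = whitener @ c @ whitener
    t = _spd_logm(0.5 * (inner + inner.T), name="whitened connectivity")
    return 0.5 * (t + t.T)


def tangent_inverse(t: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Map a tangent matrix back to the SPD manifold at *mean*."""
    half = _spd_power(mean, 0.5, name="reference mean")
    return half @ _spd_expm(t) @ half


def frechet_mean(covs, tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Affine-invariant Frechet (geometric) mean of SPD matrices.

    Fixed-point iteration started at the arithmetic mean:

        G <- G^{1/2} expm( mean_s logm(G^{-1/2} C_s G^{-1/2}) ) G^{1/2}

    stopping when the Frobenius norm of the mean log term drops below
    *tol*. For commuting inputs this reduces to the elementwise geometric
    mean of the eigenvalues.
    """
    covs = [np.asarray(c, float) for c in covs]
    if not covs:
        raise ConnectivityError("need at least one matrix")
    shape = covs[0].shape
    for c in covs:
        if c.shape != shape:
            raise ConnectivityError("all matrices must share a shape")
        _eigh_checked(_check_symmetric(c), name="input")
    g = np.mean(covs, axis=0)
    residual = np.inf
    for _ in range(max_iter):
        g_half = _spd_power(g, 0.5, name="mean iterate")
        g_ihalf = _spd_power(g, -0.5, name="mean iterate")
        logs = np.mean(
            [_spd_logm(g_ihalf @ c @ g_ihalf, name="whitened input")
             for c in covs], axis=0)
        residual = np.linalg.norm(logs, "fro")
        if residual < tol:
            return 0.5 * (g + g.T)
        g = g_half @ _spd_expm(logs) @ g_half
        g = 0.5 * (g + g.T)
    raise ConnectivityError(
        f"Frechet mean did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})")


def subject_connectivity(ts: TimeSeriesMatrix,
                         shrinkage: float = 0.1) -> np.ndarray:
    """Regularized covariance for one preprocessed subject.

    After per-parcel variance normalization the sample covariance is a
    correlation matrix; shrinkage then guarantees strict positive
    definiteness for the tangent map even when frames < parcels.
    """
    return regularize(covariance_matrix(ts), shrinkage)


# -- IO -------------------------------------------------------------------

def matrix_to_tsv(m: np.ndarray, path, parcel_ids=None) -> None:
    import pandas as pd
    m = np.asarray(m, float)
    if parcel_ids is None:
        parcel_ids = list(range(m.shape[0]))
    df = pd.DataFrame(m, columns=[str(p) for p in parcel_ids])
    df.insert(0, "parcel_id", parcel_ids)
    df.to_csv(path, sep="\t", index=False)


def matrix_from_tsv(path):
    import pandas as pd
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    parcel_ids = list(df["parcel_id"])
    return df.drop(columns=["parcel_id"]).to_numpy(float), parcel_ids
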