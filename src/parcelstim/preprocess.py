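"""Parcel-level BOLD time-series cleaning.

Operates strictly at parcel resolution (inputs are parcels x timepoints
matrices): frame scrubbing by DVARS, polynomial detrending, and confound
regression with a component-based (CompCor-style) noise model built from
the highest-variance parcels. Voxel/image-level steps (motion realignment,
skull stripping, slice timing, spatial smoothing) are out of scope.

Pipeline order is fixed: scrub -> detrend -> confound regression ->
per-parcel variance normalization. Global signal regression is deliberately
not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


@dataclass
class TimeSeriesMatrix:
    """Parcels x timepoints signal with a per-frame retention mask.

    ``values[p, t]`` is the signal of parcel ``p`` at frame ``t``;
    ``frame_mask[t]`` is True where the frame is retained. Scrubbed frames
    keep their values (for audit) but are ignored by every downstream
    computation.
    """

    values: np.ndarray
    frame_mask: np.ndarray = None
    parcel_ids: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessError("values must be 2-D (parcels x timepoints)")
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.values.shape[1], dtype=bool)
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
        if self.frame_mask.shape != (self.values.shape[1],):
            raise PreprocessError("frame_mask length must equal n_timepoints")
        if self.parcel_ids is None:
            self.parcel_ids = list(range(self.values.shape[0]))
        if len(self.parcel_ids) != self.values.shape[0]:
            raise PreprocessError("parcel_ids length must equal n_parcels")
        if np.isnan(self.values[:, self.frame_mask]).any():
            raise PreprocessError("NaN in retained frames")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def retained(self) -> np.ndarray:
        """Values restricted to retained frames (parcels x n_retained)."""
        return self.values[:, self.frame_mask]

    def rank_sufficient(self) -> bool:
        """Whether enough frames remain for a full-rank covariance."""
        return self.n_retained >= self.n_parcels + 2

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path, mask_path=None) -> None:
        """Write as TSV: first column parcel_id, remaining columns frames
        (header = frame index). Mask optionally as single-column TSV."""
        df = pd.DataFrame(self.values,
                          columns=[str(t) for t in range(self.n_timepoints)])
        df.insert(0, "parcel_id", self.parcel_ids)
        df.to_csv(path, sep="\t", index=False)
        if mask_path is not None:
            pd.DataFrame({"retained": self.frame_mask.astype(int)}).to_csv(
                mask_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, mask_path=None) -> "TimeSeriesMatrix":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        parcel_ids = list(df["parcel_id"])
        values = df.drop(columns=["parcel_id"]).to_numpy(float)
        mask = None
        if mask_path is not None:
            mask = pd.read_csv(mask_path, sep="\t", float_precision="round_trip")["retained"].to_numpy(bool)
        return cls(values=values, frame_mask=mask, parcel_ids=parcel_ids)


@dataclass
class ConfoundSet:
    """Nuisance regressors aligned with retained frames (rows) by column."""

    regressors: np.ndarray  # n_retained x k

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, float))
        if self.regressors.size == 0:
            self.regressors = self.regressors.reshape(0, 0)

    @property
    def k(self) -> int:
        return 0 if self.regressors.size == 0 else self.regressors.shape[1]


def compute_dvars(ts: TimeSeriesMatrix) -> np.ndarray:
    """Frame-to-frame RMS signal change over parcels.

    ``dvars[t] = sqrt(mean_p (x[p,t] - x[p,t-1])^2)`` for t >= 1;
    ``dvars[0] = 0`` by convention (no preceding frame).
    """
    if ts.n_timepoints < 2:
        raise PreprocessError("DVARS needs at least 2 timepoints")
    diffs = np.diff(ts.values, axis=1)
    dvars = np.sqrt(np.mean(diffs ** 2, axis=0))
    return np.concatenate([[0.0], dvars])


def scrub_frames(ts: TimeSeriesMatrix, dvars: np.ndarray,
                 n_sigma: float = 2.0) -> TimeSeriesMatrix:
    """Mask frames whose DVARS exceeds mean + n_sigma * SD.

    The threshold is one-sided (motion only inflates DVARS) and computed
    once from frames 1..T-1 of the original series — dvars[0] is a
    placeholder, not a measurement. The returned mask is the conjunction
    with any pre-existing mask.
    """
    dvars = np.asarray(dvars, float)
    if dvars.shape != (ts.n_timepoints,):
        raise PreprocessError("dvars not aligned with time series")
    d = dvars[1:]
    thresh = d.mean() + n_sigma * d.std(ddof=0)
    bad = dvars > thresh
    bad[0] = False
    mask = ts.frame_mask & ~bad
    if not mask.any():
        raise PreprocessError(
            f"all frames scrubbed (threshold {thresh:.4g}); "
            "inspect DVARS or relax n_sigma")
    out = TimeSeriesMatrix(ts.values.copy(), mask, list(ts.parcel_ids),
                           dict(ts.meta))
    out.meta["dvars_threshold"] = float(thresh)
    out.meta["n_scrubbed"] = int(bad.sum())
    if not out.rank_sufficient():
        warnings.warn(
            f"only {out.n_retained} retained frames for {out.n_parcels} "
            "parcels: covariance is rank-deficient, regularization mandatory",
            stacklevel=2)
    return out


def _trend_basis(frame_idx: np.ndarray, order: int = 2) -> np.ndarray:
    """Orthonormalized polynomial basis (intercept..order) in frame index."""
    t = (frame_idx - frame_idx.mean())
    scale = np.abs(t).max() or 1.0
    t = t / scale
    cols = [t ** d for d in range(order + 1)]
    basis = np.column_stack(cols)
    q, _ = np.linalg.qr(basis)
    return q


def detrend(ts: TimeSeriesMatrix, order: int = 2) -> TimeSeriesMatrix:
    """Remove per-parcel intercept + linear + quadratic trends.

    The fit uses the retained frames' original indices, so scrubbing does
    not warp the time axis. Scrubbed frames have the fitted trend removed
    too (audit only).
    """
    if ts.n_retained < order + 2:
        raise PreprocessError("too few retained frames to detrend")
    idx = np.flatnonzero(ts.frame_mask)
    basis_all = _trend_basis(np.arange(ts.n_timepoints, dtype=float), order)
    basis = basis_all[idx]
    coefs, *_ = np.linalg.lstsq(basis, ts.retained().T, rcond=None)
    fitted = basis_all @ coefs
    out = TimeSeriesMatrix(ts.values - fitted.T, ts.frame_mask.copy(),
                           list(ts.parcel_ids), dict(ts.meta))
    return out


def compcor_confounds(ts: TimeSeriesMatrix, n_components: int = 5,
                      pool_fraction: float = 0.1) -> ConfoundSet:
    """Component-based confounds from the noisiest parcels.

    Parcel-level surrogate for voxelwise CompCor: the noise pool is the
    top ``pool_fraction`` of parcels by retained-frame variance; the
    confounds are the first ``n_components`` principal components of their
    standardized series.
    """
    data = ts.retained()
    var = data.var(axis=1, ddof=1)
    # pool must strictly exceed the component count, else regression
    # annihilates the pool parcels themselves
    n_pool = max(int(np.ceil(pool_fraction * ts.n_parcels)),
                 min(n_components + 1, ts.n_parcels))
    pool = np.argsort(var)[::-1][:n_pool]
    x = data[pool].T  # frames x pool
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd
    n_comp = min(n_components, n_pool - 1, x.shape[0])
    if n_comp < 1:
        return ConfoundSet(np.empty((0, 0)))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    comps = u[:, :n_comp] * s[:n_comp]
    return ConfoundSet(comps)


def regress_confounds(ts: TimeSeriesMatrix,
                      confounds: ConfoundSet) -> TimeSeriesMatrix:
    """Residualize retained frames against the confounds (plus intercept).

    Collinear confound columns are dropped with a warning. With k = 0 the
    input is returned unchanged (no intercept removal).
    """
    if confounds.k == 0:
        return ts
    x = confounds.regressors
    if x.shape[0] != ts.n_retained:
        raise PreprocessError("confound rows must align with retained frames")
    if x.shape[1] >= ts.n_retained:
        raise PreprocessError("more confounds than retained frames")
    design = np.column_stack([np.ones(x.shape[0]), x])
    # drop collinear columns via pivoted rank check
    q, r, piv = _pivoted_qr(design)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])))
    if rank < design.shape[1]:
        warnings.warn(
            f"confound matrix rank-deficient; dropping "
            f"{design.shape[1] - rank} collinear column(s)", stacklevel=2)
        design = design[:, np.sort(piv[:rank])]
    data = ts.retained().T  # frames x parcels
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    resid = data - design @ beta
    values = ts.values.copy()
    values[:, ts.frame_mask] = resid.T
    return TimeSeriesMatrix(values, ts.frame_mask.copy(),
                            list(ts.parcel_ids), dict(ts.meta))


def _pivoted_qr(a):
    from scipy.linalg import qr
    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def normalize_variance(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Scale each parcel to unit variance over retained frames."""
    data = ts.retained()
    sd = data.std(axis=1, ddof=1)
    tol = 1e-10 * max(1.0, float(np.abs(data).max()))
    if (sd <= tol).any():
        bad = [ts.parcel_ids[i] for i in np.flatnonzero(sd <= tol)]
        raise PreprocessError(f"zero-variance parcel(s): {bad}")
    values = ts.values / sd[:, None]
    return TimeSeriesMatrix(values, ts.frame_mask.copy(),
                            list(ts.parcel_ids), dict(ts.meta))


def preprocess(ts: TimeSeriesMatrix, dvars_sigma: float = 2.0,
               compcor_components: int = 5, detrend_order: int = 2,
               normalize: bool = True) -> TimeSeriesMatrix:
    """Full parcel-level cleaning in the fixed order:

    1. DVARS scrubbing (mask computed once from the raw series),
    2. polynomial detrending (intercept + linear + quadratic),
    3. CompCor-style confound regression,
    4. per-parcel variance normalization.
    """
    dvars = compute_dvars(ts)
    out = scrub_frames(ts, dvars, n_sigma=dvars_sigma)
    out = detrend(out, order=detrend_order)
    if compcor_components > 0:
        conf = compcor_confounds(out, n_components=compcor_components)
        out = regress_confounds(out, conf)
    if normalize:
        out = normalize_variance(out)
    out.meta["preprocessed"] = True
    return out
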