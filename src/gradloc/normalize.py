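"""Batch-effect removal and variance-stabilizing normalization of reporter-ion signals.

Two preprocessing steps precede fold-change computation:

1. ``remove_batch_effect`` fits, per protein, one additive offset per batch on
   the log2 scale (each biological replicate is one batch) and equalizes the
   per-batch means to the protein's grand mean — the contract of limma-style
   additive batch correction for a one-factor design.

2. ``fit_vsn`` / ``apply_normalization`` calibrate each sample (a replicate x
   channel column) with an affine map followed by a generalized log2
   transform, h_c(x) = glog2((x - o_c) / s_c) + d_c, fitted by alternating
   trimmed least squares against a consensus reference profile. The transform
   is strictly increasing per channel, aligns channel medians on the
   transformed scale, and behaves like log2(x) + const for signals far above
   the glog cofactor. This re-implements the *contract* of variance
   stabilizing normalization, not any particular package's code path.

A simpler per-channel median-scaling + log2 alternative is available for
diagnostics via :func:`median_log2_normalize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, ValidationError
from .io_formats import CHANNELS, SignalMatrix

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)


def glog2(y):
    """Generalized log2: asinh(y)/ln 2 = log2(y + sqrt(y^2 + 1))."""
    return np.arcsinh(y) / _LN2


@dataclass
class NormalizationModel:
    """Per-sample affine + glog2 calibration.

    ``samples`` are ``"replicate:channel"`` keys; ``scale`` (> 0) is the glog
    cofactor/slope, ``offset`` the background term, and ``shift`` a final
    additive alignment on the glog2 scale that makes sample medians agree on
    the training data.
    """

    samples: list[str]
    scale: pd.Series
    offset: pd.Series
    shift: pd.Series
    n_iter: int
    converged: bool
    trim: float

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            raise ValidationError("normalization scales must be strictly positive")

    def transform_column(self, x: np.ndarray, sample: str) -> np.ndarray:
        s = self.scale[sample]
        o = self.offset[sample]
        d = self.shift[sample]
        return glog2((x - o) / s) + d


def _sample_key(replicate_id: str, channel: str) -> str:
    return f"{replicate_id}:{channel}"


def _stack(matrices: Sequence[SignalMatrix]) -> pd.DataFrame:
    cols = {}
    index = matrices[0].protein_ids
    for m in matrices:
        if not m.protein_ids.equals(index):
            raise ValidationError("matrices must share an identical protein set and order")
        for ch in CHANNELS:
            cols[_sample_key(m.replicate_id, ch)] = m.values[ch].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=index)


def remove_batch_effect(
    matrices: Sequence[SignalMatrix],
    batch_labels: Sequence[str] | None = None,
) -> list[SignalMatrix]:
    """Equalize per-protein batch means on the log2 scale.

    Each input matrix is one batch (default: its replicate id is the batch
    label). For every protein, the mean log2 signal of each batch is shifted
    to the protein's grand mean (the unweighted mean of batch means), then
    values are exponentiated back to the signal scale. Proteins with no
    observed value in a batch are left unchanged there.
    """
    if batch_labels is None:
        batch_labels = [m.replicate_id for m in matrices]
    if len(matrices) < 2 or len(set(batch_labels)) < 2:
        log.warning("remove_batch_effect: fewer than two batches; returning input unchanged")
        return [m.copy() for m in matrices]
    index = matrices[0].protein_ids
    logs = []
    for m in matrices:
        if not m.protein_ids.equals(index):
            raise ValidationError("batches must share an identical protein set and order")
        if m.scale != "raw":
            raise ValidationError("remove_batch_effect expects raw-scale signals")
        logs.append(np.log2(m.values.to_numpy(dtype=float)))
    batch_means = [np.nanmean(L, axis=1) for L in logs]  # per protein
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(np.column_stack(batch_means), axis=1)
    out = []
    for m, L, bm in zip(matrices, logs, batch_means):
        offset = bm - grand  # NaN where batch all-missing -> leave unchanged
        n_all_missing = int(np.isnan(bm).sum())
        if n_all_missing:
            log.warning(
                "batch %s: %d protein(s) with no observed channel left uncorrected",
                m.replicate_id, n_all_missing,
            )
        offset = np.where(np.isnan(offset), 0.0, offset)
        corrected = np.power(2.0, L - offset[:, None])
        out.append(
            SignalMatrix(
                replicate_id=m.replicate_id,
                values=pd.DataFrame(corrected, index=index, columns=list(CHANNELS)),
                unique_peptides=m.unique_peptides,
                scale="raw",
            )
        )
    return out


def _trimmed_affine_fit(
    x: np.ndarray, r: np.ndarray, trim: float, fixed_mask: np.ndarray | None = None
) -> tuple[float, float, np.ndarray]:
    """Fit x ~ s*r + o by relative-error weighted least squares with trimming.

    Reporter-ion noise is predominantly multiplicative, so residuals are
    weighted by 1/r^2 (relative error); an unweighted fit would be dominated
    by the brightest proteins and push the intercept to the scale of the
    median signal, distorting low-intensity values under the glog. For data
    that are exactly affine in the reference the fit is exact either way.
    """
    obs = np.isfinite(x) & np.isfinite(r)
    if obs.sum() < 3:
        raise ValidationError("too few observed values to calibrate a channel")
    floor = max(np.nanmedian(np.abs(r[obs])) * 1e-3, 1e-12)
    w_all = 1.0 / np.maximum(np.abs(r), floor) ** 2
    mask = obs if fixed_mask is None else (obs & fixed_mask)
    s, o = 1.0, 0.0
    for _ in range(10):
        xr, rr, w = x[mask], r[mask], w_all[mask]
        wsum = w.sum()
        rbar = float((w * rr).sum() / wsum)
        xbar = float((w * xr).sum() / wsum)
        var = float((w * (rr - rbar) ** 2).sum() / wsum)
        if var <= 0:
            s, o = 1.0, xbar - rbar
        else:
            s = float((w * (rr - rbar) * (xr - xbar)).sum() / wsum / var)
            o = xbar - s * rbar
        if s <= 0:  # degenerate anticorrelation; keep monotone contract
            s = 1e-12
            o = xbar - s * rbar
        if fixed_mask is not None or trim <= 0:
            return s, o, mask
        resid = np.abs(x - (s * r + o)) * np.sqrt(w_all)
        resid[~obs] = np.inf
        n_keep = max(3, int(np.ceil(obs.sum() * (1.0 - trim))))
        keep_idx = np.argpartition(resid, n_keep - 1)[:n_keep]
        new_mask = np.zeros_like(obs)
        new_mask[keep_idx] = True
        new_mask &= obs
        if (new_mask == mask).all():
            return s, o, mask
        mask = new_mask
    return s, o, mask


def fit_vsn(
    matrices: Sequence[SignalMatrix],
    trim: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-8,
    freeze_after: int = 25,
) -> NormalizationModel:
    """Fit the affine + glog2 calibration jointly across all samples.

    Alternates between (a) a consensus reference profile — the per-protein
    mean of calibrated raw values across samples — and (b) per-sample trimmed
    least-squares fits of the raw column against that reference. Trim masks
    are frozen after ``freeze_after`` iterations so the alternation converges
    to machine precision. A final per-sample additive shift aligns medians on
    the glog2 scale.
    """
    if not 0 <= trim < 0.5:
        raise ConfigurationError("trim fraction must be in [0, 0.5)")
    X = _stack(matrices)
    if len(X) < 20:
        log.warning("fit_vsn: only %d proteins; calibration may be unstable", len(X))
    arr = X.to_numpy(dtype=float)
    n_obs = np.isfinite(arr).sum(axis=0)
    if (n_obs == 0).any():
        empty = [c for c, n in zip(X.columns, n_obs) if n == 0]
        raise ValidationError(f"channel(s) entirely missing: {empty}")

    samples = list(X.columns)
    n_samples = len(samples)
    scale = np.ones(n_samples)
    offset = np.zeros(n_samples)
    # initial reference: plain per-protein mean of raw values
    ref = np.nanmean(arr, axis=1)
    masks: list[np.ndarray | None] = [None] * n_samples
    delta = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = np.concatenate([scale, offset])
        frozen = it > freeze_after
        for j in range(n_samples):
            s, o, m = _trimmed_affine_fit(
                arr[:, j], ref, trim, fixed_mask=masks[j] if frozen else None
            )
            scale[j], offset[j] = s, o
            if not frozen:
                masks[j] = m
        # gauge fix: the model (s_j, o_j, ref) is invariant under a global
        # affine reparameterization; pin mean(s)=1, mean(o)=0 so the
        # iteration's flat directions cannot drift and block convergence
        b = 1.0 / scale.mean()
        a = -offset.mean() / scale.mean()
        scale *= b
        offset += scale / b * a
        calibrated = (arr - offset[None, :]) / scale[None, :]
        ref = np.nanmean(calibrated, axis=1)
        cur = np.concatenate([scale, offset])
        norm = np.maximum(np.abs(prev), 1.0)
        delta = float(np.max(np.abs(cur - prev) / norm))
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"vsn calibration did not converge after {max_iter} iterations "
            f"(last relative change {delta:.3e})"
        )
    z = glog2((arr - offset[None, :]) / scale[None, :])
    med = np.nanmedian(z, axis=0)
    grand_med = float(np.nanmedian(med))
    shift = grand_med - med
    return NormalizationModel(
        samples=samples,
        scale=pd.Series(scale, index=samples),
        offset=pd.Series(offset, index=samples),
        shift=pd.Series(shift, index=samples),
        n_iter=it,
        converged=True,
        trim=trim,
    )


def apply_normalization(m: SignalMatrix, model: NormalizationModel) -> SignalMatrix:
    """Transform a raw matrix onto the glog2 scale; missing cells stay missing."""
    keys = [_sample_key(m.replicate_id, ch) for ch in CHANNELS]
    missing = [k for k in keys if k not in model.samples]
    if missing:
        raise ValidationError(f"normalization model lacks sample(s) {missing}")
    out = {}
    for ch, key in zip(CHANNELS, keys):
        out[ch] = model.transform_column(m.values[ch].to_numpy(dtype=float), key)
    values = pd.DataFrame(out, index=m.protein_ids, columns=list(CHANNELS))
    return SignalMatrix(
        replicate_id=m.replicate_id,
        values=values,
        unique_peptides=m.unique_peptides,
        scale="glog2",
    )


def median_log2_normalize(matrices: Sequence[SignalMatrix]) -> list[SignalMatrix]:
    """Diagnostic alternative: per-sample median scaling followed by log2.

    Every sample column is divided by its median (aligning medians to the
    joint grand median) and log2-transformed.
    """
    X = _stack(matrices)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log2(X.to_numpy(dtype=float))
    L[~np.isfinite(L)] = np.nan
    med = np.nanmedian(L, axis=0)
    grand = float(np.nanmedian(med))
    out = []
    for m in matrices:
        cols = {}
        for ch in CHANNELS:
            key = _sample_key(m.replicate_id, ch)
            j = list(X.columns).index(key)
            cols[ch] = L[:, j] - med[j] + grand
        values = pd.DataFrame(cols, index=m.protein_ids, columns=list(CHANNELS))
        out.append(
            SignalMatrix(
                replicate_id=m.replicate_id,
                values=values,
                unique_peptides=m.unique_peptides,
                scale="log2",
            )
        )
    return out
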