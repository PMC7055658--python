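"""Fractionation profiles and the sucrose gradient ratio statistic.

A protein's fractionation profile is its log2 fold change in each gradient
fraction (f02..f11) relative to the unfractionated total-membrane channel.
The sucrose gradient ratio condenses the profile into one number:

    ratio = mean(logFC f08, f09, f10) - mean(logFC f02, f03, f04)

i.e. high-density minus low-density enrichment. OM vesicles are denser than
IM vesicles on a sucrose gradient, so positive ratios indicate OM-like and
negative ratios IM-like behaviour; soluble contaminants sit near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .io_formats import (
    FRACTIONS,
    HIGH_DENSITY_FRACTIONS,
    LOW_DENSITY_FRACTIONS,
    TOTAL_CHANNEL,
    SignalMatrix,
)

log = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Per-protein log2 fold-change vectors over the ten quantified fractions.

    ``replicate_id`` is a replicate identifier or ``"averaged"``. ``fallback``
    (only on averaged sets) flags proteins whose average used a single
    replicate for at least one fraction because the other was missing.
    """

    replicate_id: str
    logfc: pd.DataFrame
    fallback: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.logfc.columns) != list(FRACTIONS):
            raise ValidationError(
                f"profile set must have exactly the fraction columns {list(FRACTIONS)}"
            )
        if np.isinf(self.logfc.to_numpy(dtype=float)).any():
            raise ValidationError("log fold changes must be finite or missing")

    @property
    def protein_ids(self) -> pd.Index:
        return self.logfc.index

    def complete(self) -> pd.DataFrame:
        """Rows with no missing fraction (the clustering input)."""
        return self.logfc.dropna()


def compute_logfc(m: SignalMatrix) -> ProfileSet:
    """Log2 fold change of each fraction versus the total-membrane channel.

    On a log-like scale (glog2/log2) the fold change is a subtraction; on the
    raw scale it is log2(fraction / total). A protein with a missing total
    signal has its whole profile flagged missing.
    """
    total = m.values[TOTAL_CHANNEL].to_numpy(dtype=float)
    fracs = m.values[list(FRACTIONS)].to_numpy(dtype=float)
    if m.scale in ("glog2", "log2"):
        logfc = fracs - total[:, None]
    elif m.scale == "raw":
        with np.errstate(divide="ignore", invalid="ignore"):
            logfc = np.log2(fracs) - np.log2(total)[:, None]
        logfc[~np.isfinite(logfc)] = np.nan
    else:
        raise ConfigurationError(f"unknown signal scale {m.scale!r}")
    logfc[~np.isfinite(total)[:, None] & np.ones_like(logfc, dtype=bool)] = np.nan
    n_no_total = int((~np.isfinite(total)).sum())
    if n_no_total:
        log.warning(
            "replicate %s: %d protein(s) without a total-membrane signal", m.replicate_id, n_no_total
        )
    return ProfileSet(
        replicate_id=m.replicate_id,
        logfc=pd.DataFrame(logfc, index=m.protein_ids, columns=list(FRACTIONS)),
    )


def average_replicates(a: ProfileSet, b: ProfileSet) -> ProfileSet:
    """Element-wise mean of two replicate profiles.

    A value observed in only one replicate is carried over from that replicate
    and the protein is flagged in ``fallback``; a value missing in both stays
    missing.
    """
    if not a.protein_ids.equals(b.protein_ids):
        raise ValidationError("profile sets must cover the same proteins in the same order")
    A = a.logfc.to_numpy(dtype=float)
    B = b.logfc.to_numpy(dtype=float)
    stacked = np.stack([A, B])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        mean = np.nanmean(stacked, axis=0)
    single_source = np.isnan(A) ^ np.isnan(B)
    fallback = pd.Series(single_source.any(axis=1), index=a.protein_ids, name="fallback")
    return ProfileSet(
        replicate_id="averaged",
        logfc=pd.DataFrame(mean, index=a.protein_ids, columns=list(FRACTIONS)),
        fallback=fallback,
    )


def compute_sucrose_ratio(p: ProfileSet, mode: str = "mean_of_logs") -> pd.Series:
    """Per-protein sucrose gradient ratio.

    ``mean_of_logs`` (default): mean logFC of f08-f10 minus mean logFC of
    f02-f04. ``log_of_sums``: log2 of the summed linear-scale fold changes of
    the high-density triplet minus the same for the low-density triplet. The
    ratio is missing unless all six contributing fractions are observed.
    """
    high = p.logfc[list(HIGH_DENSITY_FRACTIONS)].to_numpy(dtype=float)
    low = p.logfc[list(LOW_DENSITY_FRACTIONS)].to_numpy(dtype=float)
    complete = np.isfinite(high).all(axis=1) & np.isfinite(low).all(axis=1)
    if mode == "mean_of_logs":
        ratio = high.mean(axis=1) - low.mean(axis=1)
    elif mode == "log_of_sums":
        ratio = np.log2(np.power(2.0, high).sum(axis=1)) - np.log2(np.power(2.0, low).sum(axis=1))
    else:
        raise ConfigurationError("ratio_mode must be 'mean_of_logs' or 'log_of_sums'")
    ratio = np.where(complete, ratio, np.nan)
    return pd.Series(ratio, index=p.protein_ids, name="sucrose_ratio")


def replicate_correlation(a: ProfileSet, b: ProfileSet) -> tuple[float, int]:
    """Pearson correlation of all paired finite logFC values (10 per protein)."""
    shared = a.protein_ids.intersection(b.protein_ids)
    x = a.logfc.loc[shared].to_numpy(dtype=float).ravel()
    y = b.logfc.loc[shared].to_numpy(dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValidationError(f"need at least 3 paired values for a correlation (got {n})")
    r, _ = stats.pearsonr(x[ok], y[ok])
    return float(r), n
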