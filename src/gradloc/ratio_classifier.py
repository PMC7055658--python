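"""Percentile-calibrated classification of sucrose gradient ratios.

Cutoffs are calibrated on the data themselves using annotation-benchmarked
proteins: the IM cutoff is the 90th percentile of the ratio distribution of
benchmark IM proteins, the OM cutoff the 10th percentile of benchmark OM
proteins. Proteins at or below the IM cutoff are called IM, at or above the
OM cutoff OM, and strictly between the two soluble. Peripheral-IM ("IM-cyto")
proteins have a bimodal ratio distribution and are excluded from calibration;
the pipeline resolves them afterwards from their consensus calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .io_formats import AnnotationTable

log = logging.getLogger(__name__)

#: Categories entering each calibration group.
CALIBRATION_CATEGORIES = {
    "IM": ("IM-integral", "IM-peri"),
    "OM": ("OMP", "OMLP"),
    "soluble": ("cytoplasmic", "periplasmic"),
}


@dataclass
class RatioCutoffs:
    """Calibrated sucrose-ratio thresholds and the benchmark sizes behind them."""

    im_upper: float
    om_lower: float
    n_im: int
    n_om: int
    n_soluble: int
    percentile_convention: str = "linear interpolation between order statistics"

    def __post_init__(self) -> None:
        if not self.im_upper < self.om_lower:
            raise CalibrationError(
                f"IM cutoff ({self.im_upper:.4g}) must lie below the OM cutoff "
                f"({self.om_lower:.4g}); the benchmark distributions do not separate"
            )


def build_benchmark_groups(
    ann: AnnotationTable,
    detected,
    include_imlp: bool = False,
) -> dict[str, set]:
    """Benchmark protein sets (IM / OM / soluble) restricted to detected proteins.

    IM-cyto and "other" categories are never used for benchmarking. IM
    lipoproteins join the IM calibration set only when ``include_imlp`` is set
    (the default follows the IM-integral + IM-peri grouping).
    """
    detected = set(detected)
    cats = {g: set(v) for g, v in CALIBRATION_CATEGORIES.items()}
    if include_imlp:
        cats["IM"].add("IMLP")
    groups: dict[str, set] = {}
    for group, categories in cats.items():
        members = {
            pid
            for pid, cat in ann.categories.items()
            if cat in categories and pid in detected
        }
        if not members:
            raise CalibrationError(f"benchmark group {group!r} has no detected proteins")
        groups[group] = members
    return groups


def derive_cutoffs(ratios: pd.Series, groups: dict[str, set]) -> RatioCutoffs:
    """90th percentile of benchmark IM ratios / 10th percentile of benchmark OM ratios.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default, R's type 7).
    """
    vals = {}
    for group in ("IM", "OM", "soluble"):
        r = ratios.reindex(list(groups[group])).dropna()
        if len(r) == 0:
            raise CalibrationError(f"no finite ratios in benchmark group {group!r}")
        if len(r) < 10:
            log.warning("benchmark group %s has only %d finite ratios", group, len(r))
        vals[group] = r.to_numpy(dtype=float)
    im_upper = float(np.percentile(vals["IM"], 90, method="linear"))
    om_lower = float(np.percentile(vals["OM"], 10, method="linear"))
    return RatioCutoffs(
        im_upper=im_upper,
        om_lower=om_lower,
        n_im=len(vals["IM"]),
        n_om=len(vals["OM"]),
        n_soluble=len(vals["soluble"]),
    )


#: Absolute slack on the inclusive cutoff comparisons so that exact ties
#: (e.g. a noise-free ratio equal to its own calibration percentile) are not
#: broken by floating-point jitter.
BOUNDARY_TOL = 1e-9


def classify_by_ratio(ratios: pd.Series, cutoffs: RatioCutoffs) -> pd.Series:
    """Assign IM / OM / soluble from the calibrated cutoffs.

    Boundary ties go to the membrane class (<= IM cutoff is IM, >= OM cutoff
    is OM, compared with a 1e-9 absolute tolerance); a missing ratio yields
    no call.
    """
    r = ratios.to_numpy(dtype=float)
    call = np.where(
        np.isnan(r),
        None,
        np.where(
            r <= cutoffs.im_upper + BOUNDARY_TOL,
            "IM",
            np.where(r >= cutoffs.om_lower - BOUNDARY_TOL, "OM", "soluble"),
        ),
    )
    return pd.Series(call, index=ratios.index, name="ratio_call", dtype=object)
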