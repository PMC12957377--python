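"""Matrix-level preprocessing for serum abundance blocks.

Implements the standard chain applied to each omics block before modeling:
log2 transform, between-mixture bridging against an artificial mean
reference channel (the abundance-level analog of TMT reference-channel
normalization), missingness filtering with two distinct boundary rules,
zero-mean/unit-variance scaling with parameters retained for held-out
samples, and median imputation for the network stage.

Two missingness rules coexist deliberately: the metabolite rule drops an
analyte only when *more than* the threshold fraction is missing (an analyte
missing in exactly half the samples survives), while the protein rule drops
at *or above* the threshold (the same analyte is removed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Per-block record of what filtering and scaling did."""

    n_before: int
    n_after: int
    dropped: dict[str, float] = field(default_factory=dict)  # analyte -> missing fraction
    scaling: pd.DataFrame | None = None  # per-analyte mean / sd (columns "mean", "sd")

    def to_dict(self) -> dict:
        out = {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "dropped": {k: float(v) for k, v in self.dropped.items()},
        }
        if self.scaling is not None:
            out["scaling"] = {
                "mean": self.scaling["mean"].to_dict(),
                "sd": self.scaling["sd"].to_dict(),
            }
        return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; the missing mask is preserved.

    Raises on nonpositive observed values, naming the offending analyte and
    sample, since a raw abundance of zero or below has no log.
    """
    bad = (matrix <= 0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"nonpositive value for analyte {col!r} in sample {row!r}; "
            "log2 requires positive abundances"
        )
    return np.log2(matrix)


def bridge_mixtures(
    matrix: pd.DataFrame,
    mixture_ids: pd.Series,
    mode: str = "mean_reference",
    reference_samples: dict | None = None,
) -> pd.DataFrame:
    """Remove additive between-mixture shifts using a reference channel.

    In ``mean_reference`` mode the reference for each mixture is the mean
    over that mixture's samples (an artificial reference channel), computed
    per analyte ignoring missing values; in ``designated_reference`` mode it
    is the value of one flagged reference sample per mixture
    (``reference_samples``: mixture id -> sample id). The reference is
    subtracted from every sample in the mixture, so purely additive
    per-mixture shifts cancel exactly.
    """
    if mode not in ("mean_reference", "designated_reference"):
        raise ValueError(f"unknown bridging mode {mode!r}")
    mixture_ids = pd.Series(mixture_ids, index=matrix.index) if not isinstance(mixture_ids, pd.Series) else mixture_ids
    if mixture_ids.isna().any() or not mixture_ids.index.equals(matrix.index):
        raise ValueError("every sample must be assigned to exactly one mixture")
    out = matrix.copy()
    for mix, idx in matrix.groupby(mixture_ids).groups.items():
        sub = matrix.loc[idx]
        if mode == "mean_reference":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                ref = sub.mean(axis=0, skipna=True)
        else:
            if not reference_samples or mix not in reference_samples:
                raise ValueError(f"designated mode requires a reference sample for mixture {mix!r}")
            ref = matrix.loc[reference_samples[mix]]
        all_missing = ref.isna()
        if all_missing.any():
            log.warning(
                "mixture %s: %d analytes with no observed values; left missing",
                mix, int(all_missing.sum()),
            )
            ref = ref.fillna(0.0)  # subtracting 0 leaves the all-NaN entries NaN
        out.loc[idx] = sub - ref
    return out


def filter_missingness(
    matrix: pd.DataFrame, max_missing_frac: float = 0.5, strict: bool = True
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop analytes by missing fraction.

    ``strict=True`` (metabolite rule) drops analytes missing in *more than*
    ``max_missing_frac`` of samples; ``strict=False`` (protein rule) drops
    at *50% or more*, i.e. fraction >= threshold.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = matrix.isna().mean(axis=0)
    drop = frac > max_missing_frac if strict else frac >= max_missing_frac
    report = PreprocessReport(
        n_before=matrix.shape[1],
        n_after=int((~drop).sum()),
        dropped={a: float(frac[a]) for a in matrix.columns[drop]},
    )
    return matrix.loc[:, ~drop], report


def scale_unit_variance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each analyte to mean 0, SD 1 over its non-missing entries.

    Sample SD (n-1 denominator). Returns the scaled matrix and a parameter
    table (columns ``mean``, ``sd``) for applying the same transform to
    held-out samples via :func:`apply_scaling`.
    """
    n_obs = matrix.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = list(matrix.columns[n_obs < 2])
        raise ValueError(f"analytes with fewer than 2 observed values: {bad}")
    mean = matrix.mean(axis=0, skipna=True)
    sd = matrix.std(axis=0, ddof=1, skipna=True)
    zero = sd <= 0
    if zero.any():
        raise ValueError(f"zero-variance analytes cannot be scaled: {list(matrix.columns[zero])}")
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return (matrix - mean) / sd, params


def apply_scaling(matrix: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Apply stored (mean, sd) scaling parameters to new samples."""
    missing = [c for c in matrix.columns if c not in params.index]
    if missing:
        raise ValueError(f"no scaling parameters for analytes: {missing}")
    p = params.loc[matrix.columns]
    return (matrix - p["mean"]) / p["sd"]


def median_impute(
    matrix: pd.DataFrame, medians: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Replace missing entries by the analyte median; observed entries untouched.

    Pass precomputed ``medians`` (e.g. from the training split) to impute a
    held-out matrix consistently; otherwise medians are taken over the
    matrix itself (even counts: mean of the two central order statistics).
    """
    if medians is None:
        if matrix.notna().sum(axis=0).eq(0).any():
            bad = list(matrix.columns[matrix.notna().sum(axis=0) == 0])
            raise ValueError(f"analytes with no observed values cannot be imputed: {bad}")
        medians = matrix.median(axis=0, skipna=True)
    return matrix.fillna(medians), medians


def preprocess_block(
    matrix: pd.DataFrame,
    mixture_ids: pd.Series | None = None,
    already_log2: bool = True,
    missing_rule: str = "strict",
    max_missing_frac: float = 0.5,
    scale: bool = True,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Default chain: log2 -> bridge -> filter -> scale (scaling last)."""
    if missing_rule not in ("strict", "nonstrict"):
        raise ValueError("missing_rule must be 'strict' or 'nonstrict'")
    X = matrix if already_log2 else log2_transform(matrix)
    if mixture_ids is not None:
        X = bridge_mixtures(X, mixture_ids)
    X, report = filter_missingness(X, max_missing_frac, strict=missing_rule == "strict")
    if scale:
        X, params = scale_unit_variance(X)
        report.scaling = params
    return X, report
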