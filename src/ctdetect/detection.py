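"""Detection classifier, sensitivity, tumor-fraction MLE and exact oracle.

A sample is called ctDNA-positive when the number of distinct panel sites
with at least one mutant duplex reaches an SNV-count threshold (the
canonical stringency sweep is thresholds 2..10; the headline rule is >= 2).
Under the binomial count model each site is detected independently with
probability ``1 - (1 - f)^t_j``, so the number of detected sites follows a
Poisson-binomial distribution; :func:`exact_detection_probability` evaluates
the resulting detection probability exactly by dynamic-programming
convolution and serves as the analytic oracle for every Monte-Carlo
sensitivity estimate in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DuplexCountTable, SampleRecord, metadata_frame
from .errors import EmptyGroupError, ValidationError

BURDEN_FLUX_LOW = 1.5e7
BURDEN_FLUX_HIGH = 1.5e8
CANONICAL_THRESHOLDS = tuple(range(2, 11))


@dataclass(frozen=True)
class DetectionResult:
    """Per-sample detection summary at one SNV threshold."""

    sample_id: str
    snvs_detected: int
    mutant_molecules: int
    total_molecules: int
    threshold: int
    positive: bool


def detect_sample(
    n: np.ndarray,
    t: np.ndarray,
    threshold: int,
    sample_id: str = "sample",
) -> DetectionResult:
    """Classify one sample from its per-site mutant/total duplex counts.

    ``snvs_detected`` counts distinct sites with n_j >= 1; the sample is
    positive iff ``snvs_detected >= threshold`` (weak inequality).  An
    empty site vector yields snvs_detected = 0, positive only at
    threshold 0.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    n = np.asarray(n, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    if n.shape != t.shape:
        raise ValidationError("n and t must have the same shape")
    if n.size and (np.any(n < 0) or np.any(n > t)):
        raise ValidationError("counts must satisfy 0 <= n <= t")
    detected = int(np.count_nonzero(n >= 1))
    return DetectionResult(
        sample_id=sample_id,
        snvs_detected=detected,
        mutant_molecules=int(n.sum()),
        total_molecules=int(t.sum()),
        threshold=int(threshold),
        positive=detected >= threshold,
    )


def detect_table(table: DuplexCountTable, threshold: int) -> pd.DataFrame:
    """Apply :func:`detect_sample` to every sample in a count table."""
    samples, _, t, n = table.to_matrices()
    rows = [detect_sample(n[i], t[i], threshold, sample_id=s) for i, s in enumerate(samples)]
    return pd.DataFrame([r.__dict__ for r in rows])


def sensitivity(positives) -> float:
    """Fraction of positive samples in a non-empty group."""
    arr = np.asarray(list(positives), dtype=bool)
    if arr.size == 0:
        raise EmptyGroupError("sensitivity is undefined for an empty group")
    return float(arr.mean())


def burden_stratum(flux: float, low: float = BURDEN_FLUX_LOW, high: float = BURDEN_FLUX_HIGH) -> str:
    """Map a total-burden flux (photons/s) to the small/medium/large strata."""
    if flux < low:
        return "small"
    if flux <= high:
        return "medium"
    return "large"


def stratified_sensitivity(
    table: DuplexCountTable,
    metadata: list[SampleRecord] | pd.DataFrame,
    thresholds=CANONICAL_THRESHOLDS,
) -> pd.DataFrame:
    """Burden-stratified sensitivity per (stratum, arm, threshold).

    Strata are defined by the flux cutoffs 1.5e7 and 1.5e8 photons/s.
    Only strata actually populated appear in the output; an empty overall
    metadata set is an error.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    if meta.empty:
        raise EmptyGroupError("no samples in metadata")
    meta = meta.assign(stratum=meta["burden_flux"].map(burden_stratum))
    out = []
    for threshold in thresholds:
        det = detect_table(table, threshold).merge(meta, on="sample_id")
        for (stratum, arm), grp in det.groupby(["stratum", "arm"], sort=True):
            out.append(
                {
                    "stratum": stratum,
                    "arm": arm,
                    "threshold": threshold,
                    "sensitivity": sensitivity(grp["positive"]),
                    "n_samples": len(grp),
                }
            )
    return pd.DataFrame(out)


def estimate_tumor_fraction(n: np.ndarray, t: np.ndarray) -> float:
    """Maximum-likelihood tumor fraction under the binomial model: sum(n)/sum(t).

    Returns NaN (flagged missing) when the sample has no molecules at all.
    """
    n = np.asarray(n, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    total = t.sum()
    if total <= 0:
        warnings.warn("tumor fraction undefined: sample has zero total molecules", stacklevel=2)
        return float("nan")
    return float(n.sum() / total)


def tumor_fraction_table(table: DuplexCountTable) -> pd.DataFrame:
    samples, _, t, n = table.to_matrices()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fhat = [estimate_tumor_fraction(n[i], t[i]) for i in range(len(samples))]
    return pd.DataFrame({"sample_id": samples, "f_hat": fhat})


def site_detection_probabilities(t: np.ndarray, f: float) -> np.ndarray:
    """Per-site probability of observing >= 1 mutant duplex: 1 - (1-f)^t.

    Computed as ``-expm1(t * log1p(-f))`` for accuracy at tiny f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"tumor fraction must lie in [0, 1], got {f}")
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    if f == 0.0:
        return np.zeros_like(t)
    if f == 1.0:
        return (t > 0).astype(np.float64)
    return -np.expm1(t * np.log1p(-f))


def exact_detection_probability(t, f: float, threshold: int) -> float:
    """P(number of detected sites >= threshold) under the binomial model.

    The count of detected sites is Poisson-binomial with per-site success
    probabilities ``p_j = 1 - (1-f)^{t_j}``; the tail probability is
    computed exactly with a capped dynamic-programming convolution over
    sites (state = min(#detected, threshold); O(S * threshold) time).
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if threshold == 0:
        return 1.0
    p = site_detection_probabilities(t, f)
    # dp[k] = P(min(#detected so far, threshold) == k)
    dp = np.zeros(threshold + 1, dtype=np.float64)
    dp[0] = 1.0
    for pj in p:
        if pj == 0.0:
            continue
        dp[threshold] += dp[threshold - 1] * pj
        dp[1:threshold] = dp[1:threshold] * (1.0 - pj) + dp[0 : threshold - 1] * pj
        dp[0] *= 1.0 - pj
    return float(min(max(dp[threshold], 0.0), 1.0))


def relative_duplex_depth(t) -> np.ndarray:
    """Z-score per-site depths within one library (population SD).

    Output has mean 0 and SD 1.  Constant depth yields all zeros with a
    warning, since the normalization is then degenerate.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.size < 2 or not np.all(np.isfinite(t)):
        raise ValidationError("relative duplex depth needs >= 2 finite depths")
    sd = t.std()  # population (n-denominator) SD
    if sd == 0:
        warnings.warn("zero depth variance; relative duplex depth set to 0 everywhere", stacklevel=2)
        return np.zeros_like(t)
    return (t - t.mean()) / sd


def percent_remaining(conc_at_60min: float, conc_at_1min: float) -> float:
    """Percentage of a tracer remaining at 60 min relative to 1 min."""
    if conc_at_1min <= 0:
        raise ValidationError("reference concentration must be > 0")
    if conc_at_60min < 0:
        raise ValidationError("concentrations must be >= 0")
    return 100.0 * conc_at_60min / conc_at_1min


def fold_change(numerator_group, denominator_group, stat: str = "median") -> float:
    """Group fold change: stat(numerator) / stat(denominator).

    ``stat`` is 'median' or 'mean'.  Used for primed-vs-control summary
    ratios of concentrations or molecule counts.
    """
    funcs = {"median": np.median, "mean": np.mean}
    if stat not in funcs:
        raise ValidationError(f"stat must be one of {sorted(funcs)}, got {stat!r}")
    num = funcs[stat](np.asarray(list(numerator_group), dtype=np.float64))
    den = funcs[stat](np.asarray(list(denominator_group), dtype=np.float64))
    if den == 0:
        raise ValidationError("denominator group statistic is zero")
    return float(num / den)
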