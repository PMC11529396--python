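"""Bootstrap panel downsampling and binomial tumor-fraction down-scaling.

Two procedures extrapolate an observed cohort to harder detection regimes:

* :func:`downsample_panel` — bootstrap site resampling: each replicate draws
  a smaller panel (with replacement by default) from the full fingerprint,
  shared across all samples of that replicate, and recomputes group
  sensitivity on the restricted table.
* :func:`downscale_fraction` — holds the observed per-site total molecule
  counts fixed and regenerates mutant counts ``n_ij ~ Binomial(t_ij, f)``
  at lower target tumor fractions, optionally combined with panel
  downsampling.

Both report, for every grid cell, the mean and the standard error of the
replicate sensitivities (SE = SD of the replicate values by default; the
SD/sqrt(R) convention is available via ``se_mode='sem'``).  RNG streams are
split per (replicate, sample) from the master seed, so results are
deterministic given (seed, plan, table).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import DuplexCountTable, metadata_frame
from .errors import ValidationError

_SE_MODES = ("sd", "sem")


@dataclass
class ResamplingPlan:
    """Grid specification for the resampling procedures."""

    panel_sizes: Sequence[int] = (1822,)
    thresholds: Sequence[int] = tuple(range(2, 11))
    fractions: Sequence[float] = ()
    n_replicates: int = 100
    seed: int = 0
    with_replacement: bool = True
    collapse_duplicates: bool = False
    se_mode: str = "sd"

    def __post_init__(self):
        self.panel_sizes = tuple(int(k) for k in self.panel_sizes)
        self.thresholds = tuple(int(v) for v in self.thresholds)
        self.fractions = tuple(float(f) for f in self.fractions)
        if not self.panel_sizes or any(k < 1 for k in self.panel_sizes):
            raise ValidationError("panel_sizes must be a non-empty list of integers >= 1")
        if not self.thresholds or any(v < 0 for v in self.thresholds):
            raise ValidationError("thresholds must be non-empty, all >= 0")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValidationError("fractions must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2 (SE needs at least 2 replicates)")
        if self.se_mode not in _SE_MODES:
            raise ValidationError(f"se_mode must be one of {_SE_MODES}")

    @classmethod
    def from_yaml(cls, path) -> "ResamplingPlan":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "resampling" in raw:
            raw = raw["resampling"]
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _arm_lookup(metadata) -> dict[str, str]:
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    return dict(zip(meta["sample_id"], meta["arm"]))


def _summarize(values: np.ndarray, se_mode: str) -> tuple[float, float]:
    mean = float(values.mean())
    se = float(values.std(ddof=1))
    if se_mode == "sem":
        se /= np.sqrt(len(values))
    return mean, se


def _draw_sites(rng: np.random.Generator, n_sites: int, k: int, with_replacement: bool) -> np.ndarray:
    if with_replacement:
        return rng.integers(0, n_sites, size=k)
    return rng.choice(n_sites, size=k, replace=False)


def _detected_counts(n: np.ndarray, idx: np.ndarray, collapse: bool) -> np.ndarray:
    """SNV counts per sample on a resampled site multiset ``idx``.

    With replacement a site may be drawn twice; by default each copy counts
    toward the SNV tally (faithful bootstrap).  ``collapse`` counts each
    distinct detected site once instead.
    """
    if collapse:
        idx = np.unique(idx)
    return (n[:, idx] >= 1).sum(axis=1)


def _group_sensitivities(
    counts: np.ndarray, thresholds: Sequence[int], arm_codes: np.ndarray, arms: Sequence[str]
) -> dict[tuple[int, str], float]:
    out = {}
    for thr in thresholds:
        pos = counts >= thr
        for a, arm in enumerate(arms):
            mask = arm_codes == a
            out[(thr, arm)] = float(pos[mask].mean())
    return out


def _prepare(table: DuplexCountTable, metadata):
    if len(table) == 0:
        raise ValidationError("count table is empty")
    samples, sites, t, n = table.to_matrices()
    arm_of = _arm_lookup(metadata)
    missing = [s for s in samples if s not in arm_of]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    arms = sorted({arm_of[s] for s in samples})
    arm_codes = np.array([arms.index(arm_of[s]) for s in samples])
    return samples, sites, t, n, arms, arm_codes


def downsample_panel(
    table: DuplexCountTable,
    metadata,
    plan: ResamplingPlan,
) -> pd.DataFrame:
    """Bootstrap sensitivity at smaller panel sizes.

    For each replicate and panel size, one site multiset is drawn (with
    replacement by default) and applied to every sample, then group
    sensitivity is computed at each threshold.  Returns the grid with
    columns (panel_size, threshold, fraction, arm, mean, se, n_replicates);
    ``fraction`` is the string 'observed' since mutant counts are not
    regenerated.
    """
    samples, sites, t, n, arms, arm_codes = _prepare(table, metadata)
    n_sites = len(sites)
    if max(plan.panel_sizes) > n_sites:
        raise ValidationError(
            f"requested panel size {max(plan.panel_sizes)} exceeds full panel ({n_sites} sites)"
        )
    if not plan.with_replacement and max(plan.panel_sizes) > n_sites:
        raise ValidationError("cannot sample more sites than the panel without replacement")
    children = np.random.SeedSequence(plan.seed).spawn(plan.n_replicates)
    acc: dict[tuple[int, int, str], list[float]] = {}
    for child in children:
        rng = np.random.default_rng(child)
        for k in plan.panel_sizes:
            idx = _draw_sites(rng, n_sites, k, plan.with_replacement)
            counts = _detected_counts(n, idx, plan.collapse_duplicates)
            for key, val in _group_sensitivities(counts, plan.thresholds, arm_codes, arms).items():
                acc.setdefault((k, *key), []).append(val)
    rows = []
    for (k, thr, arm), vals in acc.items():
        mean, se = _summarize(np.asarray(vals), plan.se_mode)
        rows.append(
            {
                "panel_size": k,
                "threshold": thr,
                "fraction": "observed",
                "arm": arm,
                "mean": mean,
                "se": se,
                "n_replicates": plan.n_replicates,
            }
        )
    return pd.DataFrame(rows).sort_values(["panel_size", "threshold", "arm"]).reset_index(drop=True)


def downscale_fraction(
    table: DuplexCountTable,
    metadata,
    plan: ResamplingPlan,
) -> pd.DataFrame:
    """Sensitivity at lower tumor fractions by binomial regeneration.

    Holds observed t_ij fixed; per replicate and target fraction f, draws
    fresh ``n_ij ~ Binomial(t_ij, f)`` per sample (one RNG stream per
    (replicate, sample)), combines with panel downsampling as in
    :func:`downsample_panel`, and reports the sensitivity grid over
    (fraction, panel_size, threshold, arm).

    Target fractions above a sample's own anchor estimate f_hat = sum(n)/sum(t)
    are an up-scaling and trigger a warning.
    """
    if not plan.fractions:
        raise ValidationError("plan.fractions must be non-empty for downscale_fraction")
    samples, sites, t, n, arms, arm_codes = _prepare(table, metadata)
    n_sites = len(sites)
    if max(plan.panel_sizes) > n_sites:
        raise ValidationError(
            f"requested panel size {max(plan.panel_sizes)} exceeds full panel ({n_sites} sites)"
        )
    totals = t.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_hat = np.where(totals > 0, n.sum(axis=1) / np.maximum(totals, 1), np.nan)
    finite = f_hat[np.isfinite(f_hat)]
    if finite.size and max(plan.fractions) > finite.max():
        warnings.warn(
            "some target fractions exceed every sample's estimated tumor fraction; "
            "this is an up-scaling, not a down-scaling",
            stacklevel=2,
        )
    n_samp = len(samples)
    children = np.random.SeedSequence(plan.seed).spawn(plan.n_replicates)
    acc: dict[tuple[float, int, int, str], list[float]] = {}
    for child in children:
        streams = child.spawn(n_samp + 1)
        site_rng = np.random.default_rng(streams[0])
        sample_rngs = [np.random.default_rng(s) for s in streams[1:]]
        site_draws = {
            k: _draw_sites(site_rng, n_sites, k, plan.with_replacement) for k in plan.panel_sizes
        }
        for f in plan.fractions:
            n_new = np.vstack([sample_rngs[i].binomial(t[i], f) for i in range(n_samp)])
            for k, idx in site_draws.items():
                counts = _detected_counts(n_new, idx, plan.collapse_duplicates)
                for key, val in _group_sensitivities(
                    counts, plan.thresholds, arm_codes, arms
                ).items():
                    acc.setdefault((f, k, *key), []).append(val)
    rows = []
    for (f, k, thr, arm), vals in acc.items():
        mean, se = _summarize(np.asarray(vals), plan.se_mode)
        rows.append(
            {
                "panel_size": k,
                "threshold": thr,
                "fraction": f,
                "arm": arm,
                "mean": mean,
                "se": se,
                "n_replicates": plan.n_replicates,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["fraction", "panel_size", "threshold", "arm"])
        .reset_index(drop=True)
    )


def binomial_model_check(
    table: DuplexCountTable,
    metadata=None,
    n_sim: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap goodness of fit of the binomial count model.

    For each sample, compares the observed dispersion of n_ij around the
    fitted binomial mean t_ij * f_hat (Pearson chi-square statistic over
    sites with t > 0) against ``n_sim`` datasets simulated from
    Binomial(t_ij, f_hat), re-estimating f_hat in each simulated dataset.
    Reports the statistic and resampling p-value per sample; samples with
    no molecules are skipped with a note.
    """
    samples, _, t, n = table.to_matrices()
    rng = np.random.default_rng(seed)
    rows = []
    for i, sid in enumerate(samples):
        ti, ni = t[i], n[i]
        total = ti.sum()
        if total == 0:
            warnings.warn(f"sample {sid!r} has zero total molecules; skipped", stacklevel=2)
            rows.append(
                {"sample_id": sid, "f_hat": np.nan, "statistic": np.nan, "p_value": np.nan,
                 "n_sites": 0, "note": "skipped: no molecules"}
            )
            continue
        fh = ni.sum() / total
        stat = _pearson_stat(ni, ti, fh)
        sims = np.empty(n_sim)
        for s in range(n_sim):
            nsim = rng.binomial(ti, fh)
            fsim = nsim.sum() / total
            sims[s] = _pearson_stat(nsim, ti, fsim)
        p = (1.0 + np.count_nonzero(sims >= stat)) / (n_sim + 1.0)
        rows.append(
            {"sample_id": sid, "f_hat": float(fh), "statistic": float(stat),
             "p_value": float(p), "n_sites": int((ti > 0).sum()), "note": ""}
        )
    return pd.DataFrame(rows)


def _pearson_stat(n: np.ndarray, t: np.ndarray, f: float) -> float:
    mask = t > 0
    if f <= 0.0 or f >= 1.0 or not mask.any():
        return 0.0
    mu = t[mask] * f
    var = t[mask] * f * (1.0 - f)
    return float(np.sum((n[mask] - mu) ** 2 / var))
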