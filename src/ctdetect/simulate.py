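"""Synthetic cohort generation.

Generates duplex count tables with the statistical structure the downstream
estimators assume: per-site total molecule counts ``t_ij`` drawn from a
Poisson-lognormal depth law, and mutant counts ``n_ij ~ Binomial(t_ij, f_i)``
conditional on depth and the sample's tumor fraction ``f_i``.  A "priming"
arm multiplies the expected number of recovered molecules by a configurable
fold, optionally shifting the tumor fraction to emulate agents that dilute
ctDNA while boosting recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .data import DuplexCountTable, PanelFingerprint, SampleRecord, SiteRecord
from .errors import ValidationError

import pandas as pd

_BASE_CYCLE = ("A", "C", "G", "T")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic cohort.

    ``mean_depth`` is the expected total duplex molecules per site for an
    unprimed sample; ``priming_fold`` multiplies it in the primed arm.
    ``depth_dispersion`` is the lognormal sigma of multiplicative per-site
    depth effects (0 disables them).  ``fraction_shift`` multiplies the
    primed arm's tumor fraction (1.0 = recovery-only agent; < 1 emulates a
    dilution of tumor fraction under priming).  ``background_rate`` is an
    optional extension adding a uniform non-tumor mutant rate; it defaults
    to 0 and is not part of the core model.  ``flux_per_fraction`` maps the
    true fraction to a luminescence-style burden flux so burden strata are
    populated deterministically.
    """

    panel_size: int = 1822
    n_samples_per_arm: int = 8
    true_fraction_grid: Sequence[float] = (1e-3,)
    mean_depth: float = 1000.0
    depth_dispersion: float = 0.5
    priming_fold: float = 19.0
    fraction_shift: float = 1.0
    plasma_volume_mean: float = 0.33
    plasma_volume_sd: float = 0.09
    background_rate: float = 0.0
    flux_per_fraction: float = 1e10
    agent: str = "liposome"
    dose_mg_per_kg: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.panel_size < 1:
            raise ValidationError("panel_size must be >= 1")
        if self.n_samples_per_arm < 1:
            raise ValidationError("n_samples_per_arm must be >= 1")
        self.true_fraction_grid = tuple(float(f) for f in self.true_fraction_grid)
        if not self.true_fraction_grid:
            raise ValidationError("true_fraction_grid must be non-empty")
        if any(not 0.0 <= f <= 1.0 for f in self.true_fraction_grid):
            raise ValidationError("all true fractions must lie in [0, 1]")
        if not self.mean_depth > 0:
            raise ValidationError("mean_depth must be > 0")
        if self.depth_dispersion < 0:
            raise ValidationError("depth_dispersion must be >= 0")
        if self.priming_fold < 1:
            raise ValidationError("priming_fold must be >= 1")
        if not self.fraction_shift > 0:
            raise ValidationError("fraction_shift must be > 0")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValidationError("background_rate must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw:
            raw = raw["scenario"]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_fraction_grid"] = list(self.true_fraction_grid)
        return d


def make_panel(size: int, name: str = "synthetic-panel") -> PanelFingerprint:
    """Deterministically construct a synthetic SNV fingerprint panel.

    Sites are spread over 19 autosome labels with distinct coordinates;
    ref/alt alleles cycle so that ref != alt always holds.
    """
    if size < 1:
        raise ValidationError("panel size must be >= 1")
    sites = []
    for i in range(size):
        chrom = f"chr{1 + (i % 19)}"
        pos = 10_000 + 250 * i
        ref = _BASE_CYCLE[i % 4]
        alt = _BASE_CYCLE[(i + 1 + (i // 4) % 3) % 4]
        if alt == ref:  # defensive; cycle above never collides, but keep invariant local
            alt = _BASE_CYCLE[(i + 2) % 4]
        sites.append(SiteRecord(f"site{i:05d}", chrom, pos, ref, alt))
    return PanelFingerprint(tuple(sites), name=name)


def simulate_depths(
    config: ScenarioConfig,
    panel: PanelFingerprint,
    arm: str,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw total duplex molecule counts t_ij for one arm.

    Depth law: ``t_ij ~ Poisson(mean_depth * fold * L_ij)`` with ``L_ij``
    lognormal scaled to mean 1 (sigma = ``depth_dispersion``), giving
    E[t_ij] = mean_depth * fold exactly, with realistic overdispersion.
    Returns an (n_samples, panel_size) integer matrix.
    """
    if arm not in ("control", "primed"):
        raise ValidationError(f"arm must be 'control' or 'primed', got {arm!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = config.n_samples_per_arm
    fold = config.priming_fold if arm == "primed" else 1.0
    shape = (n_samples, len(panel))
    sigma = config.depth_dispersion
    if sigma > 0:
        # mean of lognormal(mu, sigma) is exp(mu + sigma^2/2); mu = -sigma^2/2 gives mean 1
        lam = config.mean_depth * fold * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)
    else:
        lam = np.full(shape, config.mean_depth * fold)
    return rng.poisson(lam).astype(np.int64)


def simulate_mutants(
    t: np.ndarray,
    f: float,
    rng: np.random.Generator,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Draw mutant duplex counts ``n_ij ~ Binomial(t_ij, f)`` elementwise.

    ``background_rate`` (default 0) adds a uniform non-tumor error rate:
    the effective success probability becomes ``f + b*(1-f)``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"tumor fraction must lie in [0, 1], got {f}")
    if not 0.0 <= background_rate <= 1.0:
        raise ValidationError("background_rate must lie in [0, 1]")
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValidationError("t must be non-negative")
    p = f + background_rate * (1.0 - f)
    return rng.binomial(t, p)


def simulate_cohort(
    config: ScenarioConfig,
    panel: PanelFingerprint | None = None,
) -> tuple[DuplexCountTable, list[SampleRecord]]:
    """Simulate a matched control/primed cohort.

    For every fraction in ``true_fraction_grid`` and every pair index, one
    control and one primed sample are generated with matched base tumor
    fraction (the primed arm's fraction is multiplied by ``fraction_shift``
    and clipped to [0, 1]).  Burden flux is a deterministic monotone map
    ``flux = flux_per_fraction * base_fraction`` shared by the pair.
    """
    if panel is None:
        panel = make_panel(config.panel_size)
    elif len(panel) != config.panel_size:
        raise ValidationError(
            f"panel has {len(panel)} sites but config.panel_size = {config.panel_size}"
        )
    rng = np.random.default_rng(config.seed)
    records: list[SampleRecord] = []
    frames: list[pd.DataFrame] = []
    site_ids = np.asarray(panel.site_ids)
    k = 0
    for base_f in config.true_fraction_grid:
        for pair in range(config.n_samples_per_arm):
            flux = config.flux_per_fraction * base_f
            for arm in ("control", "primed"):
                f = base_f if arm == "control" else min(base_f * config.fraction_shift, 1.0)
                t = simulate_depths(config, panel, arm, n_samples=1, rng=rng)[0]
                n = simulate_mutants(t, f, rng, background_rate=config.background_rate)
                sample_id = f"s{k:04d}_{arm}"
                k += 1
                vol = max(rng.normal(config.plasma_volume_mean, config.plasma_volume_sd), 0.05)
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        arm=arm,
                        agent=config.agent if arm == "primed" else "none",
                        dose_mg_per_kg=config.dose_mg_per_kg if arm == "primed" else 0.0,
                        burden_flux=flux,
                        plasma_volume_ml=float(vol),
                        timepoint="t0",
                        true_fraction=float(f),
                    )
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "site_id": site_ids,
                            "t": t,
                            "n": n,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return DuplexCountTable(df, panel=panel), records
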