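"""Data model and file IO for SNV fingerprint panels and duplex count tables.

The pipeline's central observable is the duplex count table: for every
(sample, panel site) pair, the number of total duplex molecules ``t`` and
mutant duplex molecules ``n`` recovered at that site.  Panels are stored as
BED-like TSV (0-based half-open coordinates), count tables and sample
metadata as headered TSV.  ``site_id`` is the authoritative join key
throughout; genomic coordinates are annotation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

ARMS = ("control", "primed")
AGENTS = ("liposome", "antibody", "none")

COUNTS_COLUMNS = ("sample_id", "site_id", "t", "n")
METADATA_COLUMNS = (
    "sample_id",
    "arm",
    "agent",
    "dose_mg_per_kg",
    "burden_flux",
    "plasma_volume_ml",
    "timepoint",
)
SENSITIVITY_COLUMNS = (
    "panel_size",
    "threshold",
    "fraction",
    "arm",
    "mean",
    "se",
    "n_replicates",
)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """One tumor-specific SNV tracked by the assay."""

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"site {self.site_id!r}: pos must be >= 0, got {self.pos}")
        for label, base in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if len(base) != 1 or base.upper() not in _BASES:
                raise ValidationError(
                    f"site {self.site_id!r}: {label} allele must be a single base, got {base!r}"
                )
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValidationError(
                f"site {self.site_id!r}: ref and alt alleles are identical ({self.ref_allele!r})"
            )


@dataclass(frozen=True)
class PanelFingerprint:
    """An ordered set of tumor-specific SNV sites ("fingerprint panel")."""

    sites: tuple[SiteRecord, ...]
    name: str = "panel"

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        if len(self.sites) < 1:
            raise ValidationError("panel must contain at least one site")
        seen: set[str] = set()
        for s in self.sites:
            if s.site_id in seen:
                raise ValidationError(f"duplicate site_id {s.site_id!r} in panel {self.name!r}")
            seen.add(s.site_id)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata accompanying a count table.

    ``true_fraction`` is only present for synthetic cohorts, where the
    generating tumor fraction is known.
    """

    sample_id: str
    arm: str
    agent: str = "none"
    dose_mg_per_kg: float = 0.0
    burden_flux: float = 0.0
    plasma_volume_ml: float = 0.33
    timepoint: str = "t0"
    true_fraction: float | None = None

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValidationError(f"sample {self.sample_id!r}: arm must be one of {ARMS}, got {self.arm!r}")
        if self.agent not in AGENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: agent must be one of {AGENTS}, got {self.agent!r}"
            )
        if not self.plasma_volume_ml > 0:
            raise ValidationError(f"sample {self.sample_id!r}: plasma_volume_ml must be > 0")
        if self.burden_flux < 0:
            raise ValidationError(f"sample {self.sample_id!r}: burden_flux must be >= 0")
        if self.dose_mg_per_kg < 0:
            raise ValidationError(f"sample {self.sample_id!r}: dose must be >= 0")
        if self.true_fraction is not None and not 0.0 <= self.true_fraction <= 1.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: true_fraction must lie in [0, 1], got {self.true_fraction}"
            )


class DuplexCountTable:
    """Long-format table of per-sample, per-site duplex molecule counts.

    Invariants enforced at construction: integer counts with ``0 <= n <= t``
    for every row, at most one row per (sample_id, site_id) pair, and — when
    a panel is bound — every ``site_id`` a member of that panel.
    """

    def __init__(self, df: pd.DataFrame, panel: PanelFingerprint | None = None):
        missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"count table missing columns: {missing}")
        df = df.loc[:, list(COUNTS_COLUMNS)].reset_index(drop=True)
        if len(df):
            for col in ("t", "n"):
                vals = df[col].to_numpy()
                if not np.issubdtype(np.asarray(vals).dtype, np.number):
                    raise ValidationError(f"column {col!r} must be numeric")
                if np.any(vals != np.floor(vals)) or np.any(vals < 0):
                    raise ValidationError(f"column {col!r} must hold non-negative integers")
            df = df.astype({"t": np.int64, "n": np.int64})
            bad = df["n"] > df["t"]
            if bad.any():
                rows = df.index[bad].tolist()[:5]
                raise ValidationError(f"n > t at rows {rows} (showing up to 5)")
            dup = df.duplicated(subset=["sample_id", "site_id"])
            if dup.any():
                pairs = df.loc[dup, ["sample_id", "site_id"]].head().to_records(index=False).tolist()
                raise ValidationError(f"duplicate (sample_id, site_id) pairs: {pairs}")
        else:
            df = df.astype({"sample_id": str, "site_id": str, "t": np.int64, "n": np.int64})
        if panel is not None and len(df):
            unknown = sorted(set(df["site_id"]) - set(panel.site_ids))
            if unknown:
                raise ValidationError(f"site_ids not in panel {panel.name!r}: {unknown[:10]}")
        self._df = df
        self.panel = panel

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DuplexCountTable):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def sample_ids(self) -> list[str]:
        """Sample identifiers in first-appearance order."""
        return list(dict.fromkeys(self._df["sample_id"]))

    def to_matrices(self) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
        """Pivot to dense matrices ``(samples, sites, t, n)``.

        Missing (sample, site) pairs are filled with t=0, n=0; a warning is
        logged because downstream statistics treat absent sites as
        zero-depth dropouts rather than errors.
        """
        samples = self.sample_ids
        if self.panel is not None:
            sites = list(self.panel.site_ids)
        else:
            sites = list(dict.fromkeys(self._df["site_id"]))
        si = {s: i for i, s in enumerate(samples)}
        ji = {s: j for j, s in enumerate(sites)}
        t = np.zeros((len(samples), len(sites)), dtype=np.int64)
        n = np.zeros_like(t)
        rows = self._df
        ii = rows["sample_id"].map(si).to_numpy()
        jj = rows["site_id"].map(ji).to_numpy()
        if len(rows):
            t[ii, jj] = rows["t"].to_numpy()
            n[ii, jj] = rows["n"].to_numpy()
        n_missing = t.size - len(rows)
        if n_missing > 0:
            logger.warning(
                "count table has %d missing (sample, site) pairs; treated as t=0, n=0",
                n_missing,
            )
        return samples, sites, t, n


# ---------------------------------------------------------------------------
# panel IO


def read_panel(path, name: str | None = None) -> PanelFingerprint:
    """Read a fingerprint panel from a BED-like TSV.

    Accepts either 6 columns (chrom, start, end, ref, alt, site_id; 0-based
    half-open) or 4 columns (chrom, pos, ref, alt) where ``site_id`` is
    derived as ``chrom:pos:ref>alt``.  Lines starting with '#' are comments.
    """
    path = Path(path)
    sites: list[SiteRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) == 6:
                    chrom, start, end, ref, alt, site_id = parts
                    pos = int(start)
                    if int(end) != pos + 1:
                        raise ValueError(f"SNV interval must have end == start + 1, got {start}..{end}")
                elif len(parts) == 4:
                    chrom, pos_s, ref, alt = parts
                    pos = int(pos_s)
                    site_id = f"{chrom}:{pos}:{ref}>{alt}"
                else:
                    raise ValueError(f"expected 4 or 6 tab-separated columns, got {len(parts)}")
            except ValueError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from exc
            try:
                sites.append(SiteRecord(site_id, chrom, pos, ref, alt))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    if name is None:
        name = path.stem
    return PanelFingerprint(tuple(sites), name=name)


def write_panel(panel: PanelFingerprint, path) -> None:
    """Write a panel as 6-column BED-like TSV (0-based half-open)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in panel.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.ref_allele}\t{s.alt_allele}\t{s.site_id}\n")


# ---------------------------------------------------------------------------
# count-table IO


def read_counts(path, panel: PanelFingerprint | None = None) -> DuplexCountTable:
    """Read a duplex count TSV (header: sample_id, site_id, t, n)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError("file is empty (expected a header line)", path=path) from exc
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path, line=1)
    return DuplexCountTable(df, panel=panel)


def write_counts(table: DuplexCountTable, path) -> None:
    table._df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# sample metadata IO


def read_metadata(path) -> list[SampleRecord]:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "arm": str, "agent": str, "timepoint": str},
        float_precision="round_trip",
    )
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path, line=1)
    records = []
    for _, row in df.iterrows():
        tf = row.get("true_fraction", None)
        if tf is not None and (pd.isna(tf)):
            tf = None
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                arm=row["arm"],
                agent=row["agent"],
                dose_mg_per_kg=float(row["dose_mg_per_kg"]),
                burden_flux=float(row["burden_flux"]),
                plasma_volume_ml=float(row["plasma_volume_ml"]),
                timepoint=str(row["timepoint"]),
                true_fraction=None if tf is None else float(tf),
            )
        )
    return records


def metadata_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(SampleRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def _roundtrip_floats(df: pd.DataFrame) -> pd.DataFrame:
    """Render float columns with Python's shortest round-trip repr.

    pandas' default CSV float formatting can drop the last significant
    digit, breaking the lossless round-trip contract.
    """
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    return df


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    df = metadata_frame(records)
    if df["true_fraction"].isna().all():
        df = df.drop(columns=["true_fraction"])
    else:
        df["true_fraction"] = df["true_fraction"].astype(float)
    _roundtrip_floats(df).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# sensitivity grid IO


def write_sensitivity(estimates: pd.DataFrame, path) -> None:
    """Write a sensitivity grid with the fixed schema

    (panel_size, threshold, fraction, arm, mean, se, n_replicates).
    """
    missing = [c for c in SENSITIVITY_COLUMNS if c not in estimates.columns]
    if missing:
        raise ValidationError(f"sensitivity table missing columns: {missing}")
    out = _roundtrip_floats(estimates.loc[:, list(SENSITIVITY_COLUMNS)])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sensitivity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in SENSITIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path, line=1)
    return df
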