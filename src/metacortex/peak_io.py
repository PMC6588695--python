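"""Peak-table and sample-metadata I/O, mode merging, and MDS embedding.

The pipeline consumes two tables:

* a *peak table*: peaks x samples matrix of linear-scale LC-MS intensities,
  with per-peak m/z, optional retention time and an ionization-mode label
  (``positive`` or ``negative``);
* a *sample metadata* table: one row per sample with species, diagnostic
  group, age, sex, postmortem delay (PMD), RNA integrity (RIN), injection
  order and batch.

Files are CSV (UTF-8, header row, ``NA`` for missing); TSV is auto-detected
from a ``.tsv``/``.txt`` extension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    ArgumentError,
    FormatError,
    LinkageError,
    MergeError,
    ValidationError,
)

MODES = ("positive", "negative")
SPECIES = ("human", "chimpanzee", "macaque")
GROUPS = ("control", "ASD")

_META_REQUIRED = ["sample_id", "species", "group", "age", "injection_order"]
_META_OPTIONAL = ["sex", "pmd_hours", "rin", "batch"]


@dataclass
class PeakTable:
    """Peaks x samples intensity matrix with per-peak mass annotations.

    Intensities are linear scale unless ``log2`` is set. Peak and sample
    identifiers are unique; ``mode`` holds one ionization label per peak.
    """

    peak_ids: list[str]
    mode: np.ndarray          # per-peak, values in MODES
    mz: np.ndarray            # per-peak m/z (Da)
    rt: np.ndarray | None     # per-peak retention time (min) or None
    intensities: np.ndarray   # peaks x samples
    sample_ids: list[str]
    log2: bool = False

    def __post_init__(self) -> None:
        self.peak_ids = [str(p) for p in self.peak_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.mode = np.asarray(self.mode, dtype=object)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
        n_peaks, n_samples = self.intensities.shape
        if len(self.peak_ids) != n_peaks or len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"matrix shape {self.intensities.shape} does not match "
                f"{len(self.peak_ids)} peak ids x {len(self.sample_ids)} sample ids"
            )
        dup = _duplicates(self.peak_ids)
        if dup:
            raise FormatError(f"duplicate peak ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids: {sorted(dup)}")
        if len(self.mode) != n_peaks or len(self.mz) != n_peaks:
            raise ValidationError("per-peak annotations must match peak count")
        bad_modes = set(self.mode) - set(MODES)
        if bad_modes:
            raise ValidationError(f"unknown ionization modes: {sorted(bad_modes)}")
        if np.any(self.mz <= 0) or not np.all(np.isfinite(self.mz)):
            raise ValidationError("m/z values must be positive and finite")
        if not self.log2:
            neg = np.argwhere(self.intensities < 0)
            if neg.size:
                i, j = neg[0]
                raise ValidationError(
                    f"negative intensity at peak {self.peak_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def log2_intensities(self, pseudocount: float = 0.0) -> np.ndarray:
        """Return the matrix on log2 scale (identity if already log2)."""
        if self.log2:
            return self.intensities
        return np.log2(self.intensities + pseudocount)

    def subset_peaks(self, keep: np.ndarray) -> "PeakTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            peak_ids=[self.peak_ids[i] for i in keep],
            mode=self.mode[keep],
            mz=self.mz[keep],
            rt=None if self.rt is None else self.rt[keep],
            intensities=self.intensities[keep, :],
        )

    def subset_samples(self, sample_ids: list[str]) -> "PeakTable":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise LinkageError(f"samples not in table: {missing}")
        cols = [index[s] for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            intensities=self.intensities[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.intensities, index=self.peak_ids, columns=self.sample_ids
        )
        frame.insert(0, "mz", self.mz)
        if self.rt is not None:
            frame.insert(1, "rt", self.rt)
        frame.index.name = "peak_id"
        return frame


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_peak_table(
    path: str,
    mode: str,
    metadata: pd.DataFrame | None = None,
) -> PeakTable:
    """Read a peak table CSV/TSV.

    The file carries a ``peak_id`` column, an ``mz`` column, an optional
    ``rt`` column, and one intensity column per sample. When ``metadata``
    is supplied, every sample column must exist in it.
    """
    if mode not in MODES:
        raise ArgumentError(f"mode must be one of {MODES}, got {mode!r}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype={"peak_id": str})
    if "peak_id" not in raw.columns or "mz" not in raw.columns:
        raise FormatError("peak table requires 'peak_id' and 'mz' columns")
    dup = _duplicates(list(raw["peak_id"]))
    if dup:
        raise FormatError(f"duplicate peak id(s): {sorted(dup)}")
    rt = raw["rt"].to_numpy(float) if "rt" in raw.columns else None
    sample_cols = [c for c in raw.columns if c not in ("peak_id", "mz", "rt")]
    if not sample_cols:
        raise FormatError("peak table has no sample columns")
    values = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"non-numeric intensity at peak {raw['peak_id'].iloc[i]!r}, "
            f"sample {sample_cols[j]!r}"
        )
    neg = np.argwhere(values.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative intensity at peak {raw['peak_id'].iloc[i]!r}, "
            f"sample {sample_cols[j]!r}"
        )
    if metadata is not None:
        known = set(metadata["sample_id"])
        orphan = [s for s in sample_cols if s not in known]
        if orphan:
            raise LinkageError(f"sample columns absent from metadata: {orphan}")
    return PeakTable(
        peak_ids=list(raw["peak_id"]),
        mode=np.full(len(raw), mode, dtype=object),
        mz=raw["mz"].to_numpy(float),
        rt=rt,
        intensities=values.to_numpy(float),
        sample_ids=sample_cols,
    )


def write_peak_table(table: PeakTable, path: str) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path))


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Read and validate sample metadata.

    Required columns: sample_id, species, group, age, injection_order.
    Species parsed case-insensitively; nonhuman samples must have group NA;
    negative ages encode prenatal time points (years before birth).
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    missing = [c for c in _META_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(f"metadata missing required column(s): {missing}")
    meta = raw.copy()
    dup = _duplicates(list(meta["sample_id"]))
    if dup:
        raise ValidationError(f"duplicate sample_id(s): {sorted(dup)}")
    meta["species"] = meta["species"].astype(str).str.strip().str.lower()
    bad = set(meta["species"]) - set(SPECIES)
    if bad:
        raise ValidationError(f"unknown species: {sorted(bad)}")
    meta["group"] = meta["group"].astype(object).where(meta["group"].notna(), None)
    meta["group"] = [
        None if g is None or str(g).strip().upper() == "NA" else str(g).strip()
        for g in meta["group"]
    ]
    for sid, sp, g in zip(meta["sample_id"], meta["species"], meta["group"]):
        if sp == "human":
            if g not in GROUPS:
                raise ValidationError(
                    f"human sample {sid!r} must have group in {GROUPS}, got {g!r}"
                )
        elif g is not None:
            raise ValidationError(
                f"nonhuman sample {sid!r} must have group NA, got {g!r}"
            )
    meta["age"] = pd.to_numeric(meta["age"], errors="raise").astype(float)
    meta["injection_order"] = pd.to_numeric(
        meta["injection_order"], errors="raise"
    ).astype(int)
    if (meta["injection_order"] <= 0).any():
        raise ValidationError("injection_order must be positive")
    if meta["injection_order"].duplicated().any():
        raise ValidationError("injection_order values must be unique within a run")
    for col in _META_OPTIONAL:
        if col not in meta.columns:
            meta[col] = np.nan if col in ("pmd_hours", "rin") else None
    for col in ("pmd_hours", "rin"):
        meta[col] = pd.to_numeric(meta[col], errors="coerce")
    if (meta["pmd_hours"].dropna() < 0).any():
        raise ValidationError("pmd_hours must be non-negative")
    return meta.reset_index(drop=True)


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    out = meta.copy()
    out["group"] = [g if g is not None else "NA" for g in out["group"]]
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


def merge_modes(pos: PeakTable, neg: PeakTable) -> PeakTable:
    """Concatenate positive- and negative-mode tables along the peak axis.

    Peak ids are prefixed ``pos:``/``neg:`` so the merge is reversible and
    collision-free; sample columns are aligned by id.
    """
    set_pos, set_neg = set(pos.sample_ids), set(neg.sample_ids)
    if set_pos != set_neg:
        only_pos = sorted(set_pos - set_neg)
        only_neg = sorted(set_neg - set_pos)
        raise MergeError(
            f"sample sets differ; only in positive: {only_pos}, "
            f"only in negative: {only_neg}"
        )
    if pos.log2 != neg.log2:
        raise MergeError("cannot merge tables on different intensity scales")
    neg_aligned = neg.subset_samples(pos.sample_ids)
    return PeakTable(
        peak_ids=[f"pos:{p}" for p in pos.peak_ids]
        + [f"neg:{p}" for p in neg_aligned.peak_ids],
        mode=np.concatenate([pos.mode, neg_aligned.mode]),
        mz=np.concatenate([pos.mz, neg_aligned.mz]),
        rt=None
        if pos.rt is None or neg_aligned.rt is None
        else np.concatenate([pos.rt, neg_aligned.rt]),
        intensities=np.vstack([pos.intensities, neg_aligned.intensities]),
        sample_ids=list(pos.sample_ids),
        log2=pos.log2,
    )


def mds_embedding(table: PeakTable, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples.

    Intensities are log2-transformed and standardized per peak, distances
    are Euclidean over the standardized peaks, and coordinates come from the
    eigendecomposition of the double-centered squared-distance matrix,
    ordered by decreasing eigenvalue. For an exactly embeddable metric the
    pairwise embedded distances reproduce the input distances.
    """
    n = table.n_samples
    if n < 3:
        raise ArgumentError("MDS requires at least 3 samples")
    if n_dims >= n:
        raise ArgumentError(f"n_dims ({n_dims}) must be < sample count ({n})")
    x = table.log2_intensities()
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    diff = z[:, :, None] - z[:, None, :]
    d2 = np.einsum("kij,kij->ij", diff, diff)
    coords = classical_mds_from_distances(np.sqrt(d2), n_dims)
    return pd.DataFrame(
        coords,
        index=table.sample_ids,
        columns=[f"dim{k + 1}" for k in range(n_dims)],
    )


def classical_mds_from_distances(dist: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson MDS on a symmetric distance matrix."""
    d2 = np.asarray(dist, float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)
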