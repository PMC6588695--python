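"""Putative metabolite annotation by adduct m/z matching.

Observed peak m/z values are matched against theoretical singly-charged
adduct masses of a compound table (HMDB/LMSD-style) within a relative
tolerance in parts per million. All candidates within tolerance are
reported; no best-match collapse is attempted, since LC-MS m/z matching is
putative by nature and downstream gene linking consumes every candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, FormatError, ValidationError
from .peak_io import PeakTable

# Monoisotopic mass deltas (Da) for singly charged adducts. Values are the
# sums/differences of proton, NH4, Na (minus one electron), formic acid and
# water monoisotopic masses, fixed to 6 decimals in one auditable table.
ADDUCT_DELTAS: dict[str, float] = {
    "[M+H]": 1.007276,
    "[M+NH4]": 18.033823,
    "[M+Na]": 22.989218,
    "[M-H]": -1.007276,
    "[M+FA-H]": 44.998201,     # formic acid adduct, deprotonated
    "[M-H2O-H]": -19.018390,
    "[M+Na-2H]": 20.974666,
}

POSITIVE_ADDUCTS = ("[M+H]", "[M+NH4]", "[M+Na]")
NEGATIVE_ADDUCTS = ("[M-H]", "[M+FA-H]", "[M-H2O-H]", "[M+Na-2H]")


@dataclass
class AnnotationConfig:
    """Tolerance and per-mode adduct sets (defaults match the study design)."""

    ppm_tolerance: float = 10.0
    adducts_positive: tuple[str, ...] = POSITIVE_ADDUCTS
    adducts_negative: tuple[str, ...] = NEGATIVE_ADDUCTS

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ArgumentError("ppm_tolerance must be > 0")
        for a in (*self.adducts_positive, *self.adducts_negative):
            if a not in ADDUCT_DELTAS:
                raise ArgumentError(f"unknown adduct label {a!r}")

    def adducts_for(self, mode: str) -> tuple[str, ...]:
        return self.adducts_positive if mode == "positive" else self.adducts_negative


def adduct_mz(monoisotopic_mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct of a neutral mass."""
    if adduct not in ADDUCT_DELTAS:
        raise ArgumentError(f"unknown adduct label {adduct!r}")
    if monoisotopic_mass <= 0:
        raise ArgumentError("monoisotopic mass must be > 0")
    return monoisotopic_mass + ADDUCT_DELTAS[adduct]


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ArgumentError("m/z values must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def read_compound_table(path: str) -> pd.DataFrame:
    """Read a compound table CSV (compound_id, name, monoisotopic_mass[, source])."""
    raw = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "name", "monoisotopic_mass"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"compound table missing column(s): {sorted(missing)}")
    if raw["compound_id"].duplicated().any():
        dup = raw.loc[raw["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValidationError(f"duplicate compound id(s): {dup}")
    mass = pd.to_numeric(raw["monoisotopic_mass"], errors="raise")
    if (mass <= 0).any() or not np.isfinite(mass).all():
        raise ValidationError("monoisotopic masses must be positive and finite")
    raw["monoisotopic_mass"] = mass.astype(float)
    if "source" not in raw.columns:
        raw["source"] = "other"
    return raw


def annotate_peaks(
    table: PeakTable,
    compounds: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Match every peak against every mode-appropriate adduct of every compound.

    Returns one row per (peak, compound, adduct) with |ppm error| <= tolerance.
    Candidate lookup is an interval query over a mass-sorted index and is, by
    contract, record-for-record identical to an exhaustive scan.
    """
    if config is None:
        config = AnnotationConfig()
    if len(compounds) == 0:
        raise ArgumentError("compound table is empty")
    masses = compounds["monoisotopic_mass"].to_numpy(float)
    ids = compounds["compound_id"].to_numpy(object)
    order = np.argsort(masses, kind="stable")
    masses_sorted, ids_sorted = masses[order], ids[order]

    tol = config.ppm_tolerance * 1e-6
    records: list[tuple] = []
    for i, peak_id in enumerate(table.peak_ids):
        observed = table.mz[i]
        for adduct in config.adducts_for(table.mode[i]):
            delta = ADDUCT_DELTAS[adduct]
            # |obs - theo| <= theo * tol  <=>  theo in [obs/(1+tol), obs/(1-tol)]
            lo = observed / (1.0 + tol) - delta
            hi = observed / (1.0 - tol) - delta
            a = np.searchsorted(masses_sorted, lo, side="left")
            b = np.searchsorted(masses_sorted, hi, side="right")
            for j in range(a, b):
                theo = masses_sorted[j] + delta
                if theo <= 0:
                    continue
                err = ppm_error(observed, theo)
                if abs(err) <= config.ppm_tolerance:
                    records.append((peak_id, ids_sorted[j], adduct, theo, err))
    result = pd.DataFrame(
        records,
        columns=["peak_id", "compound_id", "adduct", "theoretical_mz", "ppm_error"],
    )
    return result.sort_values(
        ["peak_id", "compound_id", "adduct"], kind="stable"
    ).reset_index(drop=True)


def annotate_peaks_bruteforce(
    table: PeakTable,
    compounds: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Exhaustive O(peaks x compounds) reference scan (testing oracle)."""
    if config is None:
        config = AnnotationConfig()
    if len(compounds) == 0:
        raise ArgumentError("compound table is empty")
    records = []
    for i, peak_id in enumerate(table.peak_ids):
        for adduct in config.adducts_for(table.mode[i]):
            for cid, mass in zip(
                compounds["compound_id"], compounds["monoisotopic_mass"]
            ):
                theo = mass + ADDUCT_DELTAS[adduct]
                if theo <= 0:
                    continue
                err = ppm_error(table.mz[i], theo)
                if abs(err) <= config.ppm_tolerance:
                    records.append((peak_id, cid, adduct, theo, err))
    result = pd.DataFrame(
        records,
        columns=["peak_id", "compound_id", "adduct", "theoretical_mz", "ppm_error"],
    )
    return result.sort_values(
        ["peak_id", "compound_id", "adduct"], kind="stable"
    ).reset_index(drop=True)
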