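"""Scoring of the three cilia-dependent behavioural assays.

Dye filling (number of phasmid neurons, 0-4, taking up lipophilic dye),
roaming (squares of a 5x5 mm grid entered overnight, normalised to the
wild-type mean), and osmotic avoidance (time to escape a high-osmolarity
ring, right-censored at 10 min).  Worms with a missing field are excluded
per-assay; trials are pooled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import COHORT_COLUMNS

DEFAULT_CENSOR_MIN = 10.0


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a behavioural cohort CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return validate_cohort(df)


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, index=False)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    dye = df["dye_filled_count"].dropna()
    if not dye.isin([0, 1, 2, 3, 4]).all():
        raise ValueError("dye_filled_count must be in 0..4")
    t = df["escape_time_min"].dropna()
    if (t <= 0).any():
        raise ValueError("escape_time_min must be > 0")
    return df


def _group(df: pd.DataFrame, genotype: str) -> pd.DataFrame:
    sub = df[df["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no records for genotype {genotype!r}")
    return sub


def dye_filling_frequency(df: pd.DataFrame, genotype: str) -> tuple[np.ndarray, int]:
    """Frequencies of worms with dye uptake in 0..4 phasmid neurons.

    Trials are pooled; returns (5 fractions summing to 1, n scored worms).
    """
    counts = _group(df, genotype)["dye_filled_count"].dropna().astype(int)
    if counts.empty:
        raise ValueError(f"no dye-filling scores for genotype {genotype!r}")
    freqs = np.bincount(counts, minlength=5).astype(float)
    n = int(freqs.sum())
    return freqs / n, n


def roaming_index(
    df: pd.DataFrame, genotype: str, reference_genotype: str
) -> np.ndarray:
    """Per-worm square counts divided by the reference genotype's mean."""
    ref = _group(df, reference_genotype)["squares_entered"].dropna().astype(float)
    if ref.empty:
        raise ValueError(f"no roaming scores for reference {reference_genotype!r}")
    ref_mean = ref.mean()
    if not ref_mean > 0:
        raise ValueError("reference roaming mean must be > 0")
    vals = _group(df, genotype)["squares_entered"].dropna().astype(float)
    return vals.to_numpy() / ref_mean


def osmotic_retention_curve(
    df: pd.DataFrame,
    genotype: str,
    time_grid: Optional[Sequence[float]] = None,
    censor_time_min: float = DEFAULT_CENSOR_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of worms still inside the osmotic ring at each time point.

    Censored worms never escape.  The curve is evaluated on a 1-min grid
    by default; its final (10-min) values are what the group comparison
    uses.  Returns ``(times, fraction_remaining)``.
    """
    if time_grid is None:
        time_grid = np.arange(1.0, censor_time_min + 1e-9, 1.0)
    times = np.asarray(time_grid, dtype=float)
    if np.any(times <= 0) or np.any(times > censor_time_min + 1e-9):
        raise ValueError("time grid must lie in (0, censor]")
    sub = _group(df, genotype).dropna(subset=["escape_time_min"])
    if sub.empty:
        raise ValueError(f"no escape times for genotype {genotype!r}")
    t = sub["escape_time_min"].to_numpy(dtype=float)
    censored = sub["censored"].to_numpy(dtype=bool)
    remaining = np.array(
        [float(np.mean(censored | (t > tt))) for tt in times]
    )
    return times, remaining


def final_retention(
    df: pd.DataFrame, genotype: str, censor_time_min: float = DEFAULT_CENSOR_MIN
) -> float:
    """Fraction remaining at the end of the assay (the 10-min convention)."""
    _, rem = osmotic_retention_curve(
        df, genotype, time_grid=[censor_time_min], censor_time_min=censor_time_min
    )
    return float(rem[-1])
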