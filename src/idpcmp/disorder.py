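"""Per-residue disorder tracks and per-protein disorder metrics.

External disorder predictors (Disopred, VSL2, IUPred, ANCHOR and kin) emit one
score in [0, 1] per residue.  This module ingests such tracks, binarizes them
at a predictor-specific threshold (0.5 for VSL2/IUPred-style scores, 0.05 for
Disopred-style), detects long disordered windows (LDWs, runs of at least 30
consecutive disordered residues) and disordered binding regions (DBRs), and
summarizes each protein as:

* percentage of disordered residues,
* number of LDWs and percentage of residues inside LDWs,
* a "disordered protein" flag (>= 50% disordered residues),
* number of DBRs and percentage of residues in DBRs.

A deliberately simple built-in composition predictor (charge/hydropathy
foldability index over a sliding window) is provided so the full pipeline can
run end-to-end without any external predictor output.

Coordinates: score files are 1-based; in memory every region is a half-open
0-based ``(start, end)`` pair.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DataError

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Formal residue charge at neutral pH used by the built-in predictor.
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

DEFAULT_LDW_MIN = 30
DEFAULT_DBR_MIN_LEN = 6
DEFAULT_DISORDERED_CUTOFF = 50.0

#: Fine and coarse percentage bin presets for binned disorder distributions.
BIN_EDGES_FINE = tuple(range(0, 101, 10))
BIN_EDGES_COARSE = (0, 30, 50, 100)


@dataclass
class DisorderProfile:
    """Per-residue scores in [0, 1] for one protein and one predictor."""

    protein_id: str
    predictor_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise DataError(
                f"profile {self.protein_id!r}: scores must be a non-empty 1-D array"
            )
        if np.any(self.scores < 0.0) or np.any(self.scores > 1.0):
            bad = int(np.flatnonzero((self.scores < 0) | (self.scores > 1))[0])
            raise DataError(
                f"profile {self.protein_id!r}: score {self.scores[bad]} at "
                f"position {bad + 1} outside [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class DisorderMask:
    """Thresholded binary form of a :class:`DisorderProfile`.

    ``flags[i]`` is True when residue ``i`` is called disordered (or, for a
    binding-region track, binding).
    """

    protein_id: str
    flags: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1 or self.flags.size == 0:
            raise DataError(
                f"mask {self.protein_id!r}: flags must be a non-empty 1-D array"
            )

    def __len__(self) -> int:
        return int(self.flags.size)


@dataclass
class DisorderMetrics:
    """Per-protein disorder summary (one table row per protein).

    DBR fields are ``None`` when no binding-region track was supplied.
    """

    protein_id: str
    length: int
    pct_disordered: float
    n_ldw: int
    pct_in_ldw: float
    is_disordered_protein: bool
    n_dbr: int | None = None
    pct_dbr_residues: float | None = None


def parse_scores(
    path: str | Path,
    dialect: str = "long_tsv",
    predictor_name: str = "file",
) -> dict[str, DisorderProfile]:
    """Read per-residue score tracks into profiles keyed by protein id.

    ``long_tsv``: tab-separated with a header naming at least ``protein_id``,
    ``position`` (1-based, contiguous per protein) and ``score``; an optional
    ``residue`` column is ignored.  ``horizontal``: no header, one line per
    protein holding the id followed by its scores.
    """
    path = Path(path)
    if dialect == "long_tsv":
        return _parse_long_tsv(path, predictor_name)
    if dialect == "horizontal":
        return _parse_horizontal(path, predictor_name)
    raise ConfigError(f"unknown score dialect {dialect!r}")


def _parse_long_tsv(path: Path, predictor_name: str) -> dict[str, DisorderProfile]:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    profiles: dict[str, DisorderProfile] = {}
    for pid, group in frame.groupby("protein_id", sort=False):
        positions = group["position"].to_numpy()
        expected = np.arange(1, len(group) + 1)
        if not np.array_equal(positions, expected):
            gap = int(expected[positions != expected][0])
            raise DataError(
                f"{path}: protein {pid!r}: positions not contiguous from 1 "
                f"(first problem at position {gap})"
            )
        profiles[str(pid)] = DisorderProfile(
            str(pid), predictor_name, group["score"].to_numpy(dtype=float)
        )
    if not profiles:
        raise DataError(f"{path}: no score rows found")
    return profiles


def _parse_horizontal(path: Path, predictor_name: str) -> dict[str, DisorderProfile]:
    profiles: dict[str, DisorderProfile] = {}
    with open(path) as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            pid, *values = row
            if not values:
                raise DataError(f"{path}: line {lineno}: no scores for {pid!r}")
            try:
                scores = np.array([float(v) for v in values])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
            if pid in profiles:
                raise DataError(f"{path}: duplicate protein_id {pid!r}")
            profiles[pid] = DisorderProfile(pid, predictor_name, scores)
    if not profiles:
        raise DataError(f"{path}: no score rows found")
    return profiles


def binarize(profile: DisorderProfile, threshold: float) -> DisorderMask:
    """Call a residue disordered when its score is >= *threshold*.

    The boundary is inclusive, consistent with the >= 50% disordered-protein
    rule used downstream.  Lowering the threshold can only add flags, so every
    derived metric is monotone non-increasing in the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"threshold must be in (0, 1), got {threshold}")
    return DisorderMask(profile.protein_id, profile.scores >= threshold, threshold)


def _true_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open 0-based (start, end) pairs."""
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def long_windows(
    mask: DisorderMask, min_len: int = DEFAULT_LDW_MIN
) -> list[tuple[int, int]]:
    """Maximal disordered runs of at least *min_len* residues, sorted."""
    if min_len < 1:
        raise ConfigError(f"min_len must be >= 1, got {min_len}")
    return [(s, e) for s, e in _true_runs(mask.flags) if e - s >= min_len]


def compute_metrics(
    disorder_mask: DisorderMask,
    dbr_mask: DisorderMask | None = None,
    ldw_min: int = DEFAULT_LDW_MIN,
    disordered_protein_cutoff: float = DEFAULT_DISORDERED_CUTOFF,
    dbr_min_len: int = DEFAULT_DBR_MIN_LEN,
) -> DisorderMetrics:
    """Summarize one protein's binary disorder (and optional DBR) track.

    The disordered-protein flag uses an inclusive cutoff: a protein with
    exactly ``disordered_protein_cutoff`` percent disordered residues is
    flagged.  DBRs are maximal binding runs of at least *dbr_min_len*.
    """
    if not 0.0 < disordered_protein_cutoff <= 100.0:
        raise ConfigError(
            f"disordered_protein_cutoff must be in (0, 100], got "
            f"{disordered_protein_cutoff}"
        )
    n = len(disorder_mask)
    if dbr_mask is not None and len(dbr_mask) != n:
        raise DataError(
            f"protein {disorder_mask.protein_id!r}: disorder mask length {n} != "
            f"DBR mask length {len(dbr_mask)}"
        )
    pct_disordered = 100.0 * float(np.count_nonzero(disorder_mask.flags)) / n
    windows = long_windows(disorder_mask, ldw_min)
    in_ldw = sum(e - s for s, e in windows)
    n_dbr: int | None = None
    pct_dbr: float | None = None
    if dbr_mask is not None:
        dbr_regions = [
            (s, e) for s, e in _true_runs(dbr_mask.flags) if e - s >= dbr_min_len
        ]
        n_dbr = len(dbr_regions)
        pct_dbr = 100.0 * sum(e - s for s, e in dbr_regions) / n
    return DisorderMetrics(
        protein_id=disorder_mask.protein_id,
        length=n,
        pct_disordered=pct_disordered,
        n_ldw=len(windows),
        pct_in_ldw=100.0 * in_ldw / n,
        is_disordered_protein=pct_disordered >= disordered_protein_cutoff,
        n_dbr=n_dbr,
        pct_dbr_residues=pct_dbr,
    )


def metrics_table(
    profiles: Mapping[str, DisorderProfile],
    dbr_profiles: Mapping[str, DisorderProfile] | None = None,
    threshold: float = 0.5,
    dbr_threshold: float = 0.5,
    ldw_min: int = DEFAULT_LDW_MIN,
    disordered_protein_cutoff: float = DEFAULT_DISORDERED_CUTOFF,
    dbr_min_len: int = DEFAULT_DBR_MIN_LEN,
) -> dict[str, DisorderMetrics]:
    """Binarize and summarize a whole proteome's score tracks at once."""
    out: dict[str, DisorderMetrics] = {}
    for pid, profile in profiles.items():
        mask = binarize(profile, threshold)
        dbr_mask = None
        if dbr_profiles is not None and pid in dbr_profiles:
            dbr_mask = binarize(dbr_profiles[pid], dbr_threshold)
        out[pid] = compute_metrics(
            mask,
            dbr_mask,
            ldw_min=ldw_min,
            disordered_protein_cutoff=disordered_protein_cutoff,
            dbr_min_len=dbr_min_len,
        )
    return out


def builtin_predictor(sequence: str, window: int = 51) -> DisorderProfile:
    """Charge/hydropathy composition predictor (pipeline fallback).

    For each residue a foldability index is computed over a centered window::

        f = 2.785 * <H> - |<R>| - 1.151

    where ``<H>`` is the mean Kyte–Doolittle hydropathy rescaled to [0, 1] via
    ``(KD + 4.5) / 9`` and ``<R>`` the mean net charge (K, R = +1; D, E = -1).
    Windows shrink at the termini instead of padding.  Negative foldability
    (charged, non-hydrophobic stretches) indicates disorder, so the reported
    score is a logistic squash of ``-f``: f < 0 maps above 0.5.

    This is a physics-flavoured baseline, not a trained predictor; it exists
    so the pipeline and its tests run with no external predictor output.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and positive, got {window}")
    seq = sequence.upper()
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise DataError(f"nonstandard residues for builtin predictor: {sorted(bad)}")
    hydro = np.array([(KYTE_DOOLITTLE[ch] + 4.5) / 9.0 for ch in seq])
    charge = np.array([RESIDUE_CHARGE.get(ch, 0.0) for ch in seq])
    mean_h = _windowed_mean(hydro, window)
    mean_r = _windowed_mean(charge, window)
    fold = 2.785 * mean_h - np.abs(mean_r) - 1.151
    return DisorderProfile(
        protein_id="", predictor_name="builtin", scores=expit(-fold)
    )


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with truncated (not padded) terminal windows."""
    n = values.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_proteome(
    records: Iterable, window: int = 51
) -> dict[str, DisorderProfile]:
    """Run :func:`builtin_predictor` over protein records."""
    profiles: dict[str, DisorderProfile] = {}
    for rec in records:
        profile = builtin_predictor(rec.sequence, window)
        profile.protein_id = rec.protein_id
        profiles[rec.protein_id] = profile
    return profiles


def bin_fractions(
    metrics: Iterable[DisorderMetrics],
    field: str = "pct_disordered",
    edges: Sequence[float] = BIN_EDGES_FINE,
) -> pd.DataFrame:
    """Histogram a percentage metric over proteins.

    Bins are half-open ``[a, b)`` with the last bin closed, so a value of 100
    lands in the final bin.  Returns columns ``bin_left``, ``bin_right``,
    ``count``, ``fraction``.
    """
    edges_arr = np.asarray(list(edges), dtype=float)
    if edges_arr.size < 2 or np.any(np.diff(edges_arr) <= 0):
        raise ConfigError("bin edges must be strictly ascending with >= 2 values")
    if edges_arr[0] > 0 or edges_arr[-1] < 100:
        raise ConfigError("bin edges must cover [0, 100]")
    values = []
    for m in metrics:
        value = getattr(m, field)
        if value is None:
            raise DataError(f"metric field {field!r} missing for {m.protein_id!r}")
        values.append(float(value))
    counts, _ = np.histogram(np.array(values), bins=edges_arr)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges_arr[:-1],
            "bin_right": edges_arr[1:],
            "count": counts,
            "fraction": counts / total if total else np.zeros_like(counts, float),
        }
    )
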