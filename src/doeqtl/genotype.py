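"""Founder diplotype state space, dosage collapse, and marker-map handling.

A Diversity Outbred (DO) genome is a mosaic of haplotypes from eight inbred
founder strains.  At every marker a sample carries an unordered pair of
founder origins (a *diplotype*), giving 36 possible states: 8 homozygous and
28 heterozygous.  Genotype reconstruction upstream of this package emits a
probability distribution over those 36 states per (sample, marker); the
additive association model downstream works on the expected founder allele
count (the *haplotype dosage*, in [0, 2]) obtained by collapsing the
diplotype simplex.

State order is fixed here and serialized into file headers: the 8 homozygous
states in founder order A..H, followed by the 28 heterozygous pairs in
lexicographic order (AB, AC, ..., AH, BC, ..., GH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FOUNDER_LABELS",
    "FOUNDER_CODES",
    "FounderPanel",
    "enumerate_diplotype_states",
    "diplotype_state_index",
    "collapse_matrix",
    "collapse_to_dosage",
    "interpolate_missing",
    "validate_marker_map",
    "read_marker_map",
    "write_marker_map",
    "read_diplotype_probs",
    "write_diplotype_probs",
    "write_dosages",
]

#: The eight DO founder strains, in canonical A..H order.
FOUNDER_LABELS: tuple[str, ...] = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HILtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

FOUNDER_CODES: str = "ABCDEFGH"

N_FOUNDERS = 8
N_STATES = 36

_SIMPLEX_TOL = 1e-4


@dataclass(frozen=True)
class FounderPanel:
    """The ordered panel of eight founder strains with their letter codes."""

    labels: tuple[str, ...] = FOUNDER_LABELS
    codes: str = FOUNDER_CODES

    def __post_init__(self) -> None:
        if len(self.labels) != N_FOUNDERS:
            raise ValueError(f"founder panel must have exactly 8 strains, got {len(self.labels)}")
        if len(self.codes) != N_FOUNDERS or len(set(self.codes)) != N_FOUNDERS:
            raise ValueError("founder codes must be 8 distinct letters")

    def code_of(self, label: str) -> str:
        return self.codes[self.labels.index(label)]

    def label_of(self, code: str) -> str:
        return self.labels[self.codes.index(code)]


def enumerate_diplotype_states() -> list[str]:
    """Return the 36 diplotype state codes in canonical order.

    The 8 homozygous states ("AA".."HH") come first, then the 28 unordered
    heterozygous pairs in lexicographic order ("AB", "AC", ..., "GH").
    """
    homo = [c + c for c in FOUNDER_CODES]
    het = [
        FOUNDER_CODES[i] + FOUNDER_CODES[j]
        for i in range(N_FOUNDERS)
        for j in range(i + 1, N_FOUNDERS)
    ]
    return homo + het


_STATES = enumerate_diplotype_states()
_STATE_INDEX = {s: i for i, s in enumerate(_STATES)}


def diplotype_state_index(founder_a: int, founder_b: int) -> int:
    """Canonical state index for the unordered founder pair (a, b)."""
    i, j = sorted((founder_a, founder_b))
    if not (0 <= i <= j < N_FOUNDERS):
        raise ValueError(f"founder indices out of range: {(founder_a, founder_b)}")
    code = FOUNDER_CODES[i] + FOUNDER_CODES[j]
    return _STATE_INDEX[code]


def collapse_matrix() -> np.ndarray:
    """The fixed (36, 8) matrix K with dosage = probs @ K.

    A homozygous state ff contributes 2 to founder f; a heterozygous state fg
    contributes 1 to each of f and g.
    """
    K = np.zeros((N_STATES, N_FOUNDERS))
    for s, code in enumerate(_STATES):
        i = FOUNDER_CODES.index(code[0])
        j = FOUNDER_CODES.index(code[1])
        K[s, i] += 1.0
        K[s, j] += 1.0
    return K


_K = collapse_matrix()


def _check_simplex(probs: np.ndarray) -> None:
    if probs.shape[-1] != N_STATES:
        raise ValueError(f"last axis must have {N_STATES} diplotype states, got {probs.shape[-1]}")
    if np.any(probs < 0):
        raise ValueError("diplotype probabilities must be nonnegative")
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
        bad = np.abs(sums - 1.0).max()
        raise ValueError(f"diplotype probabilities must sum to 1 per (sample, marker); max deviation {bad:.3g}")


def collapse_to_dosage(probs: np.ndarray) -> np.ndarray:
    """Collapse diplotype probabilities to expected founder allele dosages.

    dosage_f = 2 * P(ff) + sum_{g != f} P(fg); every (sample, marker) slice of
    the result sums to 2.

    Parameters
    ----------
    probs
        Array (..., 36) of diplotype state probabilities in canonical order.

    Returns
    -------
    Array (..., 8) of founder dosages in [0, 2].
    """
    probs = np.asarray(probs, dtype=float)
    _check_simplex(probs)
    return probs @ _K


def validate_marker_map(mmap: pd.DataFrame) -> pd.DataFrame:
    """Check the marker map contract: required columns, per-chromosome sorted positions."""
    required = {"marker_id", "chrom", "pos_bp"}
    missing = required - set(mmap.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    if mmap["marker_id"].duplicated().any():
        raise ValueError("marker ids must be unique")
    for chrom, sub in mmap.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions must be strictly increasing within chromosome {chrom}")
    if "measured" not in mmap.columns:
        mmap = mmap.assign(measured=True)
    return mmap


def interpolate_missing(probs: np.ndarray, mmap: pd.DataFrame) -> np.ndarray:
    """Fill probability slices at unmeasured markers from the nearest measured marker.

    Unmeasured markers (``measured == False`` in the map) receive a copy of the
    probability slice from the nearest measured marker on the same chromosome,
    by base-pair distance.  On an exact distance tie the upstream (lower
    position) neighbor wins.  Measured markers are returned bit-for-bit
    unchanged.
    """
    mmap = validate_marker_map(mmap)
    probs = np.asarray(probs, dtype=float)
    if probs.shape[1] != len(mmap):
        raise ValueError(f"probability tensor has {probs.shape[1]} markers but map has {len(mmap)}")
    measured = mmap["measured"].to_numpy(dtype=bool)
    if measured.all():
        return probs.copy()

    out = probs.copy()
    pos = mmap["pos_bp"].to_numpy(dtype=float)
    chroms = mmap["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        meas_idx = idx[measured[idx]]
        if len(meas_idx) == 0:
            raise ValueError(f"chromosome {chrom} has no measured marker to interpolate from")
        miss_idx = idx[~measured[idx]]
        if len(miss_idx) == 0:
            continue
        mpos = pos[meas_idx]
        for m in miss_idx:
            d = np.abs(mpos - pos[m])
            # argmin returns the first minimum; measured positions are sorted
            # ascending, so ties resolve to the lower genomic position.
            src = meas_idx[int(np.argmin(d))]
            out[:, m, :] = probs[:, src, :]
    return out


# ---------------------------------------------------------------------------
# Text I/O: wide TSVs keyed by canonical state / founder codes.
# ---------------------------------------------------------------------------

def write_marker_map(mmap: pd.DataFrame, path: str | Path) -> None:
    validate_marker_map(mmap).to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    mmap = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "measured" in mmap.columns:
        mmap["measured"] = mmap["measured"].astype(bool)
    return validate_marker_map(mmap)


def write_diplotype_probs(
    probs: np.ndarray, samples: list[str], mmap: pd.DataFrame, path: str | Path
) -> None:
    """One row per (sample, marker); 36 probability columns named by state code."""
    n_s, n_m, _ = probs.shape
    rows = pd.DataFrame(
        probs.reshape(n_s * n_m, N_STATES), columns=_STATES
    )
    rows.insert(0, "marker_id", np.tile(mmap["marker_id"].to_numpy(), n_s))
    rows.insert(0, "sample_id", np.repeat(samples, n_m))
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_diplotype_probs(path: str | Path, mmap: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    samples = list(pd.unique(df["sample_id"]))
    n_m = len(mmap)
    marker_order = {m: i for i, m in enumerate(mmap["marker_id"])}
    probs = np.zeros((len(samples), n_m, N_STATES))
    sample_index = {s: i for i, s in enumerate(samples)}
    si = df["sample_id"].map(sample_index).to_numpy()
    mi = df["marker_id"].map(marker_order)
    if mi.isna().any():
        raise ValueError("genotype file contains markers absent from the map")
    probs[si, mi.to_numpy(dtype=int)] = df[_STATES].to_numpy()
    return probs, samples


def write_dosages(
    dosages: np.ndarray, samples: list[str], mmap: pd.DataFrame, path: str | Path
) -> None:
    """Dosage export: one row per (sample, marker) with 8 founder columns A..H."""
    n_s, n_m, _ = dosages.shape
    cols = [f"dosage_{c}" for c in FOUNDER_CODES]
    rows = pd.DataFrame(dosages.reshape(n_s * n_m, N_FOUNDERS), columns=cols)
    rows.insert(0, "marker_id", np.tile(mmap["marker_id"].to_numpy(), n_s))
    rows.insert(0, "sample_id", np.repeat(samples, n_m))
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
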