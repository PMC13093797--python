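"""Secondary-peak base calling and triplicate consensus for Sanger traces.

Works on tabular per-position peak heights (columns A, C, G, T), not raw
electropherogram signal.  A position's primary base is the tallest peak;
a secondary peak is accepted — yielding the two-base IUPAC ambiguity
code — when its height strictly exceeds a fraction of the primary peak:
50% in ordinary sequence, 30% inside repetitive regions.  Specimens whose
traces are bimodal are sequenced in triplicate and the per-position
majority (>= 2 of 3) call is kept; three-way disagreements become ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakTrace",
    "CalledSequence",
    "call_bases",
    "replicate_consensus",
    "homopolymer_mask",
    "read_peak_table",
]

_ORDER = "ACGT"
# two-base IUPAC codes, keyed by the sorted base pair
_IUPAC2 = {
    ("A", "C"): "M",
    ("A", "G"): "R",
    ("A", "T"): "W",
    ("C", "G"): "S",
    ("C", "T"): "Y",
    ("G", "T"): "K",
}


@dataclass
class PeakTrace:
    """Per-position peak heights (L x 4, order A,C,G,T) plus a repeat mask."""

    heights: np.ndarray
    repeat_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[1] != 4:
            raise ValueError("heights must be an L x 4 array (A, C, G, T)")
        if (self.heights < 0).any():
            raise ValueError("peak heights must be nonnegative")
        if self.repeat_mask is not None:
            self.repeat_mask = np.asarray(self.repeat_mask, dtype=bool)
            if self.repeat_mask.shape != (len(self.heights),):
                raise ValueError("repeat_mask length must equal trace length")

    def __len__(self) -> int:
        return len(self.heights)


@dataclass
class CalledSequence:
    """Called bases (IUPAC) with the positions where a secondary peak won."""

    bases: str
    ambiguity_flags: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i in self.ambiguity_flags:
            if self.bases[i] in _ORDER or self.bases[i] == "N":
                raise ValueError(
                    f"flagged position {i} does not hold a degenerate code"
                )

    def __len__(self) -> int:
        return len(self.bases)


def homopolymer_mask(primary: str, min_run: int = 4) -> np.ndarray:
    """Mark positions inside homopolymer runs of length >= ``min_run``.

    This is the default notion of "repetitive region" when the caller
    supplies none; it is deliberately conservative and user-overridable.
    """
    mask = np.zeros(len(primary), dtype=bool)
    i = 0
    while i < len(primary):
        j = i
        while j < len(primary) and primary[j] == primary[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def call_bases(
    trace: PeakTrace,
    nonrepeat_threshold: float = 0.50,
    repeat_threshold: float = 0.30,
) -> CalledSequence:
    """Call bases, accepting secondary peaks above the applicable ratio.

    The secondary/primary ratio must *strictly exceed* the threshold for
    an ambiguity code to be emitted.  Argmax ties are broken by the fixed
    base order A < C < G < T.  When the trace carries no repeat mask, one
    is derived from homopolymer runs (length >= 4) of the primary-base
    sequence.
    """
    for name, thr in (
        ("nonrepeat_threshold", nonrepeat_threshold),
        ("repeat_threshold", repeat_threshold),
    ):
        if not 0.0 < thr < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {thr}")
    h = trace.heights
    zero_rows = np.where(h.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(
            f"position {int(zero_rows[0])} has no positive peak height"
        )
    # stable argmax with A<C<G<T tie-break: argmax returns the first max
    primary_idx = h.argmax(axis=1)
    primary = "".join(_ORDER[i] for i in primary_idx)

    mask = trace.repeat_mask
    if mask is None:
        mask = homopolymer_mask(primary)

    masked = h.copy()
    masked[np.arange(len(h)), primary_idx] = -np.inf
    secondary_idx = masked.argmax(axis=1)
    primary_h = h[np.arange(len(h)), primary_idx]
    secondary_h = h[np.arange(len(h)), secondary_idx]
    ratio = secondary_h / primary_h
    thr = np.where(mask, repeat_threshold, nonrepeat_threshold)
    accept = ratio > thr

    bases = []
    flags = []
    for i in range(len(h)):
        if accept[i]:
            pair = tuple(sorted((_ORDER[primary_idx[i]], _ORDER[secondary_idx[i]])))
            bases.append(_IUPAC2[pair])
            flags.append(i)
        else:
            bases.append(_ORDER[primary_idx[i]])
    return CalledSequence(bases="".join(bases), ambiguity_flags=flags)


def replicate_consensus(
    calls: list[CalledSequence] | tuple[CalledSequence, ...],
) -> tuple[CalledSequence, list[int]]:
    """Per-position majority consensus of three replicate calls.

    A base supported by at least two of the three replicates is kept;
    positions where all three disagree become ``N`` and are returned in
    the disagreement report.
    """
    if len(calls) != 3:
        raise ValueError("replicate consensus expects exactly three calls")
    lengths = {len(c) for c in calls}
    if len(lengths) != 1:
        raise ValueError(f"replicate calls differ in length: {sorted(lengths)}")
    (length,) = lengths
    bases = []
    disagreements = []
    flags = []
    flagged = [set(c.ambiguity_flags) for c in calls]
    for i in range(length):
        votes = [c.bases[i] for c in calls]
        winner = None
        for b in votes:
            if votes.count(b) >= 2:
                winner = b
                break
        if winner is None:
            bases.append("N")
            disagreements.append(i)
        else:
            bases.append(winner)
            if winner not in _ORDER and winner != "N":
                flags.append(i)
    return CalledSequence(bases="".join(bases), ambiguity_flags=flags), disagreements


def read_peak_table(path: str | Path) -> PeakTrace:
    """Read a peak-height CSV (position, A, C, G, T[, repeat_flag])."""
    df = pd.read_csv(path)
    required = ["A", "C", "G", "T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} lacks columns: {missing}")
    if "position" in df.columns:
        df = df.sort_values("position")
    mask = (
        df["repeat_flag"].astype(bool).to_numpy()
        if "repeat_flag" in df.columns
        else None
    )
    return PeakTrace(heights=df[required].to_numpy(float), repeat_mask=mask)
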