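"""Haplotype collapsing and per-island genetic diversity statistics.

Specimens with identical sequences over their comparable (unambiguous,
ungapped) positions are collapsed into haplotypes.  Per-island statistics
follow the conventions of standard population-genetic software:

* haplotype richness ``H`` — number of distinct haplotypes in the sample;
* haplotype diversity ``Hd`` — Nei's unbiased estimator
  ``Hd = n (1 - sum p_i^2) / (n - 1)``, undefined (NaN) when ``H == 1``;
* nucleotide diversity ``Pi`` — mean pairwise p-distance over all
  specimen pairs, with pairwise deletion of gap/ambiguous sites.

Distances are uncorrected p-distances: the proportion of differing sites
among positions where both sequences carry an unambiguous A/C/G/T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeSet",
    "collapse_haplotypes",
    "p_distance",
    "distance_matrix",
    "distance_summary",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_table",
]

_BASES = b"ACGT"


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8; comparable positions are A/C/G/T only."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok_a = np.isin(a, np.frombuffer(_BASES, dtype=np.uint8))
    ok_b = np.isin(b, np.frombuffer(_BASES, dtype=np.uint8))
    return ok_a & ok_b


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Positions where either sequence carries a gap or a non-ACGT symbol are
    excluded from both numerator and denominator.

    Raises
    ------
    ValueError
        If the sequences differ in length or share no comparable site.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)})"
        )
    ea, eb = _encode(a), _encode(b)
    mask = _comparable(ea, eb)
    n_comp = int(mask.sum())
    if n_comp == 0:
        raise ValueError("no comparable sites between sequences")
    return float(np.count_nonzero(ea[mask] != eb[mask]) / n_comp)


def _n_diffs(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    mask = _comparable(a, b)
    return int(np.count_nonzero(a[mask] != b[mask])), int(mask.sum())


@dataclass
class HaplotypeSet:
    """Distinct haplotypes plus their haplotype-by-island occurrence counts.

    Attributes
    ----------
    sequences
        Mapping of haplotype id (``H01``, ``H02``, ... in first-occurrence
        order) to the representative aligned sequence.
    occurrence
        Integer DataFrame indexed by haplotype id with one column per
        island; entries are specimen counts.
    specimen_map
        Mapping of specimen id to its assigned haplotype id.
    """

    sequences: dict[str, str]
    occurrence: pd.DataFrame
    specimen_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("haplotype sequences are not aligned (ragged)")
        if (self.occurrence.to_numpy() < 0).any():
            raise ValueError("negative occurrence counts")

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def islands(self) -> list[str]:
        return list(self.occurrence.columns)

    def counts_for(self, island: str) -> pd.Series:
        col = self.occurrence[island]
        return col[col > 0]

    def endemism_fraction(self) -> float:
        """Fraction of haplotypes observed on exactly one island."""
        present = (self.occurrence > 0).sum(axis=1)
        return float((present == 1).mean())


def collapse_haplotypes(
    sequences: Mapping[str, str],
    island_map: Mapping[str, str],
    prefix: str = "H",
) -> HaplotypeSet:
    """Collapse aligned specimen sequences into haplotypes.

    A specimen joins the earliest haplotype from which it shows zero
    differences over comparable positions (gap/ambiguity-only differences
    are therefore merged into the earlier haplotype); otherwise it founds a
    new haplotype.  Ids are assigned in first-occurrence order and
    zero-padded (``H01`` ... or ``H001`` ... depending on how many arise).

    Parameters
    ----------
    sequences
        Specimen id -> aligned sequence.
    island_map
        Specimen id -> island id; every specimen must be mapped.
    """
    if not sequences:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: sequences differ in length")
    missing = [s for s in sequences if s not in island_map]
    if missing:
        raise ValueError(f"specimens without island assignment: {missing[:5]}")

    reps: list[np.ndarray] = []
    rep_seqs: list[str] = []
    assign: dict[str, int] = {}
    # exact-match fast path: identical strings share a haplotype trivially
    exact: dict[str, int] = {}
    for spec_id, seq in sequences.items():
        key = seq.upper()
        if key in exact:
            assign[spec_id] = exact[key]
            continue
        enc = _encode(seq)
        hit = None
        for j, rep in enumerate(reps):
            mask = _comparable(enc, rep)
            if mask.any() and not np.count_nonzero(enc[mask] != rep[mask]):
                hit = j
                break
        if hit is None:
            hit = len(reps)
            reps.append(enc)
            rep_seqs.append(seq.upper())
        exact[key] = hit
        assign[spec_id] = hit

    width = max(2, len(str(len(reps))))
    hap_ids = [f"{prefix}{j + 1:0{width}d}" for j in range(len(reps))]
    islands = sorted(set(island_map[s] for s in sequences))
    occ = pd.DataFrame(0, index=hap_ids, columns=islands, dtype=int)
    specimen_map = {}
    for spec_id in sequences:
        hap = hap_ids[assign[spec_id]]
        occ.loc[hap, island_map[spec_id]] += 1
        specimen_map[spec_id] = hap
    return HaplotypeSet(
        sequences=dict(zip(hap_ids, rep_seqs)),
        occurrence=occ,
        specimen_map=specimen_map,
    )


def distance_matrix(haps: HaplotypeSet | Mapping[str, str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise p-distances between haplotypes."""
    seqs = haps.sequences if isinstance(haps, HaplotypeSet) else dict(haps)
    ids = list(seqs)
    enc = [_encode(seqs[i]) for i in ids]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = _comparable(enc[i], enc[j])
            n_comp = int(mask.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]} and {ids[j]}"
                )
            d = np.count_nonzero(enc[i][mask] != enc[j][mask]) / n_comp
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def distance_summary(dmat: pd.DataFrame) -> pd.DataFrame:
    """Per-haplotype maximum and minimum p-distance to any other haplotype."""
    if dmat.shape[0] < 2:
        raise ValueError("distance summary requires at least 2 haplotypes")
    vals = dmat.to_numpy().astype(float).copy()
    np.fill_diagonal(vals, np.nan)
    return pd.DataFrame(
        {
            "Max": np.nanmax(vals, axis=1),
            "Min": np.nanmin(vals, axis=1),
        },
        index=dmat.index,
    )


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Nei's unbiased haplotype diversity ``n (1 - sum p_i^2) / (n - 1)``.

    Returns NaN (the "undefined" sentinel) when only one haplotype is
    present; raises for samples of fewer than two specimens.
    """
    c = np.asarray(list(counts), dtype=float)
    if (c <= 0).any():
        raise ValueError("haplotype counts must be positive")
    n = c.sum()
    if n < 2:
        raise ValueError(f"haplotype diversity needs n >= 2 specimens, got {n:g}")
    if len(c) == 1:
        return float("nan")
    p = c / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1.0))


def nucleotide_diversity(sequences: Sequence[str]) -> float:
    """Mean pairwise p-distance over all specimen pairs (pairwise deletion)."""
    n = len(sequences)
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 specimens")
    enc = [_encode(s) for s in sequences]
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        mask = _comparable(enc[i], enc[j])
        n_comp = int(mask.sum())
        if n_comp == 0:
            raise ValueError(f"no comparable sites between specimens {i} and {j}")
        total += np.count_nonzero(enc[i][mask] != enc[j][mask]) / n_comp
    return float(total / (n * (n - 1) / 2))


def nucleotide_diversity_from_counts(
    counts: Mapping[str, int], dmat: pd.DataFrame
) -> float:
    """Pi from haplotype counts and a haplotype distance matrix.

    Equivalent to the specimen-pair form on gap-free data:
    ``sum_{i<j} x_i x_j d_ij / C(n, 2)`` with ``x`` the haplotype counts.
    """
    ids = [h for h, c in counts.items() if c > 0]
    x = np.array([counts[h] for h in ids], dtype=float)
    n = x.sum()
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 specimens")
    if len(ids) == 1:
        return 0.0
    d = dmat.loc[ids, ids].to_numpy()
    num = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            num += x[i] * x[j] * d[i, j]
    return float(num / (n * (n - 1) / 2))


def diversity_table(
    haps: HaplotypeSet,
    sequences: Mapping[str, str] | None = None,
    island_map: Mapping[str, str] | None = None,
    pd_per_island: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-island diversity table with columns Sn, H, Hd, Pi, PD.

    ``Pi`` is computed from the specimen alignment when ``sequences`` and
    ``island_map`` are given; otherwise from the haplotype distance matrix
    and occurrence counts (exact on gap-free data).  Islands with a single
    specimen report ``H=1``, ``Hd`` undefined (NaN) and ``Pi=0``; islands
    with zero specimens are excluded.
    """
    dmat = None
    if sequences is None and len(haps.sequences) > 1:
        dmat = distance_matrix(haps)
    rows = {}
    for island in haps.islands:
        col = haps.occurrence[island]
        sn = int(col.sum())
        if sn == 0:
            continue
        h = int((col > 0).sum())
        if sn == 1:
            hd, pi = float("nan"), 0.0
        else:
            hd = haplotype_diversity(col[col > 0])
            if sequences is not None and island_map is not None:
                island_seqs = [
                    sequences[s] for s in sequences if island_map[s] == island
                ]
                pi = nucleotide_diversity(island_seqs)
            elif h == 1:
                pi = 0.0
            elif dmat is not None:
                pi = nucleotide_diversity_from_counts(col.to_dict(), dmat)
            else:
                # occurrence-only input: no sequences, Pi unavailable
                pi = float("nan")
        row = {"Sn": sn, "H": h, "Hd": hd, "Pi": pi}
        if pd_per_island is not None:
            row["PD"] = float(pd_per_island[island])
        rows[island] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "Island"
    return out
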