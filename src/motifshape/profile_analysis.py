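"""Shape-profile matrices: clustering, averaging, comparison, testing.

A dataset of aligned binding sites becomes one matrix per structural
feature (rows = sequences, columns = positions in core coordinates).
On top of these the module provides the quantitative analyses a motif
comparison needs:

* row clustering for heat-map display (agglomerative, Euclidean
  distance, capped at 3000 rows);
* per-position averaging;
* comparison of two average profiles under a user-chosen alignment
  offset, reported as Pearson correlation (PCC) and Euclidean distance
  (ED);
* per-position two-sample Kolmogorov-Smirnov tests between two
  datasets, flagging positions with significantly different feature
  distributions;
* dendrograms over many factors from EDs between average profiles.

Base-pair features (MGW, ProT) use integer core coordinates; step
features (Roll, HelT) use midpoint coordinates (j + 0.5) so all tracks
share one axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp, pearsonr

from .shape_engine import (
    BP_FEATURES,
    FEATURES,
    PentamerTable,
    predict_shape,
    symmetrize_profile,
)
from .tfbs_assembly import TFBSDataset

__all__ = [
    "ProfileMatrix",
    "ComparisonResult",
    "DifferentialResult",
    "dataset_profiles",
    "average_profile",
    "cluster_rows",
    "compare_profiles",
    "ks_differential",
    "shape_dendrogram",
    "aggregate_linkage",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_long_tsv",
]

logger = logging.getLogger(__name__)

#: Heat-map colour semantics emitted alongside matrices (rendering is
#: a display concern; red = narrow minor groove, blue = wide).
COLOUR_SCALE = {
    "MGW": {"low": "red", "mid": "white", "high": "blue"},
    "ProT": {"low": "red", "mid": "white", "high": "blue"},
    "Roll": {"low": "red", "mid": "white", "high": "blue"},
    "HelT": {"low": "red", "mid": "white", "high": "blue"},
}


@dataclass
class ProfileMatrix:
    """Per-sequence feature values over aligned positions.

    ``values`` is (n_sequences, n_positions) with NaN for undefined
    cells; ``positions`` are core-start-relative coordinates (half-
    integral for step features); ``row_order`` is a permutation set by
    clustering (defaults to input order).
    """

    feature: str
    seq_ids: list[str]
    positions: np.ndarray
    values: np.ndarray
    row_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.shape != (len(self.seq_ids), len(self.positions)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.seq_ids)} ids x {len(self.positions)} positions"
            )
        if self.row_order is None:
            self.row_order = np.arange(len(self.seq_ids))

    @property
    def n_rows(self) -> int:
        return len(self.seq_ids)


def dataset_profiles(
    dataset: TFBSDataset,
    table: PentamerTable,
    symmetrize_centre: float | None = None,
) -> dict[str, ProfileMatrix]:
    """Predict shape for every sequence; return one matrix per feature.

    ``symmetrize_centre`` (core coordinates) mirror-averages each row
    about that position — appropriate when the motif is palindromic.
    Rows keep the dataset's input order; clustering is a separate step.
    """
    if not len(dataset):
        raise ValueError("empty dataset")
    origin = -dataset.flank_width
    L = dataset.total_length
    bp_pos = np.arange(L, dtype=float) + origin
    step_pos = np.arange(L - 1, dtype=float) + origin + 0.5
    tracks: dict[str, list[np.ndarray]] = {f: [] for f in FEATURES}
    for sid, seq in zip(dataset.seq_ids, dataset.sequences):
        try:
            prof = predict_shape(seq, table)
        except ValueError as exc:
            raise ValueError(f"shape prediction failed for {sid!r}: {exc}") from exc
        if symmetrize_centre is not None:
            prof = symmetrize_profile(prof, symmetrize_centre - origin)
        for f in FEATURES:
            tracks[f].append(prof.track(f))
    out = {}
    for f in FEATURES:
        pos = bp_pos if f in BP_FEATURES else step_pos
        out[f] = ProfileMatrix(
            feature=f,
            seq_ids=list(dataset.seq_ids),
            positions=pos,
            values=np.vstack(tracks[f]),
        )
    return out


def average_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column means over defined cells; all-missing columns stay NaN."""
    if matrix.n_rows == 0:
        raise ValueError("empty matrix")
    mask = ~np.isnan(matrix.values)
    count = mask.sum(axis=0)
    total = np.where(mask, matrix.values, 0.0).sum(axis=0)
    out = np.full(matrix.values.shape[1], np.nan)
    present = count > 0
    out[present] = total[present] / count[present]
    return out


def _pairwise_complete_ed(values: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows, NaN-aware.

    Distances use only positions defined in both rows, rescaled by
    sqrt(n_total / n_complete) so sparser overlaps stay on the same
    scale as complete rows.
    """
    n, m = values.shape
    mask = ~np.isnan(values)
    filled = np.where(mask, values, 0.0)
    sq = filled**2
    # sum over shared positions of (x - y)^2
    shared = mask.astype(float) @ mask.T.astype(float)
    cross = filled @ filled.T
    sumx = sq @ mask.T.astype(float)
    d2 = sumx + sumx.T - 2 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (m / shared)
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    return np.sqrt(d2)


def aggregate_linkage(dist: np.ndarray, method: str = "average") -> np.ndarray:
    """Deterministic agglomerative clustering from a distance matrix.

    Plain Lance-Williams agglomeration over the full matrix: at each
    step merge the active pair at minimal distance, ties broken by the
    smallest (older-cluster, newer-cluster) id pair.  Returns a linkage
    matrix in the standard (left, right, height, size) row layout.
    """
    if method not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = dist
    np.fill_diagonal(big, np.inf)
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = big[np.ix_(active, active)]
        iu = np.triu_indices(len(active), k=1)
        flat = sub[iu]
        k = int(np.argmin(flat))  # argmin returns the first minimum: tie-break
        i, j = active[iu[0][k]], active[iu[1][k]]
        d = flat[k]
        new = n + step
        for m_id in active:
            if m_id in (i, j):
                continue
            if method == "single":
                dm = min(big[i, m_id], big[j, m_id])
            elif method == "complete":
                dm = max(big[i, m_id], big[j, m_id])
            else:
                dm = (size[i] * big[i, m_id] + size[j] * big[j, m_id]) / (
                    size[i] + size[j]
                )
            big[new, m_id] = big[m_id, new] = dm
        size[new] = size[i] + size[j]
        Z[step] = (min(i, j), max(i, j), d, size[new])
        active.remove(i)
        active.remove(j)
        active.append(new)
    return Z


def cluster_rows(
    matrix: ProfileMatrix,
    max_rows: int = 3000,
    linkage: str = "average",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Order rows for heat-map display by agglomerative clustering.

    Returns ``(row_order, Z)``.  Matrices larger than ``max_rows`` are
    returned in input order with no tree (Z None), mirroring the display
    convention that only sets of <= 3000 sequences are clustered.
    All-missing rows are placed after the clustered rows, in input
    order, with a warning.
    """
    n = matrix.n_rows
    if n > max_rows:
        logger.info("matrix has %d rows > cap %d; returning input order", n, max_rows)
        return np.arange(n), None
    defined = ~np.all(np.isnan(matrix.values), axis=1)
    excluded = np.nonzero(~defined)[0]
    if excluded.size:
        logger.warning("%d all-missing row(s) excluded from clustering", excluded.size)
    keep = np.nonzero(defined)[0]
    if keep.size < 2:
        return np.arange(n), None
    dist = _pairwise_complete_ed(matrix.values[keep])
    if keep.size <= 64:
        Z = aggregate_linkage(dist, method=linkage)
    else:
        # same linkage criterion via the C implementation; tie handling
        # may differ but distances on real-valued profiles are tie-free
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(Z)
    row_order = np.concatenate([keep[order], excluded])
    matrix.row_order = row_order
    return row_order, Z


@dataclass
class ComparisonResult:
    """PCC/ED comparison of two average profiles under one alignment."""

    alignment_offset: int
    per_feature: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "alignment_offset": self.alignment_offset,
            "features": self.per_feature,
        }


def compare_profiles(
    avg1: Mapping[str, np.ndarray],
    avg2: Mapping[str, np.ndarray],
    offset: int = 0,
) -> ComparisonResult:
    """Compare two per-feature average profiles shifted by ``offset``.

    ``avg2`` position p aligns with ``avg1`` position p + offset.  PCC
    and ED are computed per feature over the overlapping positions
    defined in both; fewer than 2 shared positions is an alignment
    error.
    """
    per_feature: dict[str, dict[str, float]] = {}
    for f in avg1:
        if f not in avg2:
            continue
        v1 = np.asarray(avg1[f], dtype=float)
        v2 = np.asarray(avg2[f], dtype=float)
        lo1 = max(0, offset)
        lo2 = max(0, -offset)
        span = min(len(v1) - lo1, len(v2) - lo2)
        if span < 2:
            raise ValueError(
                f"alignment offset {offset} leaves overlap {max(span, 0)} < 2 "
                f"for feature {f}"
            )
        a = v1[lo1 : lo1 + span]
        b = v2[lo2 : lo2 + span]
        ok = ~(np.isnan(a) | np.isnan(b))
        n = int(ok.sum())
        if n < 2:
            raise ValueError(
                f"fewer than 2 defined shared positions for feature {f} "
                f"at offset {offset}"
            )
        pcc = float(pearsonr(a[ok], b[ok])[0])
        ed = float(np.sqrt(np.sum((a[ok] - b[ok]) ** 2)))
        per_feature[f] = {"pcc": pcc, "ed": ed, "n_positions": n}
    if not per_feature:
        raise ValueError("no shared features to compare")
    return ComparisonResult(alignment_offset=offset, per_feature=per_feature)


@dataclass
class DifferentialResult:
    """Per-position two-sample K-S comparison of two profile matrices.

    ``table`` rows: position, D, p_value, category (``strong`` for
    p < 0.001, ``weak`` for p < 0.05, ``none`` otherwise, ``untested``
    when either group has too few defined values).
    """

    feature: str
    table: pd.DataFrame
    thresholds: tuple[float, float]

    def positions_with(self, category: str) -> list[float]:
        return list(self.table.loc[self.table["category"] == category, "position"])


def ks_differential(
    matrix1: ProfileMatrix,
    matrix2: ProfileMatrix,
    thresholds: tuple[float, float] = (0.001, 0.05),
    min_n: int = 8,
) -> DifferentialResult:
    """Positionwise two-sample Kolmogorov-Smirnov test.

    Shared columns are compared; a position needs at least ``min_n``
    defined values in each group, otherwise it is reported untested.
    P-values are exact for small samples (combined n <= 25) and
    asymptotic otherwise.
    """
    strong, weak = thresholds
    if not (0 < strong < weak < 1):
        raise ValueError(f"thresholds must satisfy 0 < strong < weak < 1: {thresholds}")
    shared = sorted(set(matrix1.positions) & set(matrix2.positions))
    if not shared:
        raise ValueError("matrices share no position columns")
    pos_idx1 = {p: i for i, p in enumerate(matrix1.positions)}
    pos_idx2 = {p: i for i, p in enumerate(matrix2.positions)}
    rows = []
    for p in shared:
        x = matrix1.values[:, pos_idx1[p]]
        y = matrix2.values[:, pos_idx2[p]]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) < min_n or len(y) < min_n:
            rows.append((p, np.nan, np.nan, "untested"))
            continue
        method = "exact" if len(x) + len(y) <= 25 else "asymp"
        res = ks_2samp(x, y, method=method)
        if res.pvalue < strong:
            cat = "strong"
        elif res.pvalue < weak:
            cat = "weak"
        else:
            cat = "none"
        rows.append((p, float(res.statistic), float(res.pvalue), cat))
    table = pd.DataFrame(rows, columns=["position", "D", "p_value", "category"])
    return DifferentialResult(
        feature=matrix1.feature, table=table, thresholds=thresholds
    )


def _newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix to Newick with branch lengths.

    Branch length of a node = parent merge height - own merge height
    (leaves have height 0).
    """
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    children = {}
    for step, (a, b, h, _) in enumerate(Z):
        node = n + step
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{labels[node]}:{bl:.6g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{bl:.6g}"

    root = n + len(Z) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def shape_dendrogram(
    avg_profiles: Mapping[str, np.ndarray],
    linkage: str = "average",
) -> tuple[str, np.ndarray, list[str]]:
    """Dendrogram over factors from EDs between average shape profiles.

    ``avg_profiles`` maps factor name -> pre-aligned mean feature vector
    (commonly MGW).  Factors are sorted by name before clustering so tie
    breaking is deterministic by label.  Returns ``(newick, Z, labels)``.
    """
    labels = sorted(avg_profiles)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles for a dendrogram")
    vecs = []
    lengths = set()
    for name in labels:
        v = np.asarray(avg_profiles[name], dtype=float)
        lengths.add(len(v))
        vecs.append(v)
    if len(lengths) != 1:
        raise ValueError(
            f"profiles must be pre-aligned to equal length, got {sorted(lengths)}"
        )
    values = np.vstack(vecs)
    dist = _pairwise_complete_ed(values)
    Z = aggregate_linkage(dist, method=linkage)
    return _newick(Z, labels), Z, labels


# ---------------------------------------------------------------------------
# Matrix TSV round-trip (repr floats: bit-exact)


def write_matrix_tsv(matrix: ProfileMatrix, path: str | Path) -> None:
    """Write a profile matrix as TSV (row = seq_id, NA for missing)."""
    with Path(path).open("w") as fh:
        fh.write("# feature=%s\n" % matrix.feature)
        header = ["seq_id"] + [_fmt_pos(p) for p in matrix.positions]
        fh.write("\t".join(header) + "\n")
        for sid, row in zip(matrix.seq_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def _fmt_pos(p: float) -> str:
    return str(int(p)) if float(p).is_integer() else repr(float(p))


def read_matrix_tsv(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        feature = "MGW"
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("feature="):
                    feature = tok.split("=", 1)[1]
            header = fh.readline().strip().split("\t")
        else:
            header = first.split("\t")
        positions = np.array([float(h) for h in header[1:]])
        seq_ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            seq_ids.append(parts[0])
            rows.append([np.nan if c == "NA" else float(c) for c in parts[1:]])
    return ProfileMatrix(
        feature=feature,
        seq_ids=seq_ids,
        positions=positions,
        values=np.array(rows, dtype=float),
    )


def write_long_tsv(
    matrices: Mapping[str, ProfileMatrix], path: str | Path
) -> None:
    """Long-format export: ``seq_id  feature  position  value``."""
    with Path(path).open("w") as fh:
        fh.write("seq_id\tfeature\tposition\tvalue\n")
        for f, m in matrices.items():
            for sid, row in zip(m.seq_ids, m.values):
                for p, v in zip(m.positions, row):
                    cell = "NA" if np.isnan(v) else repr(float(v))
                    fh.write(f"{sid}\t{f}\t{_fmt_pos(p)}\t{cell}\n")
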