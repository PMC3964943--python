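"""PWM construction and motif-occurrence scanning with exact p-values.

A position frequency matrix (PFM) is converted to a log-odds position
weight matrix (PWM, base-2) against a 0-order background.  Probe
sequences are scanned on both strands and each window score receives an
exact p-value, P(score >= s) for a random W-mer drawn from the
background, computed by positional convolution of the discretized score
distribution.  Windows with p <= 1e-3 (the conventional cutoff for
calling core binding sites on binding-microarray probes) are reported
as occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .shape_engine import reverse_complement

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "ProbeRecord",
    "ScorePValueMap",
    "build_pwm",
    "score_pvalue_map",
    "scan",
    "barcode",
    "parse_pfm",
    "read_probes",
    "write_probes",
    "write_occurrences",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class ProbeRecord:
    """One microarray probe: identifier, sequence, fluorescence signal."""

    probe_id: str
    sequence: str
    intensity: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"probe {self.probe_id!r} has empty sequence")
        if not np.isfinite(self.intensity):
            raise ValueError(f"probe {self.probe_id!r} has non-finite intensity")


@dataclass(frozen=True)
class MotifOccurrence:
    """A significant motif match on a probe.

    ``offset`` is the 0-based start of the matched window on the probe's
    forward strand regardless of ``strand``; ``score`` is the log-odds
    score in bits and ``p_value`` the background probability of a score
    at least as high.
    """

    probe_id: str
    offset: int
    strand: str
    score: float
    p_value: float


class ScorePValueMap:
    """Exact score -> p-value map on a fixed discretization grid.

    Scores are rounded to ``1/scale`` bit before both the distribution
    convolution and the lookup, so reported p-values are self-consistent
    with the scoring grid.
    """

    def __init__(self, int_scores: np.ndarray, background: np.ndarray, scale: int):
        self.scale = scale
        self.int_scores = int_scores
        lo = int(int_scores.min(axis=0).sum())
        hi = int(int_scores.max(axis=0).sum())
        dist = np.array([1.0])
        for j in range(int_scores.shape[1]):
            col = int_scores[:, j]
            col_lo, col_hi = int(col.min()), int(col.max())
            out = np.zeros(len(dist) + (col_hi - col_lo), dtype=float)
            for b in range(4):
                shift = int(col[b]) - col_lo
                out[shift : shift + len(dist)] += background[b] * dist
            dist = out
        assert len(dist) == hi - lo + 1
        self.min_int = lo
        self.max_int = hi
        #: survival[k] = P(integer score >= lo + k)
        self.survival = dist[::-1].cumsum()[::-1]

    def pvalue(self, score_bits: float | np.ndarray) -> np.ndarray | float:
        """P(score >= s) under the background, on the discretization grid."""
        s = np.rint(np.asarray(score_bits, dtype=float) * self.scale).astype(np.int64)
        idx = np.clip(s - self.min_int, 0, len(self.survival) - 1)
        p = self.survival[idx]
        p = np.where(s < self.min_int, 1.0, p)
        # scores above the achievable maximum cannot be observed; clip to
        # the probability of the maximum so the map stays in (0, 1]
        return p if p.shape else float(p)

    def __call__(self, score_bits):
        return self.pvalue(score_bits)


@dataclass
class MotifModel:
    """PFM plus derived log-odds PWM and background model."""

    pfm: np.ndarray
    pwm: np.ndarray
    width: int
    pseudocount: float
    background: np.ndarray
    _pvalue_map: ScorePValueMap | None = field(default=None, repr=False, compare=False)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[b] for b in self.pwm.argmax(axis=0))

    def pvalue_map(self, granularity: int = 1000) -> ScorePValueMap:
        if self._pvalue_map is None or self._pvalue_map.scale != granularity:
            self._pvalue_map = score_pvalue_map(self, granularity)
        return self._pvalue_map


def build_pwm(
    pfm: np.ndarray,
    pseudocount: float = 0.01,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Build a log-odds PWM (bits) from a 4 x W count/frequency matrix.

    Column counts are normalized to frequencies with ``pseudocount``
    distributed proportionally to the background, then log2-transformed
    against the background.  Rows are ordered A, C, G, T.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] < 1:
        raise ValueError(f"PFM must be 4 x W with W >= 1, got shape {pfm.shape}")
    if (pfm < 0).any():
        raise ValueError("PFM contains negative entries")
    colsums = pfm.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError("degenerate PFM: all-zero column")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-12:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    freq = (pfm + pseudocount * bg[:, None]) / (colsums + pseudocount)[None, :]
    pwm = np.log2(freq / bg[:, None])
    return MotifModel(
        pfm=pfm,
        pwm=pwm,
        width=pfm.shape[1],
        pseudocount=pseudocount,
        background=bg,
    )


def score_pvalue_map(model: MotifModel, granularity: int = 1000) -> ScorePValueMap:
    """Exact p-value map by positional convolution.

    ``granularity`` is the number of discretization bins per bit; the
    grid must resolve the PWM's score range into at least 100 bins.
    """
    int_scores = np.rint(model.pwm * granularity).astype(np.int64)
    span = int(int_scores.max(axis=0).sum() - int_scores.min(axis=0).sum())
    if span < 100:
        raise ValueError(
            f"granularity {granularity} yields only {span} bins over the score "
            "range; need >= 100"
        )
    return ScorePValueMap(int_scores, model.background, granularity)


def _window_scores(seq: str, pwm: np.ndarray) -> np.ndarray:
    """Score every forward-strand window of ``seq`` against ``pwm``."""
    W = pwm.shape[1]
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(seq), -1, dtype=np.int64)
    for ch, v in _BASE_INDEX.items():
        code[b == ord(ch)] = v
    if (code < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(code < 0)[0]})
        raise ValueError(f"non-ACGT character(s) in probe sequence: {bad}")
    n_win = len(seq) - W + 1
    scores = np.zeros(n_win)
    for j in range(W):
        scores += pwm[code[j : j + n_win], j]
    return scores


def scan(
    probes: Iterable[ProbeRecord],
    model: MotifModel,
    p_threshold: float = 1e-3,
    granularity: int = 1000,
) -> list[MotifOccurrence]:
    """Find motif occurrences with p <= ``p_threshold`` on both strands.

    Every window on both strands is scored; overlapping occurrences are
    all reported.  Probes shorter than the motif are skipped with a
    warning.  Output is sorted by (probe_id, offset, strand).
    """
    probes = list(probes)
    if not probes:
        raise ValueError("no probes to scan")
    pmap = model.pvalue_map(granularity)
    W = model.width
    hits: list[MotifOccurrence] = []
    for probe in probes:
        L = len(probe.sequence)
        if L < W:
            logger.warning(
                "probe %s (length %d) shorter than motif width %d; skipped",
                probe.probe_id, L, W,
            )
            continue
        seq = probe.sequence.upper()
        fwd = _window_scores(seq, model.pwm)
        rc_scores = _window_scores(reverse_complement(seq), model.pwm)
        # rc window at offset o covers forward positions L-W-o .. L-o-1
        rev = rc_scores[::-1]
        for strand, scores in (("+", fwd), ("-", rev)):
            pvals = pmap.pvalue(scores)
            for off in np.nonzero(pvals <= p_threshold)[0]:
                hits.append(
                    MotifOccurrence(
                        probe_id=probe.probe_id,
                        offset=int(off),
                        strand=strand,
                        score=float(scores[off]),
                        p_value=float(pvals[off]),
                    )
                )
    hits.sort(key=lambda h: (h.probe_id, h.offset, h.strand))
    return hits


def dedupe_occurrences(
    occurrences: Iterable[MotifOccurrence],
) -> list[MotifOccurrence]:
    """Collapse same-window occurrences to one binding site each.

    A palindromic motif matches forward and reverse strands of the same
    window; the scan reports both, but for counting binding *sites* the
    two are one location.  Keeps the higher-scoring strand per
    (probe_id, offset), preferring "+" on ties.
    """
    best: dict[tuple[str, int], MotifOccurrence] = {}
    for occ in occurrences:
        key = (occ.probe_id, occ.offset)
        cur = best.get(key)
        if cur is None or (occ.score, occ.strand == "+") > (cur.score, cur.strand == "+"):
            best[key] = occ
    return sorted(best.values(), key=lambda h: (h.probe_id, h.offset, h.strand))


#: Barcode categories: probes with 0 / 1 / >=2 motif occurrences.
BARCODE_CATEGORIES = ("white", "yellow", "brown")


def barcode(
    probes: Sequence[ProbeRecord], occurrences: Iterable[MotifOccurrence]
) -> list[tuple[str, float, int, str]]:
    """Categorize probes by binding-site count, ranked by signal intensity.

    Returns ``(probe_id, intensity, n_occurrences, category)`` tuples in
    descending intensity order (ties broken by probe_id), with category
    ``white`` for no occurrence, ``yellow`` for exactly one and
    ``brown`` for multiple.  Same-window strand duplicates (palindromic
    motifs) count as one site.
    """
    ids = [p.probe_id for p in probes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate probe_id(s): {dupes}")
    counts: dict[str, int] = {pid: 0 for pid in ids}
    for occ in dedupe_occurrences(occurrences):
        if occ.probe_id not in counts:
            raise ValueError(f"occurrence references unknown probe {occ.probe_id!r}")
        counts[occ.probe_id] += 1
    ranked = sorted(probes, key=lambda p: (-p.intensity, p.probe_id))
    out = []
    for p in ranked:
        n = counts[p.probe_id]
        cat = BARCODE_CATEGORIES[min(n, 2)]
        out.append((p.probe_id, p.intensity, n, cat))
    return out


# ---------------------------------------------------------------------------
# File formats


def parse_pfm(path_or_text: str | Path) -> np.ndarray:
    """Parse a PFM from common motif-database dialects.

    Accepts the JASPAR matrix-block format (``>name`` header, rows
    ``A [ 3 5 ... ]``), plain 4-row whitespace-separated matrices, and
    probability matrices with ``A:``-style row prefixes.  Returns a
    4 x W array in A, C, G, T row order (counts or probabilities; both
    work with :func:`build_pwm`).
    """
    if isinstance(path_or_text, Path) or (
        "\n" not in str(path_or_text) and Path(str(path_or_text)).exists()
    ):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    rows: dict[str, list[float]] = {}
    anon: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith((">", "#")):
            continue
        base = None
        if line[0].upper() in "ACGT" and (len(line) == 1 or not line[1].isalnum()):
            base = line[0].upper()
            line = line[1:].lstrip(": \t")
        cleaned = line.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in cleaned.split()]
        except ValueError as exc:
            raise ValueError(f"cannot parse PFM line {line!r}") from exc
        if not values:
            continue
        if base is not None:
            rows[base] = values
        else:
            anon.append(values)
    if len(rows) == 4:
        matrix = [rows[b] for b in _BASES]
    elif len(anon) == 4 and not rows:
        matrix = anon
    else:
        raise ValueError("PFM must provide exactly 4 base rows (A, C, G, T)")
    widths = {len(r) for r in matrix}
    if len(widths) != 1:
        raise ValueError(f"PFM rows have unequal widths {sorted(widths)}")
    return np.asarray(matrix, dtype=float)


def read_probes(path: str | Path) -> list[ProbeRecord]:
    """Read probes from TSV ``probe_id  sequence  intensity`` (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"probe file {path} needs 3 tab-separated columns")
    first = df.iloc[0]
    if str(first[0]).lower() == "probe_id":
        df = df.iloc[1:]
    return [
        ProbeRecord(probe_id=str(r[0]), sequence=str(r[1]).upper(), intensity=float(r[2]))
        for r in df.itertuples(index=False)
    ]


def write_probes(probes: Sequence[ProbeRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\tsequence\tintensity\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\t{repr(p.intensity)}\n")


def write_occurrences(occurrences: Sequence[MotifOccurrence], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\toffset\tstrand\tscore_bits\tp_value\n")
        for o in occurrences:
            fh.write(
                f"{o.probe_id}\t{o.offset}\t{o.strand}\t{o.score:.6f}\t{o.p_value:.6g}\n"
            )
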