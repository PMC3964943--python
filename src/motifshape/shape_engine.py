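"""Sliding-pentamer prediction of DNA structural features.

Double-helix geometry at a base pair (or base-pair step) is well
approximated by the local sequence context.  The engine parameterizes
this dependence with a *pentamer query table*: each 5-mer, taken up to
reverse complementation (512 canonical classes), carries precomputed
values of four structural features:

* **MGW** -- minor groove width at the central base pair (Angstrom),
* **ProT** -- propeller twist of the central base pair (degrees),
* **Roll**, **HelT** -- roll and helix twist of the two base-pair steps
  adjacent to the centre (degrees; two values each).

A window slides along the sequence; the pentamer centred at position
``i`` supplies the base-pair features for ``i`` and contributes its two
step values to the steps ``(i-1, i)`` and ``(i, i+1)``.  A step covered
by two windows stores the mean of the two contributions.  Positions
without a full pentamer window (the first and last two base pairs of an
unflanked sequence) are undefined and carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "BP_FEATURES",
    "STEP_FEATURES",
    "PentamerRecord",
    "PentamerTable",
    "ShapeProfile",
    "reverse_complement",
    "canonical_pentamer",
    "all_canonical_pentamers",
    "load_pentamer_table",
    "write_pentamer_table",
    "predict_shape",
    "symmetrize_profile",
]

#: The four structural feature tracks, in canonical order.
FEATURES = ("MGW", "ProT", "Roll", "HelT")
#: Features defined per base pair (track length L).
BP_FEATURES = ("MGW", "ProT")
#: Features defined per base-pair step (track length L - 1).
STEP_FEATURES = ("Roll", "HelT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_VALID_STRICT = frozenset("ACGT")
_VALID_AMBIG = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement of ``seq``, reversed.  ``N`` maps to ``N``."""
    if not _VALID_AMBIG.issuperset(seq):
        bad = sorted(set(seq) - _VALID_AMBIG)
        raise ValueError(f"non-nucleotide character(s) in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_pentamer(p: str) -> Tuple[str, bool]:
    """Canonicalize a 5-mer by reverse complementation.

    Returns ``(canonical, reversed)`` where ``canonical`` is the
    lexicographic minimum of ``p`` and its reverse complement and
    ``reversed`` is True iff the canonical form is not ``p`` itself.
    No odd-length DNA string equals its own reverse complement, so the
    1024 pentamers fall into exactly 512 classes of size two.
    """
    if len(p) != 5:
        raise ValueError(f"pentamer must have length 5, got {len(p)}")
    if not _VALID_STRICT.issuperset(p):
        raise ValueError(f"ambiguous base in pentamer {p!r}")
    rc = p.translate(_COMPLEMENT)[::-1]
    return (p, False) if p <= rc else (rc, True)


def all_canonical_pentamers() -> list[str]:
    """The 512 canonical pentamers in lexicographic order."""
    seen = set()
    for code in range(4**5):
        p = "".join("ACGT"[(code >> (2 * (4 - k))) & 3] for k in range(5))
        seen.add(canonical_pentamer(p)[0])
    return sorted(seen)


@dataclass(frozen=True)
class PentamerRecord:
    """Structural feature values of one canonical pentamer.

    ``roll`` and ``helt`` hold the two central-step values in the
    canonical pentamer's own 5'->3' orientation.
    """

    mgw: float
    prot: float
    roll: Tuple[float, float]
    helt: Tuple[float, float]


class PentamerTable:
    """Query table mapping canonical pentamers to structural features.

    The table is the engine's only parameterization; values typically
    derive from all-atom simulations of free DNA, but any complete
    512-entry table in the expected TSV dialect can be plugged in.
    """

    def __init__(self, entries: Mapping[str, PentamerRecord], source: str = ""):
        entries = dict(entries)
        if len(entries) != 512:
            raise ValueError(
                f"incomplete pentamer table: expected 512 entries, got {len(entries)}"
            )
        for key, rec in entries.items():
            canon, rev = canonical_pentamer(key)
            if rev:
                raise ValueError(f"non-canonical pentamer key {key!r} (use {canon!r})")
            if not rec.mgw > 0:
                raise ValueError(f"non-positive MGW for {key!r}: {rec.mgw}")
        self.entries: Dict[str, PentamerRecord] = entries
        self.source = source
        self._lut: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, pentamer: str) -> PentamerRecord:
        canon, _ = canonical_pentamer(pentamer)
        return self.entries[canon]

    def _lookup_arrays(self) -> dict[str, np.ndarray]:
        """Expand to per-code arrays over all 1024 pentamers.

        ``roll_a``/``helt_a`` is the contribution of a window to the step
        left of its centre, ``roll_b``/``helt_b`` to the step right of
        it; the pair is swapped for reverse-complement lookups so that
        prediction is exactly strand invariant.
        """
        if self._lut is None:
            lut = {
                name: np.full(1024, np.nan)
                for name in ("mgw", "prot", "roll_a", "roll_b", "helt_a", "helt_b")
            }
            for canon, rec in self.entries.items():
                rc = canon.translate(_COMPLEMENT)[::-1]
                c_code = _pentamer_code(canon)
                r_code = _pentamer_code(rc)
                for code, swapped in ((c_code, False), (r_code, True)):
                    lut["mgw"][code] = rec.mgw
                    lut["prot"][code] = rec.prot
                    r1, r2 = rec.roll
                    h1, h2 = rec.helt
                    if swapped:
                        r1, r2, h1, h2 = r2, r1, h2, h1
                    lut["roll_a"][code] = r1
                    lut["roll_b"][code] = r2
                    lut["helt_a"][code] = h1
                    lut["helt_b"][code] = h2
            self._lut = lut
        return self._lut

    def mean_mgw(self) -> float:
        """Mean MGW over the 512 canonical entries (table-level baseline)."""
        return float(np.mean([rec.mgw for rec in self.entries.values()]))


def _pentamer_code(p: str) -> int:
    code = 0
    for ch in p:
        code = (code << 2) | _BASE_CODE[ch]
    return code


_TABLE_COLUMNS = ["pentamer", "MGW", "ProT", "Roll1", "Roll2", "HelT1", "HelT2"]


def load_pentamer_table(path: str | Path, source: str | None = None) -> PentamerTable:
    """Read a pentamer table from TSV.

    Expected header: ``pentamer MGW ProT Roll1 Roll2 HelT1 HelT2`` with
    one row per canonical pentamer.  Rows keyed by non-canonical
    pentamers and incomplete tables are rejected.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"pentamer": str}, float_precision="round_trip"
    )
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pentamer table {path} lacks column(s) {missing}")
    for col in _TABLE_COLUMNS[1:]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col!r} of {path}")
    entries = {}
    for row in df.itertuples(index=False):
        key = row.pentamer
        if key in entries:
            raise ValueError(f"duplicate pentamer {key!r} in {path}")
        entries[key] = PentamerRecord(
            mgw=float(row.MGW),
            prot=float(row.ProT),
            roll=(float(row.Roll1), float(row.Roll2)),
            helt=(float(row.HelT1), float(row.HelT2)),
        )
    return PentamerTable(entries, source=source if source is not None else str(path))


def write_pentamer_table(table: PentamerTable, path: str | Path) -> None:
    """Write a table in the TSV dialect read by :func:`load_pentamer_table`.

    Floats are rendered with ``repr`` so the round-trip is bit exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for key in sorted(table.entries):
            rec = table.entries[key]
            vals = [rec.mgw, rec.prot, rec.roll[0], rec.roll[1], rec.helt[0], rec.helt[1]]
            fh.write(key + "\t" + "\t".join(repr(v) for v in vals) + "\n")


@dataclass
class ShapeProfile:
    """Per-position structural feature tracks for one sequence.

    ``mgw`` and ``prot`` have length ``L`` (one value per base pair);
    ``roll`` and ``helt`` have length ``L - 1`` (one value per step).
    Undefined entries are NaN.  ``coordinate_origin`` is the offset of
    track position 0 relative to the core start (``-2`` for a sequence
    carrying 2-bp flanks), so users see core-relative coordinates.
    """

    sequence: str
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray
    coordinate_origin: int = 0

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("mgw", "prot"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} track must have length {L}")
        for name in ("roll", "helt"):
            if len(getattr(self, name)) != L - 1:
                raise ValueError(f"{name} track must have length {L - 1}")

    def track(self, feature: str) -> np.ndarray:
        return getattr(self, feature.lower())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShapeProfile):
            return NotImplemented
        return self.sequence == other.sequence and all(
            np.array_equal(self.track(f), other.track(f), equal_nan=True)
            for f in FEATURES
        )


def predict_shape(
    seq: str, table: PentamerTable, ambiguous: str = "error"
) -> ShapeProfile:
    """Predict the four structural feature tracks of ``seq``.

    Parameters
    ----------
    seq:
        DNA string, length >= 5, over ``ACGT`` (``N`` allowed only with
        ``ambiguous="mask"``).
    table:
        Pentamer query table.
    ambiguous:
        ``"error"`` (default) rejects ``N``; ``"mask"`` marks every
        window touching an ``N`` as undefined instead.
    """
    L = len(seq)
    if L < 5:
        raise ValueError(f"sequence too short for pentamer window: length {L} < 5")
    s = seq.upper()
    if not _VALID_AMBIG.issuperset(s):
        bad = sorted(set(s) - _VALID_AMBIG)
        raise ValueError(f"non-nucleotide character(s): {bad}")
    if "N" in s:
        if ambiguous == "error":
            raise ValueError("ambiguous base N in sequence (use ambiguous='mask')")
        if ambiguous != "mask":
            raise ValueError(f"unknown ambiguous-base policy {ambiguous!r}")

    b = np.frombuffer(s.encode(), dtype=np.uint8)
    code = np.full(L, -1, dtype=np.int64)
    for ch, v in _BASE_CODE.items():
        code[b == ord(ch)] = v
    valid = code >= 0
    safe = np.where(valid, code, 0)
    # pentamer code for the window centred at i = 2 .. L-3
    wcodes = (
        safe[:-4] * 256 + safe[1:-3] * 64 + safe[2:-2] * 16 + safe[3:-1] * 4 + safe[4:]
    )
    wvalid = (
        valid[:-4] & valid[1:-3] & valid[2:-2] & valid[3:-1] & valid[4:]
    )
    lut = table._lookup_arrays()

    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    centres = np.arange(2, L - 2)
    mgw[centres[wvalid]] = lut["mgw"][wcodes[wvalid]]
    prot[centres[wvalid]] = lut["prot"][wcodes[wvalid]]

    def step_track(a_name: str, b_name: str) -> np.ndarray:
        # window centred at i contributes "a" to step i-1 and "b" to step i
        left = np.full(L - 1, np.nan)
        right = np.full(L - 1, np.nan)
        left[centres[wvalid] - 1] = lut[a_name][wcodes[wvalid]]
        right[centres[wvalid]] = lut[b_name][wcodes[wvalid]]
        return _nanmean_pair(left, right)

    return ShapeProfile(
        sequence=s,
        mgw=mgw,
        prot=prot,
        roll=step_track("roll_a", "roll_b"),
        helt=step_track("helt_a", "helt_b"),
    )


def _nanmean_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise mean of two tracks; missing values propagate quietly."""
    ok_a = ~np.isnan(a)
    ok_b = ~np.isnan(b)
    total = np.where(ok_a, a, 0.0) + np.where(ok_b, b, 0.0)
    count = ok_a.astype(float) + ok_b.astype(float)
    out = np.full(len(a), np.nan)
    present = count > 0
    out[present] = total[present] / count[present]
    return out


def _mirror_average(values: np.ndarray, two_centre: int) -> np.ndarray:
    """Average a track element-wise with its mirror about ``two_centre / 2``."""
    n = len(values)
    idx = np.arange(n)
    mirror = two_centre - idx
    partner = np.full(n, np.nan)
    ok = (mirror >= 0) & (mirror < n)
    partner[ok] = values[mirror[ok]]
    return _nanmean_pair(values, partner)


def symmetrize_profile(profile: ShapeProfile, centre: float) -> ShapeProfile:
    """Symmetrize a profile about ``centre``.

    Each track is averaged element-wise with its strand-reversed
    counterpart mirrored about ``centre`` (a base-pair coordinate; may be
    half-integral for even-length palindromes such as the E-box).
    Missing values propagate as the mean of the available values.
    Applying the operation twice equals applying it once.
    """
    L = len(profile.sequence)
    if not (0 <= centre <= L - 1):
        raise ValueError(f"centre {centre} outside profile of length {L}")
    two_c = 2.0 * centre
    if abs(two_c - round(two_c)) > 1e-9:
        raise ValueError("centre must be integral or half-integral")
    t2 = int(round(two_c))
    return ShapeProfile(
        sequence=profile.sequence,
        mgw=_mirror_average(profile.mgw, t2),
        prot=_mirror_average(profile.prot, t2),
        # step j sits between bp j and j+1; its mirror is step 2c-1-j
        roll=_mirror_average(profile.roll, t2 - 1),
        helt=_mirror_average(profile.helt, t2 - 1),
        coordinate_origin=profile.coordinate_origin,
    )
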