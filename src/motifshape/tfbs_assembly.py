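"""Assembly of aligned transcription-factor binding-site datasets.

Two input routes produce the same product, an aligned set of
equal-length binding sites:

* **Case-annotated FASTA** (the motif-database dialect): the core site
  is upper case, flanking sequence lower case.  Because a pentamer
  window needs 2 bp of context on each side, 2-bp flanks are required to
  predict shape for the whole core.  If more than half of the records
  carry >= 2-bp flanks on both sides, the unflanked records are dropped
  and every kept record is trimmed to exactly 2-bp flanks
  (``nnNNN...NNNnn``); otherwise all records are kept and flanks are
  stripped (``NNN...NNN``), leaving the two terminal core positions of
  each end without shape values.
* **Binding-microarray probes**: probes are scanned for significant
  motif occurrences (p <= 1e-3 by default); optionally probes with
  multiple occurrences are removed and only the top fraction of probes
  by signal intensity is kept; each surviving occurrence is extracted
  with 2-bp flanks, reverse-complemented into motif orientation for
  minus-strand hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .motif_scan import (
    MotifModel,
    MotifOccurrence,
    ProbeRecord,
    dedupe_occurrences,
    scan,
)
from .shape_engine import reverse_complement

__all__ = [
    "CaseAnnotatedSequence",
    "TFBSDataset",
    "parse_jaspar_fasta",
    "apply_flank_rule",
    "assemble_from_probes",
    "compute_pfm",
    "read_aligned_fasta",
    "write_dataset_fasta",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CaseAnnotatedSequence:
    """A FASTA record with an upper-case core and lower-case flanks."""

    seq_id: str
    sequence: str
    core_span: tuple[int, int]  # half-open

    @property
    def core(self) -> str:
        return self.sequence[self.core_span[0] : self.core_span[1]]

    @property
    def left_flank_len(self) -> int:
        return self.core_span[0]

    @property
    def right_flank_len(self) -> int:
        return len(self.sequence) - self.core_span[1]


@dataclass
class TFBSDataset:
    """Equal-length aligned binding sites with core span bookkeeping.

    Sequences are stored upper case; ``flank_width`` (0 or 2) gives the
    number of flanking base pairs retained on each side of the core.
    ``provenance`` records the source and the counts entering/leaving
    each filtering stage.
    """

    sequences: list[str]
    seq_ids: list[str]
    core_length: int
    flank_width: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flank_width not in (0, 2):
            raise ValueError(f"flank_width must be 0 or 2, got {self.flank_width}")
        want = self.core_length + 2 * self.flank_width
        for sid, s in zip(self.seq_ids, self.sequences):
            if len(s) != want:
                raise ValueError(
                    f"sequence {sid!r} has length {len(s)}, expected {want}"
                )
        if len(self.seq_ids) != len(self.sequences):
            raise ValueError("seq_ids and sequences differ in length")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return self.core_length + 2 * self.flank_width


def parse_jaspar_fasta(path: str | Path) -> list[CaseAnnotatedSequence]:
    """Parse case-annotated FASTA; reject malformed records, not the file.

    Each record must contain exactly one contiguous upper-case run (the
    core).  Records violating this are skipped with a logged diagnostic;
    an empty file or a file with no valid record is an error.
    """
    import logging
    import re

    logger = logging.getLogger(__name__)
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[CaseAnnotatedSequence] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq)
        if not set(seq) <= set("ACGTacgt"):
            rejected.append((rec.id, "non-ACGT characters"))
            continue
        runs = [m.span() for m in re.finditer(r"[ACGT]+", seq)]
        if len(runs) == 0:
            rejected.append((rec.id, "no upper-case core"))
            continue
        if len(runs) > 1:
            rejected.append((rec.id, f"{len(runs)} upper-case runs"))
            continue
        out.append(CaseAnnotatedSequence(rec.id, seq, runs[0]))
    for sid, why in rejected:
        logger.warning("record %s rejected: %s", sid, why)
    if not out:
        raise ValueError(f"no valid case-annotated records in {path}")
    return out


def apply_flank_rule(
    records: Sequence[CaseAnnotatedSequence],
    required_flank: int = 2,
    majority: float = 0.5,
) -> TFBSDataset:
    """Assemble a dataset applying the majority flank-retention rule.

    Let q be the fraction of records with >= ``required_flank`` bp of
    flank on *both* sides.  If q > ``majority``, only those records are
    kept, trimmed to exactly ``required_flank``-bp flanks; otherwise all
    records are kept and flanks are stripped entirely.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to assemble")
    core_lengths = {r.core_span[1] - r.core_span[0] for r in records}
    if len(core_lengths) != 1:
        raise ValueError(
            f"unequal core lengths {sorted(core_lengths)}: records must be "
            "pre-aligned to a common core before assembly"
        )
    core_length = core_lengths.pop()
    flanked = [
        r
        for r in records
        if r.left_flank_len >= required_flank and r.right_flank_len >= required_flank
    ]
    q = len(flanked) / len(records)
    if q > majority:
        seqs, ids = [], []
        for r in flanked:
            lo, hi = r.core_span
            seqs.append(r.sequence[lo - required_flank : hi + required_flank].upper())
            ids.append(r.seq_id)
        flank_width = required_flank
        kept = len(flanked)
    else:
        seqs = [r.core.upper() for r in records]
        ids = [r.seq_id for r in records]
        flank_width = 0
        kept = len(records)
    return TFBSDataset(
        sequences=seqs,
        seq_ids=ids,
        core_length=core_length,
        flank_width=flank_width,
        provenance={
            "source": "case_annotated_fasta",
            "n_input": len(records),
            "fraction_flanked": q,
            "majority_threshold": majority,
            "required_flank": required_flank,
            "n_output": kept,
        },
    )


def assemble_from_probes(
    probes: Sequence[ProbeRecord],
    model: MotifModel,
    p_threshold: float = 1e-3,
    drop_multi_site: bool = True,
    top_fraction: float | None = None,
) -> TFBSDataset:
    """Extract aligned binding sites from probe sequences.

    Pipeline: scan all probes; optionally remove probes with >= 2
    occurrences; optionally keep the ``top_fraction`` of remaining
    probes with highest intensity (intensity ties at the cutoff are
    kept); extract every occurrence with 2-bp flanks in motif
    orientation; occurrences without 2-bp probe flanks are dropped.
    """
    probes = list(probes)
    raw = scan(probes, model, p_threshold=p_threshold)
    # one binding site per window: palindromic double-strand hits collapse
    occurrences = dedupe_occurrences(raw)
    by_probe: dict[str, list[MotifOccurrence]] = {}
    for occ in occurrences:
        by_probe.setdefault(occ.probe_id, []).append(occ)

    stage = {"n_probes": len(probes), "n_occurrences_scanned": len(raw),
             "n_distinct_sites_scanned": len(occurrences)}
    survivors = probes
    if drop_multi_site:
        survivors = [p for p in survivors if len(by_probe.get(p.probe_id, [])) < 2]
    stage["n_after_multisite_filter"] = len(survivors)
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
        k = max(1, math.ceil(top_fraction * len(survivors)))
        ranked = sorted(survivors, key=lambda p: (-p.intensity, p.probe_id))
        cutoff = ranked[k - 1].intensity
        survivors = [p for p in ranked if p.intensity >= cutoff]  # keep ties
    stage["n_after_intensity_filter"] = len(survivors)

    W = model.width
    seqs, ids = [], []
    n_no_flank = 0
    probe_seq = {p.probe_id: p.sequence.upper() for p in survivors}
    surviving_ids = set(probe_seq)
    for occ in occurrences:
        if occ.probe_id not in surviving_ids:
            continue
        L = len(probe_seq[occ.probe_id])
        lo, hi = occ.offset - 2, occ.offset + W + 2
        if lo < 0 or hi > L:
            n_no_flank += 1
            continue
        site = probe_seq[occ.probe_id][lo:hi]
        if occ.strand == "-":
            site = reverse_complement(site)
        seqs.append(site)
        ids.append(f"{occ.probe_id}:{occ.offset}{occ.strand}")
    stage["n_sites_dropped_missing_flank"] = n_no_flank
    stage["n_sites"] = len(seqs)
    # deterministic set semantics: order by site id, not probe input order
    order = sorted(range(len(seqs)), key=lambda i: ids[i])
    seqs = [seqs[i] for i in order]
    ids = [ids[i] for i in order]
    if not seqs:
        raise ValueError(f"no binding sites survived assembly; stage counts: {stage}")
    return TFBSDataset(
        sequences=seqs,
        seq_ids=ids,
        core_length=W,
        flank_width=2,
        provenance={
            "source": "probe_scan",
            "p_threshold": p_threshold,
            "drop_multi_site": drop_multi_site,
            "top_fraction": top_fraction,
            **stage,
        },
    )


def compute_pfm(dataset: TFBSDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-position base counts and information content of a dataset.

    Returns ``(counts, ic)`` where ``counts`` is 4 x L (rows A, C, G, T
    over core+flank positions) and ``ic[j] = 2 - H(freq_j)`` in bits
    (uniform background, no small-sample correction).  Position
    numbering matches the shape-matrix convention (0 = core start).
    """
    if not len(dataset):
        raise ValueError("empty dataset")
    L = dataset.total_length
    counts = np.zeros((4, L))
    arr = np.frombuffer("".join(dataset.sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(dataset), L)
    for bi, base in enumerate(_BASES):
        counts[bi] = (arr == ord(base)).sum(axis=0)
    freq = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return counts, ic


def read_aligned_fasta(path: str | Path, flank_width: int | None = None) -> TFBSDataset:
    """Read pre-aligned equal-length sequences as a dataset.

    If the records are case annotated with a consistent core, the core
    span is honoured; otherwise the whole sequence is the core (or
    ``flank_width`` is applied symmetrically when given).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seqs = [str(r.seq) for r in records]
    ids = [r.id for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"pre-aligned input must have equal lengths, got {sorted(lengths)}"
        )
    L = lengths.pop()
    spans = set()
    import re

    for s in seqs:
        runs = [m.span() for m in re.finditer(r"[ACGT]+", s)]
        spans.add(runs[0] if len(runs) == 1 else None)
    if flank_width is None:
        if len(spans) == 1 and None not in spans:
            lo, hi = spans.pop()
            flank_width = lo if lo == L - hi and lo in (0, 2) else 0
        else:
            flank_width = 0
    core_length = L - 2 * flank_width
    if core_length < 1:
        raise ValueError("flank_width too large for sequence length")
    return TFBSDataset(
        sequences=[s.upper() for s in seqs],
        seq_ids=ids,
        core_length=core_length,
        flank_width=flank_width,
        provenance={"source": "user_aligned_fasta", "n_input": len(seqs),
                    "n_output": len(seqs)},
    )


def write_dataset_fasta(dataset: TFBSDataset, path: str | Path) -> None:
    """Write a dataset as case-annotated FASTA (core upper, flanks lower)."""
    w = dataset.flank_width
    with Path(path).open("w") as fh:
        for sid, s in zip(dataset.seq_ids, dataset.sequences):
            cased = (
                s[:w].lower() + s[w : len(s) - w] + s[len(s) - w :].lower()
                if w
                else s
            )
            fh.write(f">{sid}\n{cased}\n")
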