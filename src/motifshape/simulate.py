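"""Synthetic inputs: pentamer tables, motif FASTA, probe sets, intensities.

Everything the pipeline consumes can be generated here, reproducibly
from a seed, in the exact file dialects the other modules read:

* **Pentamer tables** with feature values drawn uniformly from
  physically plausible ranges (MGW 2.8-6.2 A, ProT -18-0 deg, Roll
  -8-10 deg, HelT 30-40 deg).
* **Case-annotated FASTA** emulating motif-database records: upper-case
  cores (a consensus with point mutations), lower-case flanks, with a
  configurable fraction of records carrying the 2-bp flanks the shape
  engine needs.
* **Probe sets** emulating binding microarrays: 36-bp probes, a
  fraction carrying one planted motif occurrence and a smaller fraction
  two, at random offsets and strands; log-normal intensities combining
  a sequence term (PWM score of the planted site), a shape term (mean
  minor groove width of the site) and Gaussian noise.
* **Regression fixtures**: aligned sites with intensities combining a
  mononucleotide sequence effect and a planted shape effect with
  controlled variance shares, for exercising the specificity models.

Each generator also returns a manifest recording the ground truth
(planted sites, per-record flank status, true effect components), so
downstream outputs can be verified without re-deriving the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motif_scan import ProbeRecord, build_pwm
from .shape_engine import (
    PentamerRecord,
    PentamerTable,
    all_canonical_pentamers,
    predict_shape,
    reverse_complement,
)
from .tfbs_assembly import TFBSDataset

__all__ = [
    "SimulationConfig",
    "make_pentamer_table",
    "make_jaspar_fixture",
    "make_pbm_fixture",
    "make_regression_fixture",
]

_BASES = "ACGT"

#: Plausible value ranges per structural feature (units: A / degrees).
DEFAULT_RANGES = {
    "MGW": (2.8, 6.2),
    "ProT": (-18.0, 0.0),
    "Roll": (-8.0, 10.0),
    "HelT": (30.0, 40.0),
}


@dataclass
class SimulationConfig:
    """Parameters shared by the fixture generators.

    The defaults describe a compact but realistic study: a 6-bp
    palindromic consensus (the E-box bound by bHLH factors), 36-bp
    probes, most probes motif-free, and a log-normal intensity model in
    which sequence and shape both contribute.
    """

    seed: int = 0
    consensus: str = "CACGTG"
    mutation_rate: float = 0.08
    n_records: int = 50
    n_probes: int = 500
    probe_length: int = 36
    flank_fraction: float = 0.8
    one_site_fraction: float = 0.3
    two_site_fraction: float = 0.05
    seq_weight: float = 1.0
    shape_weight: float = 1.0
    noise_sd: float = 0.3
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "flank_fraction", "one_site_fraction",
                     "two_site_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.one_site_fraction + self.two_site_fraction > 1.0:
            raise ValueError("site fractions exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.probe_length < len(self.consensus) + 4:
            raise ValueError(
                f"probe_length {self.probe_length} < motif width + 4 "
                f"({len(self.consensus) + 4})"
            )


def make_pentamer_table(config: SimulationConfig | None = None) -> PentamerTable:
    """A complete 512-entry table with values uniform in the feature ranges."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    entries = {}
    for p in all_canonical_pentamers():
        lo, hi = config.ranges["MGW"]
        mgw = float(rng.uniform(lo, hi))
        lo, hi = config.ranges["ProT"]
        prot = float(rng.uniform(lo, hi))
        lo, hi = config.ranges["Roll"]
        roll = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        lo, hi = config.ranges["HelT"]
        helt = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        entries[p] = PentamerRecord(mgw=mgw, prot=prot, roll=roll, helt=helt)
    return PentamerTable(entries, source=f"synthetic(seed={config.seed})")


def _mutate(core: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in core:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def make_jaspar_fixture(config: SimulationConfig | None = None) -> tuple[str, dict]:
    """Case-annotated FASTA text plus a ground-truth manifest.

    ``ceil(flank_fraction * n_records)`` records carry 2-3 bp lower-case
    flanks on both sides; the rest carry 0-1 bp on at least one side, so
    the majority flank-retention rule later keeps exactly the flanked
    subset (when the fraction exceeds one half).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_records
    n_flanked = math.ceil(config.flank_fraction * n)
    lines = []
    manifest = {"consensus": config.consensus, "records": []}
    for i in range(n):
        core = _mutate(config.consensus, config.mutation_rate, rng)
        flanked = i < n_flanked
        if flanked:
            lf = int(rng.integers(2, 4))
            rf = int(rng.integers(2, 4))
        else:
            # under 2 bp on at least one side
            lf = int(rng.integers(0, 2))
            rf = int(rng.integers(0, 2))
        seq = _random_seq(lf, rng).lower() + core + _random_seq(rf, rng).lower()
        sid = f"site{i:04d}"
        lines.append(f">{sid}\n{seq}")
        manifest["records"].append(
            {"seq_id": sid, "core": core, "left_flank": lf, "right_flank": rf,
             "fully_flanked": flanked}
        )
    manifest["n_fully_flanked"] = n_flanked
    return "\n".join(lines) + "\n", manifest


def _consensus_pfm(consensus: str, softness: float = 0.05,
                   n_obs: int = 1000) -> np.ndarray:
    """A sharply peaked count PFM around a consensus sequence."""
    W = len(consensus)
    pfm = np.full((4, W), softness * n_obs / 3)
    for j, ch in enumerate(consensus):
        pfm[_BASES.index(ch), j] = (1 - softness) * n_obs
    return pfm


def make_pbm_fixture(
    config: SimulationConfig | None = None,
    table: PentamerTable | None = None,
) -> tuple[list[ProbeRecord], np.ndarray, dict]:
    """Probe set, PFM and manifest emulating a binding-microarray run.

    Probes are random background sequence; a ``one_site_fraction`` of
    them carries one planted site (consensus with mutations) and a
    ``two_site_fraction`` two non-overlapping sites, at random offsets
    (always leaving >= 2-bp probe flanks) and random strands.  Log
    intensity = seq_weight * (site PWM score / width) + shape_weight *
    (site mean MGW - table mean) + N(0, noise_sd); motif-free probes get
    background noise only.
    """
    config = config or SimulationConfig()
    table = table or make_pentamer_table(config)
    rng = np.random.default_rng(config.seed + 2)
    W = len(config.consensus)
    L = config.probe_length
    pfm = _consensus_pfm(config.consensus)
    model = build_pwm(pfm)
    table_mean = table.mean_mgw()

    n1 = round(config.one_site_fraction * config.n_probes)
    n2 = round(config.two_site_fraction * config.n_probes)
    probes: list[ProbeRecord] = []
    manifest = {"consensus": config.consensus, "probes": []}
    for i in range(config.n_probes):
        pid = f"probe{i:05d}"
        n_sites = 1 if i < n1 else (2 if i < n1 + n2 else 0)
        seq = list(_random_seq(L, rng))
        planted = []
        if n_sites:
            # non-overlapping offsets leaving 2-bp flanks on the probe
            while True:
                offs = sorted(rng.integers(2, L - W - 1, size=n_sites).tolist())
                if n_sites == 1 or offs[1] - offs[0] >= W:
                    break
            for off in offs:
                site = _mutate(config.consensus, config.mutation_rate, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                ins = site if strand == "+" else reverse_complement(site)
                seq[off : off + W] = list(ins)
                planted.append({"offset": int(off), "strand": strand, "site": site})
        seq = "".join(seq)
        log_i = float(rng.normal(0.0, config.noise_sd))
        if planted:
            best = None
            for p in planted:
                site_with_flanks = seq[p["offset"] - 2 : p["offset"] + W + 2]
                if p["strand"] == "-":
                    site_with_flanks = reverse_complement(site_with_flanks)
                prof = predict_shape(site_with_flanks, table)
                score = float(
                    sum(
                        model.pwm[_BASES.index(ch), j]
                        for j, ch in enumerate(p["site"])
                    )
                )
                mgw = float(np.nanmean(prof.mgw))
                contrib = (
                    config.seq_weight * score / W
                    + config.shape_weight * (mgw - table_mean)
                )
                best = contrib if best is None else max(best, contrib)
            log_i += best + 1.0  # planted probes sit above background
        probes.append(ProbeRecord(pid, seq, float(np.exp(log_i))))
        manifest["probes"].append(
            {"probe_id": pid, "n_planted": n_sites, "planted": planted}
        )
    manifest["n_one_site"] = n1
    manifest["n_two_site"] = n2
    return probes, pfm, manifest


def make_regression_fixture(
    n_sites: int = 2000,
    seed: int = 0,
    consensus: str = "CACGTG",
    mutation_rate: float = 0.15,
    var_sequence: float = 1.0,
    var_shape: float = 0.6,
    var_noise: float = 0.4,
    table: PentamerTable | None = None,
) -> tuple[TFBSDataset, np.ndarray, PentamerTable, dict]:
    """Aligned sites with intensities carrying a planted shape effect.

    Sites are the consensus with point mutations plus random 2-bp
    flanks.  Log intensity = f(sequence) + g(shape) + noise where f is a
    random linear function of mononucleotide indicators and g is the
    mean of core MGW and Roll values — a pentamer-determined quantity a
    linear mononucleotide model cannot fully express.  Each component is
    standardized to its requested variance share, so the attainable R^2
    of sequence-only versus sequence+shape models is controlled by
    construction.
    """
    rng = np.random.default_rng(seed)
    if table is None:
        table = make_pentamer_table(SimulationConfig(seed=seed))
    W = len(consensus)
    L = W + 4
    seqs, ids = [], []
    for i in range(n_sites):
        core = _mutate(consensus, mutation_rate, rng)
        seqs.append(_random_seq(2, rng) + core + _random_seq(2, rng))
        ids.append(f"site{i:05d}")
    dataset = TFBSDataset(
        sequences=seqs,
        seq_ids=ids,
        core_length=W,
        flank_width=2,
        provenance={"source": "synthetic_regression", "seed": seed,
                    "n_input": n_sites, "n_output": n_sites},
    )

    # sequence effect: random weights over mononucleotide indicators
    weights = rng.normal(size=(L, 4))
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n_sites, L)
    base_idx = np.zeros_like(arr, dtype=int)
    for bi, b in enumerate(_BASES):
        base_idx[arr == ord(b)] = bi
    f = weights[np.arange(L)[None, :], base_idx].sum(axis=1)

    # shape effect: mean core MGW + mean core Roll (pentamer-determined)
    g = np.empty(n_sites)
    for i, s in enumerate(seqs):
        prof = predict_shape(s, table)
        g[i] = np.nanmean(prof.mgw[2 : L - 2]) + np.nanmean(prof.roll[2 : L - 3])

    def scaled(v: np.ndarray, target_var: float) -> np.ndarray:
        sd = v.std()
        if sd < 1e-12:
            return np.zeros_like(v)
        return (v - v.mean()) / sd * math.sqrt(target_var)

    f = scaled(f, var_sequence)
    g = scaled(g, var_shape)
    noise = rng.normal(0.0, math.sqrt(var_noise), size=n_sites)
    log_y = f + g + noise
    intensities = np.exp(log_y)
    manifest = {
        "seed": seed,
        "n_sites": n_sites,
        "var_sequence": var_sequence,
        "var_shape": var_shape,
        "var_noise": var_noise,
        "sequence_component": f,
        "shape_component": g,
    }
    return dataset, intensities, table, manifest
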