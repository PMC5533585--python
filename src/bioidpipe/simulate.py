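"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: quadruplicate
bait-vs-control spectral-count experiments with a handful of genuinely
proximal ("planted") proteins enriched over a common baseline, search-result
PSM tables whose scores straddle the filter thresholds by construction, and
single-molecule track mixtures of processive, diffusive, and static
particles sampled every 0.5 s.

Counts are Poisson per replicate (the simplest dispersion model consistent
with independent spectral sampling); planted proteins multiply the baseline
rate in the bait channel only.  Every generator is deterministic under its
seed and labels its own ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motility import DIFFUSIVE, NON_MOTILE, PROCESSIVE, Track
from .psm import DEFAULT_DECOY_PREFIX, TERMINUS
from .quant import CountMatrix, empty_shared

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CountSimConfig:
    """Parameters of a simulated bait-vs-control count experiment."""

    n_proteins: int = 200
    n_replicates: int = 4
    baseline_rate: float = 10.0
    planted_proteins: dict = field(default_factory=dict)  # id -> multiplier > 1
    shared_peptide_fraction: float = 0.0
    decoy_fraction: float = 0.0
    protein_length_range: tuple = (100, 1000)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        for pid, mult in self.planted_proteins.items():
            if mult <= 1:
                raise ValueError(f"multiplier for {pid} must be > 1")
        for frac in (self.shared_peptide_fraction, self.decoy_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("bad protein length range")


@dataclass
class TrackSimConfig:
    """Parameters of a simulated single-molecule track mixture."""

    n_tracks: int = 100
    frame_interval: float = 0.5  # seconds
    class_mixture: tuple = (0.4, 0.3, 0.3)  # processive, diffusive, non-motile
    velocity_mean_sd: tuple = (800.0, 100.0)  # nm/s
    diffusion_step_sd: float = 300.0          # nm per frame
    localization_noise_sd: float = 20.0       # nm
    track_length_frames: tuple = (40, 80)
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        lo, hi = self.track_length_frames
        if lo < 2 or hi < lo:
            raise ValueError("bad track length range")


def protein_ids(config: CountSimConfig) -> tuple[list, pd.Series]:
    """Deterministic protein ids and a decoy flag Series.

    The last ``decoy_fraction`` of proteins are decoys, carrying the
    shuffled-database prefix on their id.
    """
    n_decoy = int(round(config.decoy_fraction * config.n_proteins))
    ids = []
    decoy_flags = []
    for i in range(config.n_proteins):
        is_decoy = i >= config.n_proteins - n_decoy
        base = f"P{i:05d}"
        ids.append(DEFAULT_DECOY_PREFIX + base if is_decoy else base)
        decoy_flags.append(is_decoy)
    return ids, pd.Series(decoy_flags, index=ids)


def generate_count_experiment(
    config: CountSimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.Series]:
    """Simulate bait and control count experiments with planted enrichment.

    Returns (bait, control, truth) where truth is a boolean Series marking
    the planted (genuinely proximal) proteins.  Unique counts per protein
    and replicate are Poisson with the baseline rate; in the bait channel a
    planted protein's rate is baseline times its multiplier.  When
    ``shared_peptide_fraction`` > 0, that fraction of proteins (paired off
    deterministically) additionally shares one peptide per pair whose rate
    is the mean of its parents' rates, recorded in the shared table and not
    in uSpC.
    """
    rng = np.random.default_rng(config.seed)
    ids, decoy = protein_ids(config)
    for pid in config.planted_proteins:
        if pid not in set(ids):
            raise ValueError(f"planted protein {pid!r} outside the universe")
    reps = [f"rep{i + 1}" for i in range(config.n_replicates)]
    lo, hi = config.protein_length_range
    lengths = pd.Series(rng.integers(lo, hi + 1, size=config.n_proteins), index=ids)

    bait_rate = np.full(config.n_proteins, config.baseline_rate)
    control_rate = np.full(config.n_proteins, config.baseline_rate)
    for pid, mult in config.planted_proteins.items():
        bait_rate[ids.index(pid)] = config.baseline_rate * mult

    bait_unique = pd.DataFrame(
        rng.poisson(bait_rate[:, None], size=(config.n_proteins, config.n_replicates)),
        index=ids,
        columns=reps,
    )
    control_unique = pd.DataFrame(
        rng.poisson(
            control_rate[:, None], size=(config.n_proteins, config.n_replicates)
        ),
        index=ids,
        columns=reps,
    )

    n_shared_pairs = int(round(config.shared_peptide_fraction * config.n_proteins / 2))
    shared_rows = []
    for j in range(n_shared_pairs):
        a, b = ids[2 * j], ids[2 * j + 1]
        rate_bait = (bait_rate[2 * j] + bait_rate[2 * j + 1]) / 2
        rate_ctrl = (control_rate[2 * j] + control_rate[2 * j + 1]) / 2
        shared_rows.append(
            (
                f"shpep{j:04d}",
                (a, b),
                rng.poisson(rate_bait, size=config.n_replicates),
                rng.poisson(rate_ctrl, size=config.n_replicates),
            )
        )

    def shared_frame(channel: int) -> pd.DataFrame:
        if not shared_rows:
            return empty_shared(reps)
        data = {
            "parents": [row[1] for row in shared_rows],
        }
        for k, rep in enumerate(reps):
            data[rep] = [row[2 + channel][k] for row in shared_rows]
        return pd.DataFrame(data, index=[row[0] for row in shared_rows])

    bait = CountMatrix(
        unique=bait_unique, shared=shared_frame(0), lengths=lengths, decoy=decoy
    )
    control = CountMatrix(
        unique=control_unique, shared=shared_frame(1), lengths=lengths, decoy=decoy
    )
    truth = pd.Series(
        [pid in config.planted_proteins for pid in ids], index=ids, name="planted"
    )
    return bait, control, truth


def _random_peptide(rng, length: int, tryptic: bool) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    last = rng.choice(["K", "R"]) if tryptic else rng.choice(
        [aa for aa in AMINO_ACIDS if aa not in "KR"]
    )
    return body + last


def generate_psm_table(config: CountSimConfig) -> pd.DataFrame:
    """Simulate a search-result PSM table with known retain/reject truth.

    One PSM per simulated spectrum (one spectrum per protein per 'scan'),
    roughly half labeled ``retain``: those rows satisfy every filter
    criterion (some exactly at the inclusive boundaries).  Rejected rows
    violate exactly one criterion each, cycling through short peptides,
    non-tryptic termini, low DeltCn, low XCorr, and high Sp rank, so each
    rejection reason is represented.  ``decoy_fraction`` of rows map to a
    decoy protein.  The truth lives in the ``truth_retain`` column.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids, _ = protein_ids(config)
    n = max(config.n_proteins, 10)
    rows = []
    violations = ("short", "nontryptic", "deltcn", "xcorr", "sprank")
    for i in range(n):
        retain = i % 2 == 0
        charge = int(rng.integers(1, 4))
        xcorr_min = {1: 1.8, 2: 2.5, 3: 3.5}[charge]
        is_decoy = rng.random() < config.decoy_fraction
        pid = ids[int(rng.integers(0, len(ids)))]
        if is_decoy:
            pid = DEFAULT_DECOY_PREFIX + pid.removeprefix(DEFAULT_DECOY_PREFIX)
        if retain:
            boundary = i % 4 == 0
            peptide = _random_peptide(
                rng, 7 if boundary else int(rng.integers(8, 20)), tryptic=True
            )
            row = dict(
                peptide=peptide,
                flank_n=str(rng.choice(["K", "R", TERMINUS])),
                flank_c=str(rng.choice(list(AMINO_ACIDS))),
                xcorr=xcorr_min if boundary else xcorr_min + rng.uniform(0.1, 2.0),
                deltcn=0.08 if boundary else rng.uniform(0.09, 0.5),
                sp_rank=10 if boundary else int(rng.integers(1, 10)),
            )
        else:
            kind = violations[i % len(violations)]
            row = dict(
                peptide=_random_peptide(rng, int(rng.integers(8, 20)), tryptic=True),
                flank_n=str(rng.choice(["K", "R"])),
                flank_c=str(rng.choice(list(AMINO_ACIDS))),
                xcorr=xcorr_min + rng.uniform(0.1, 2.0),
                deltcn=rng.uniform(0.09, 0.5),
                sp_rank=int(rng.integers(1, 10)),
            )
            if kind == "short":
                row["peptide"] = _random_peptide(rng, int(rng.integers(2, 7)), True)
            elif kind == "nontryptic":
                row["peptide"] = _random_peptide(rng, int(rng.integers(8, 20)), False)
            elif kind == "deltcn":
                row["deltcn"] = rng.uniform(0.0, 0.079)
            elif kind == "xcorr":
                row["xcorr"] = xcorr_min - rng.uniform(0.01, 1.0)
            elif kind == "sprank":
                row["sp_rank"] = int(rng.integers(11, 50))
        rows.append(
            dict(
                spectrum_id=f"scan{i:06d}",
                charge=charge,
                protein_ids=pid,
                truth_retain=retain,
                is_decoy=is_decoy,
                **row,
            )
        )
    return pd.DataFrame(rows)


def generate_tracks(config: TrackSimConfig) -> list[Track]:
    """Simulate labeled single-molecule tracks.

    Processive tracks drift at a per-track velocity drawn from the
    configured normal distribution (random sign) plus localization noise;
    diffusive tracks are unbiased Gaussian random walks; non-motile tracks
    are localization noise around a fixed position.  Each Track carries its
    generating class in ``label``.
    """
    rng = np.random.default_rng(config.seed)
    classes = (PROCESSIVE, DIFFUSIVE, NON_MOTILE)
    tracks = []
    lo, hi = config.track_length_frames
    for i in range(config.n_tracks):
        cls = classes[rng.choice(3, p=list(config.class_mixture))]
        n = int(rng.integers(lo, hi + 1))
        t = np.arange(n) * config.frame_interval
        noise = rng.normal(0, config.localization_noise_sd, size=n)
        if cls == PROCESSIVE:
            vmean, vsd = config.velocity_mean_sd
            v = rng.normal(vmean, vsd) * (1 if rng.random() < 0.5 else -1)
            x = v * t + noise
        elif cls == DIFFUSIVE:
            steps = rng.normal(0, config.diffusion_step_sd, size=n - 1)
            x = np.concatenate([[0.0], np.cumsum(steps)]) + noise
        else:
            x = noise
        tracks.append(Track(track_id=f"track{i:05d}", times=t, positions=x, label=cls))
    return tracks
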