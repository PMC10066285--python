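"""Synthetic probe-intensity experiments with planted specificity.

A stand-in for wet-lab pulldown data: each probe's fluorescence is a
log-normal non-specific background plus a specific term proportional to
the probe's occupancy under a planted motif,

    intensity = exp(N(background_mu, background_sigma))
              + gain * occupancy * exp(N(0, noise_sigma)),

where occupancy is the sum over probe windows of the per-window PWM
probability (linear in site count — equilibrium binding far from
saturation).  Noise is multiplicative log-normal, matching the
positivity of fluorescence intensities.  Failure modes emulate the
technical outcomes an experiment classifier must recognize: no
specificity at all, artifact-k-mer contamination, and discordant
specificity between the two probe sets.

The "strong signal" defaults (gain about 10x the median background,
noise_sigma 0.3) define the simulated study conditions used throughout
the tests; realistic noise magnitudes for this array platform are not
published, so the defaults are declared, not fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kmers import SENTINEL, encode
from .motifs import PFM
from .pool import ProbePool
from .scoring import IntensityProfile

MODES = ("specific", "nonspecific", "artifact", "split_discordant")

# strong-signal regime: background exp(mu) = 100 intensity units,
# specific gain ~10x that for a single perfect site
DEFAULT_BACKGROUND_MU = math.log(100.0)
DEFAULT_BACKGROUND_SIGMA = 0.25
DEFAULT_NOISE_SIGMA = 0.3
DEFAULT_GAIN = 1000.0
DEFAULT_MISMATCH_PENALTY = 0.25


@dataclass
class SimConfig:
    """Parameters of one simulated experiment."""

    mode: str = "specific"
    motif: "PFM | str" = "UGCAUGU"
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY
    gain: float = DEFAULT_GAIN
    background_mu: float = DEFAULT_BACKGROUND_MU
    background_sigma: float = DEFAULT_BACKGROUND_SIGMA
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    artifact_kmer: str = "GGGG"
    motif_b: "PFM | str | None" = None  # second motif for split_discordant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if min(self.background_sigma, self.noise_sigma) < 0:
            raise ValueError("sigmas must be >= 0")
        if self.mismatch_penalty < 0 or self.mismatch_penalty > 1:
            raise ValueError("mismatch_penalty must be in [0, 1]")


def _affinity_matrix(motif: "PFM | str", mismatch_penalty: float) -> np.ndarray:
    """Per-position base affinities (L, 4) with a zero column for the
    sentinel code appended, so windows crossing probe boundaries score 0."""
    if isinstance(motif, PFM):
        m = motif.matrix
    else:
        codes = encode(motif)
        if (codes >= SENTINEL).any():
            raise ValueError(f"motif consensus {motif!r} must be over ACGU")
        m = np.full((codes.size, 4), mismatch_penalty)
        m[np.arange(codes.size), codes] = 1.0
    return np.hstack([m, np.zeros((m.shape[0], 1))])


def occupancy(pool: ProbePool, motif: "PFM | str", mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY) -> np.ndarray:
    """Sum-over-windows PWM affinity of each probe for a motif.

    Each length-L window contributes the product over positions of the
    per-base affinity (PFM probability, or 1 for consensus matches and
    ``mismatch_penalty`` per mismatch).
    """
    aff = _affinity_matrix(motif, mismatch_penalty)
    L = aff.shape[0]
    if L > int(pool.probe_lengths.min()):
        raise ValueError(
            f"motif length {L} exceeds the shortest probe "
            f"({int(pool.probe_lengths.min())} nt)"
        )
    # windows over the sentinel-separated concatenation; boundary windows
    # pick up a zero factor and vanish on their own
    lens = pool.probe_lengths
    parts: list[np.ndarray] = []
    sep = np.full(1, SENTINEL, dtype=np.uint8)
    for c in pool.codes():
        parts.append(c)
        parts.append(sep)
    cat = np.concatenate(parts)
    win = np.lib.stride_tricks.sliding_window_view(cat, L)
    scores = aff[0][win[:, 0]]
    for j in range(1, L):
        scores = scores * aff[j][win[:, j]]
    probe_of = np.repeat(np.arange(len(pool)), lens + 1)[: win.shape[0]]
    return np.bincount(probe_of, weights=scores, minlength=len(pool))


def _contains(pool: ProbePool, kmer: str) -> np.ndarray:
    from .kmers import kmer_to_code

    k = len(kmer)
    wcodes, wprobe = pool.window_index(k)
    hit = wprobe[wcodes == kmer_to_code(kmer)]
    out = np.zeros(len(pool), dtype=float)
    out[np.unique(hit)] = 1.0
    return out


def simulate_experiment(pool: ProbePool, cfg: SimConfig) -> IntensityProfile:
    """Simulate one probe-intensity profile; deterministic given cfg.seed."""
    if len(pool) == 0:
        raise ValueError("pool is empty")
    n = len(pool)
    rng = np.random.default_rng(cfg.seed)
    # draw order is fixed (background, then noise) so experiments sharing a
    # seed but differing in gain share their noise realization
    background = np.exp(rng.normal(cfg.background_mu, cfg.background_sigma, n))
    noise = np.exp(rng.normal(0.0, cfg.noise_sigma, n))

    if cfg.mode == "specific":
        occ = occupancy(pool, cfg.motif, cfg.mismatch_penalty)
        gain = cfg.gain
    elif cfg.mode == "nonspecific":
        occ = np.zeros(n)
        gain = 0.0
    elif cfg.mode == "artifact":
        occ = _contains(pool, cfg.artifact_kmer)
        gain = cfg.gain
    else:  # split_discordant
        if pool.set_labels is None:
            raise ValueError("split_discordant mode needs a labeled pool")
        if cfg.motif_b is None:
            raise ValueError("split_discordant mode needs motif_b")
        occ_a = occupancy(pool, cfg.motif, cfg.mismatch_penalty)
        occ_b = occupancy(pool, cfg.motif_b, cfg.mismatch_penalty)
        in_a = pool.set_labels == "A"
        occ = np.where(in_a, occ_a, occ_b)
        gain = cfg.gain

    values = background + gain * occ * noise
    return IntensityProfile(list(pool.ids), values, np.ones(n, dtype=bool))


@dataclass
class LabeledExperiment:
    """A simulated experiment with its ground-truth pass/fail label."""

    intensities: IntensityProfile
    label: str  # "pass" iff mode == "specific", by construction
    provenance: SimConfig


def random_consensus(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


def sample_pass_config(rng: np.random.Generator) -> SimConfig:
    """Seeded sampler of 'specific' experiments with varying motif length
    (4-8), sharpness, and gain — all inside the strong-signal regime."""
    length = int(rng.integers(4, 9))
    return SimConfig(
        mode="specific",
        motif=random_consensus(rng, length),
        mismatch_penalty=float(rng.uniform(0.1, 0.35)),
        gain=float(10 ** rng.uniform(2.7, 3.3)),
        seed=int(rng.integers(0, 2**31)),
    )


def sample_fail_config(rng: np.random.Generator, kind: str, artifact_kmers: Sequence[str]) -> SimConfig:
    if kind == "nonspecific":
        return SimConfig(mode="nonspecific", gain=0.0, seed=int(rng.integers(0, 2**31)))
    if kind == "artifact":
        return SimConfig(
            mode="artifact",
            artifact_kmer=str(rng.choice(list(artifact_kmers))),
            gain=float(10 ** rng.uniform(2.7, 3.3)),
            seed=int(rng.integers(0, 2**31)),
        )
    if kind == "split_discordant":
        a = random_consensus(rng, 7)
        b = random_consensus(rng, 7)
        while b == a:
            b = random_consensus(rng, 7)
        return SimConfig(
            mode="split_discordant",
            motif=a,
            motif_b=b,
            gain=float(10 ** rng.uniform(2.7, 3.3)),
            seed=int(rng.integers(0, 2**31)),
        )
    raise ValueError(f"unknown failure kind {kind!r}")


def generate_training_collection(
    pool: ProbePool,
    n_pass: int,
    n_fail: int,
    seed: int = 0,
    artifact_kmers: Sequence[str] | None = None,
) -> list[LabeledExperiment]:
    """Labeled pass/fail experiments for classifier training.

    Passes are 'specific' simulations from the seeded motif sampler;
    fails cycle through the three failure modes.  The default sizes used
    in the tests (229 passes, 242 fails) mirror a curated training
    collection of that size.
    """
    if n_pass < 0 or n_fail < 0:
        raise ValueError("n_pass and n_fail must be >= 0")
    if artifact_kmers is None:
        from .qc import ARTIFACT_KMERS

        artifact_kmers = ARTIFACT_KMERS
    rng = np.random.default_rng(seed)
    out: list[LabeledExperiment] = []
    for _ in range(n_pass):
        cfg = sample_pass_config(rng)
        out.append(LabeledExperiment(simulate_experiment(pool, cfg), "pass", cfg))
    kinds = ("nonspecific", "artifact", "split_discordant")
    for j in range(n_fail):
        cfg = sample_fail_config(rng, kinds[j % 3], artifact_kmers)
        out.append(LabeledExperiment(simulate_experiment(pool, cfg), "fail", cfg))
    return out
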