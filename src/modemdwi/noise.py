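"""Rician noise doping of noiseless diffusion signals.

Magnitude MRI data with thermal noise follows a Rician distribution: the
underlying complex signal receives independent zero-mean Gaussian noise on
the real and imaginary channels and the magnitude is taken,

    M(b) = sqrt((S(b) + e1)^2 + e2^2),   e1, e2 ~ Normal(0, sigma^2).

The noise level is quoted as sigma relative to the signal at b = 0 (which is
1 for normalized inputs).  The study levels are 0%, 1%, 5%, 10%, 15%, 20%
and 25%, each applied independently per b-value and repeated many times per
simulated decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SyntheticSignalSet

#: The seven study noise levels (fraction of S at b=0).
NOISE_LEVELS = (0.0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level (SD of each complex channel relative to S(b=0)),
    repetition count and seed."""

    level: float
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"noise level must be >= 0, got {self.level}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def rician_sample(signals: np.ndarray, sigma: float, n_reps: int,
                  rng: np.random.Generator) -> np.ndarray:
    """(n_reps, n_b) Rician magnitudes around the clean ``signals``."""
    s = np.asarray(signals, dtype=float)
    if sigma == 0.0:
        return np.tile(s, (n_reps, 1))
    e1 = rng.normal(0.0, sigma, size=(n_reps, s.size))
    e2 = rng.normal(0.0, sigma, size=(n_reps, s.size))
    return np.sqrt((s + e1) ** 2 + e2 ** 2)


def signal_columns(b_values) -> list[str]:
    """Canonical CSV column names b_0, b_50, ... for a b-value grid."""
    return [f"b_{bv:g}" for bv in b_values]


def add_rician_noise(signal_sets: SyntheticSignalSet | list[SyntheticSignalSet],
                     noise: NoiseSpec) -> pd.DataFrame:
    """Dope one or more noiseless signal sets; one row per noise repetition.

    Rows carry substrate provenance (substrate_id, group_id, level_index,
    repeat, noise_rep, label) plus the magnitude signal at every b-value.
    At level 0 the clean signals are replicated unchanged.  Per-set seeds
    spawn deterministically from ``noise.seed``.
    """
    if isinstance(signal_sets, SyntheticSignalSet):
        signal_sets = [signal_sets]
    if not signal_sets:
        return pd.DataFrame()
    master = np.random.SeedSequence(noise.seed)
    frames = []
    cols = signal_columns(signal_sets[0].b_values)
    for set_i, sset in enumerate(signal_sets):
        ss = np.random.SeedSequence(entropy=master.entropy, spawn_key=(set_i,))
        rng = np.random.default_rng(ss)
        noisy = rician_sample(sset.signals, noise.level, noise.n_reps, rng)
        md = sset.metadata
        df = pd.DataFrame(noisy, columns=cols)
        df.insert(0, "substrate_id", sset.substrate_id)
        df.insert(1, "group_id", md.get("group_id", ""))
        df.insert(2, "level_index", md.get("level_index", -1))
        df.insert(3, "repeat", md.get("repeat", 0))
        df.insert(4, "noise_rep", np.arange(noise.n_reps))
        df.insert(5, "label", md.get("label", -1))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", np.arange(len(out)))
    return out
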