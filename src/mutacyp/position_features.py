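"""Per-position conservation and accessibility descriptors.

Three statistics are computed from a protein profile: Shannon entropy of
the residue distribution at each position, the windowed Z-score of that
entropy (``zsEntropy21``), and the windowed variance of predicted relative
solvent accessibility (``varPredRSA21``). Windows are 21 residues wide by
default, centered on the query position and clipped at sequence termini.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .profile_io import AMINO_ACIDS

MAX_ENTROPY_BITS = math.log2(20)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window policy for position-context statistics.

    width
        Odd window width in residues; the 10 neighbours on each side of the
        center plus the center itself for the default 21.
    include_center
        Whether the center residue participates in the window statistics.
        Included by default: the statistic then stays well defined at
        sequence termini, which is the common convention.
    """

    width: int = 21
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"window width must be a positive odd integer, got {self.width}")

    def indices(self, pos: int, length: int) -> list[int]:
        """1-based window positions for 1-based ``pos``, clipped to [1, length]."""
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside 1..{length}")
        half = self.width // 2
        idx = range(max(1, pos - half), min(length, pos + half) + 1)
        if self.include_center:
            return list(idx)
        return [i for i in idx if i != pos]


def shannon_entropy(observed_pct: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy, in bits, of a residue distribution.

    Accepts the 20 observed percentages of a PSSM row (any nonnegative
    weights; they are normalized internally). An all-zero row — PSI-BLAST
    emits these at positions with no aligned residues — returns the maximal
    uncertainty log2(20).
    """
    if isinstance(observed_pct, Mapping):
        values = [observed_pct[a] for a in AMINO_ACIDS]
    else:
        values = list(observed_pct)
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative percentage in residue distribution")
    total = arr.sum()
    if total == 0:
        return MAX_ENTROPY_BITS
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_track(profile) -> np.ndarray:
    """Per-position entropy (bits) over a ProteinProfile's PSSM percentages."""
    return np.array([shannon_entropy(rec.observed_pct) for rec in profile.positions])


def entropy_zscore(
    entropies: Sequence[float], pos: int, w: WindowConfig = WindowConfig()
) -> float:
    """Z-score of the entropy at ``pos`` against its clipped window.

    z = (H_pos - mean_W) / sd_W with the sample (n-1) standard deviation.
    A zero-spread window (constant entropy) yields z = 0 by convention.
    The result is invariant to the logarithm base of the entropies because
    the linear rescaling cancels.
    """
    ent = np.asarray(entropies, dtype=float)
    if ent.size == 0:
        raise ValueError("empty entropy track")
    idx = np.array(w.indices(pos, ent.size)) - 1
    window = ent[idx]
    if window.size < 2:
        return 0.0
    sd = float(window.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return float((ent[pos - 1] - window.mean()) / sd)


def rsa_window_variance(
    rsa: Sequence[float], pos: int, w: WindowConfig = WindowConfig()
) -> float:
    """Sample variance of predicted RSA over the clipped window at ``pos``.

    Degenerate windows (a single position) have variance 0.
    """
    track = np.asarray(rsa, dtype=float)
    if track.size == 0:
        raise ValueError("empty RSA track")
    idx = np.array(w.indices(pos, track.size)) - 1
    window = track[idx]
    if window.size < 2:
        return 0.0
    return float(window.var(ddof=1))
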