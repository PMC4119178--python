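"""The five-feature vector scored for each missense mutation.

Final feature space (canonical order used throughout the package):

* ``Abs_dSS``      — |SS(pos, wt) - SS(pos, mut)|, the absolute difference of
  PSSM log-odds similarity scores between wild type and mutant residue;
* ``ss_Abs_dSize`` — |size(wt) - size(mut)| · |SS(wt) - SS(mut)|, the residue
  size change weighted by the similarity-score change;
* ``zsEntropy21``  — windowed Z-score of the position's Shannon entropy;
* ``predRSA``      — predicted relative solvent accessibility at the position;
* ``varPredRSA21`` — windowed variance of predicted RSA.

The signed ``dSS``, raw entropy, and unweighted |Δsize| intermediates are kept
on the vector; raw entropy is a strong discriminator in its own right but is
highly anticorrelated with Abs_dSS, so it never enters the model.

Residue "size" is the Zamyatnin residue volume (Å^3), min-max normalized to
[0, 1] so the weight product is scale-free; glycine is the minimum and
tryptophan the maximum of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .position_features import (
    WindowConfig,
    entropy_track,
    entropy_zscore,
    rsa_window_variance,
    shannon_entropy,
)
from .profile_io import (
    MutationRecord,
    ProfileError,
    ProteinProfile,
    validate_against_profile,
)

FEATURE_NAMES = (
    "Abs_dSS",
    "ss_Abs_dSize",
    "zsEntropy21",
    "predRSA",
    "varPredRSA21",
)

#: Zamyatnin residue volumes, Å^3.
RESIDUE_VOLUME_A3: Mapping[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class SizeScale:
    """Amino-acid size scale with a min-max normalized copy in [0, 1]."""

    volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.volumes) != set(RESIDUE_VOLUME_A3):
            raise ValueError("size scale must cover exactly the 20 standard residues")

    @property
    def normalized(self) -> Mapping[str, float]:
        lo = min(self.volumes.values())
        hi = max(self.volumes.values())
        return {a: (v - lo) / (hi - lo) for a, v in self.volumes.items()}

    def size_diff(self, wt: str, mut: str) -> float:
        norm = self.normalized
        return abs(norm[wt] - norm[mut])


DEFAULT_SIZE_SCALE = SizeScale(RESIDUE_VOLUME_A3)


@dataclass(frozen=True)
class FeatureVector:
    """The five model features plus named intermediates for one mutation."""

    abs_dss: float
    ss_abs_dsize: float
    zs_entropy21: float
    pred_rsa: float
    var_pred_rsa21: float
    # intermediates
    dss: float
    entropy: float
    abs_dsize: float

    def as_array(self) -> list[float]:
        """The 5 model features in canonical order."""
        return [
            self.abs_dss,
            self.ss_abs_dsize,
            self.zs_entropy21,
            self.pred_rsa,
            self.var_pred_rsa21,
        ]


def similarity_score(profile: ProteinProfile, position: int, aa: str) -> float:
    """PSSM log-odds similarity score for residue ``aa`` at 1-based position."""
    return float(profile.positions[position - 1].log_odds[aa])


def abs_dss(profile: ProteinProfile, m: MutationRecord) -> float:
    """|SS(wt) - SS(mut)| at the mutated position."""
    validate_against_profile(m, profile)
    return abs(
        similarity_score(profile, m.position, m.wt)
        - similarity_score(profile, m.position, m.mut)
    )


def ss_abs_dsize(
    profile: ProteinProfile,
    m: MutationRecord,
    scale: SizeScale = DEFAULT_SIZE_SCALE,
    *,
    signed_weight: bool = False,
) -> float:
    """Size change weighted by the similarity-score change.

    The weight is |ΔSS| by default so the feature is one-sided and
    nonnegative; ``signed_weight`` switches to the signed ΔSS = SS(wt) -
    SS(mut) variant.
    """
    validate_against_profile(m, profile)
    dss = similarity_score(profile, m.position, m.wt) - similarity_score(
        profile, m.position, m.mut
    )
    weight = dss if signed_weight else abs(dss)
    return scale.size_diff(m.wt, m.mut) * weight


def compute_features(
    profile: ProteinProfile,
    m: MutationRecord,
    w: WindowConfig = WindowConfig(),
    scale: SizeScale = DEFAULT_SIZE_SCALE,
    *,
    entropies: Optional[Sequence[float]] = None,
) -> FeatureVector:
    """Assemble the full feature vector for one validated mutation.

    ``entropies`` may carry a precomputed per-position entropy track for the
    profile (batch callers compute it once); otherwise it is derived here.
    """
    if profile.rsa is None:
        raise ProfileError(
            f"{profile.protein_id}: no RSA track loaded; supply a predicted-RSA "
            "profile (two-column position/value table) alongside the PSSM"
        )
    validate_against_profile(m, profile)
    ss_wt = similarity_score(profile, m.position, m.wt)
    ss_mut = similarity_score(profile, m.position, m.mut)
    dss = ss_wt - ss_mut
    ent = entropy_track(profile) if entropies is None else entropies
    return FeatureVector(
        abs_dss=abs(dss),
        ss_abs_dsize=scale.size_diff(m.wt, m.mut) * abs(dss),
        zs_entropy21=entropy_zscore(ent, m.position, w),
        pred_rsa=float(profile.rsa[m.position - 1]),
        var_pred_rsa21=rsa_window_variance(profile.rsa, m.position, w),
        dss=dss,
        entropy=shannon_entropy(profile.positions[m.position - 1].observed_pct),
        abs_dsize=scale.size_diff(m.wt, m.mut),
    )


def feature_table(
    profiles: Mapping[str, ProteinProfile],
    mutations: Sequence[MutationRecord],
    w: WindowConfig = WindowConfig(),
    scale: SizeScale = DEFAULT_SIZE_SCALE,
) -> pd.DataFrame:
    """Feature rows for a batch of mutations across one or more proteins.

    Columns: protein_id, mutation, the 5 model features under their
    canonical names, the intermediates (dSS, Entropy, Abs_dSize), and the
    label when present.
    """
    rows = []
    entropy_cache: dict[str, object] = {}
    for m in mutations:
        if m.protein_id not in profiles:
            raise ProfileError(f"no profile loaded for protein {m.protein_id!r}")
        if m.protein_id not in entropy_cache:
            entropy_cache[m.protein_id] = entropy_track(profiles[m.protein_id])
        fv = compute_features(profiles[m.protein_id], m, w, scale,
                              entropies=entropy_cache[m.protein_id])
        rows.append(
            {
                "protein_id": m.protein_id,
                "mutation": m.token,
                "Abs_dSS": fv.abs_dss,
                "ss_Abs_dSize": fv.ss_abs_dsize,
                "zsEntropy21": fv.zs_entropy21,
                "predRSA": fv.pred_rsa,
                "varPredRSA21": fv.var_pred_rsa21,
                "dSS": fv.dss,
                "Entropy": fv.entropy,
                "Abs_dSize": fv.abs_dsize,
                "label": m.label,
            }
        )
    return pd.DataFrame(rows)
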