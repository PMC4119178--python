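"""Synthetic profiles, RSA tracks and labeled mutation sets.

Every stage of the pipeline is testable without external databases: this
module emulates the statistical structure the classifier exploits —
deleterious mutations sit at conserved, buried positions in homogeneous
local environments, benign ones at variable, exposed positions.

Two generation paths are provided:

* ``direct`` — class-conditional Gaussian feature vectors whose mean
  separations are set from per-feature F-score targets (with equal
  within-class spread, a mean shift of 2·F standard deviations realizes
  F = |x̄_n - x̄_d|/(σ_n + σ_d) exactly in expectation);
* ``profiles`` — full ASCII PSSMs, autocorrelated RSA tracks and mutation
  lists that run through the real parser and feature extractor.

Per-position residue distributions are Dirichlet draws whose concentration
controls conservation; synthetic log-odds are round(2·log2(p/0.05)) clamped
to the PSI-BLAST integer range [-10, 13]. RSA autocorrelation comes from
moving-average smoothing of uniform noise (default correlation length 10
residues, enough to make the windowed RSA variance informative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mutation_features import FEATURE_NAMES, feature_table
from .profile_io import (
    AMINO_ACIDS,
    BENIGN,
    DELETERIOUS,
    MutationRecord,
    PositionRecord,
    ProteinProfile,
    write_ascii_pssm,
)

#: Published F-score separations of the five features, used as the default
#: class-separation targets of the generator (TS270-like conditions).
DEFAULT_F_TARGETS = (0.73, 0.61, 0.49, 0.47, 0.45)

#: Direction of the deleterious shift per feature: score differences grow,
#: entropy Z-score, exposure and local RSA variance drop.
FEATURE_SIGNS = (+1.0, +1.0, -1.0, -1.0, -1.0)

#: Plausible benign-class (mean, sd) per feature for the direct path.
_BASE_MOMENTS = (
    (2.0, 2.2),    # Abs_dSS
    (0.4, 0.55),   # ss_Abs_dSize
    (0.3, 1.0),    # zsEntropy21
    (0.45, 0.20),  # predRSA
    (0.040, 0.022),  # varPredRSA21
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults shape the training conditions of the method: 270 mutations in
    a 197:73 deleterious:benign split, conserved/buried deleterious sites,
    and the published per-feature F-score separations.
    """

    length: int = 0  # 0 = auto: 22 residues per designated site, min 500
    n_benign: int = 73
    n_deleterious: int = 197
    conc_deleterious: float = 30.0  # Dirichlet weight on the dominant residue
    conc_benign: float = 1.0        # uniform Dirichlet concentration
    rsa_autocorr: int = 10          # moving-average smoothing length, residues
    rsa_buried_mean: float = 0.12
    rsa_exposed_mean: float = 0.65
    f_targets: tuple[float, ...] = DEFAULT_F_TARGETS
    separation_scale: float = 1.0   # multiplies every F target
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_deleterious < 1:
            raise ValueError("need at least one mutation per class")
        if self.conc_deleterious <= 0 or self.conc_benign <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if len(self.f_targets) != len(FEATURE_NAMES):
            raise ValueError(f"need {len(FEATURE_NAMES)} F-score targets")

    @property
    def effective_length(self) -> int:
        """Protein length; auto mode sizes a concatenated panel so that
        designated sites rarely share a 21-residue window."""
        if self.length > 0:
            return self.length
        return max(500, 22 * (self.n_benign + self.n_deleterious))


@dataclass
class SimulatedData:
    """A generated dataset plus, for the profile path, its raw inputs."""

    features: pd.DataFrame
    labels: list[str]
    profile: Optional[ProteinProfile] = None
    mutations: Optional[list[MutationRecord]] = None


def _site_plan(cfg: SimConfig, rng: np.random.Generator):
    """Jittered-grid site placement: one site per equal-length block keeps
    designated sites spread out, so neighbouring windows seldom mix class
    environments; class assignment is a random shuffle over the grid."""
    length = cfg.effective_length
    n_sites = cfg.n_benign + cfg.n_deleterious
    if n_sites > length:
        raise ValueError(
            f"{n_sites} designated sites do not fit a length-{length} protein"
        )
    block = length / n_sites
    offsets = rng.integers(0, max(1, int(block)), size=n_sites)
    sites = np.minimum((np.arange(n_sites) * block).astype(int) + offsets,
                       length - 1) + 1  # 1-based
    classes = np.array([DELETERIOUS] * cfg.n_deleterious
                       + [BENIGN] * cfg.n_benign)
    rng.shuffle(classes)
    return sites[classes == DELETERIOUS], sites[classes == BENIGN]


def _smooth(noise: np.ndarray, span: int) -> np.ndarray:
    if span <= 1:
        return noise
    kernel = np.ones(span) / span
    padded = np.concatenate([noise[:span][::-1], noise, noise[-span:][::-1]])
    return np.convolve(padded, kernel, mode="same")[span:-span]


def _build_profile(cfg: SimConfig, rng: np.random.Generator):
    length = cfg.effective_length
    del_sites, ben_sites = _site_plan(cfg, rng)
    del_set = set(del_sites.tolist())

    background = 1.0 / 20.0
    records: list[PositionRecord] = []
    seq = []
    for pos in range(1, length + 1):
        if pos in del_set:
            alpha = np.full(20, 0.25)
            alpha[rng.integers(20)] = cfg.conc_deleterious
        else:
            alpha = np.full(20, cfg.conc_benign)
        p = rng.dirichlet(alpha)
        dominant = int(np.argmax(p))
        residue = AMINO_ACIDS[dominant]
        with np.errstate(divide="ignore"):
            lo = np.round(2.0 * np.log2(np.where(p > 0, p, 1e-12) / background))
        lo = np.clip(lo, -10, 13)
        pct = np.round(p * 100.0)
        records.append(
            PositionRecord(
                index=pos,
                residue=residue,
                log_odds=dict(zip(AMINO_ACIDS, lo.astype(float))),
                observed_pct=dict(zip(AMINO_ACIDS, pct.astype(float))),
            )
        )
        seq.append(residue)

    rsa = _smooth(rng.uniform(0.0, 1.0, length), cfg.rsa_autocorr)
    # positions within half a window of a designated site take that site's
    # class burial level (nearest site wins), giving buried homogeneous
    # deleterious neighbourhoods and exposed noisier benign ones
    half = 10
    all_sites = np.concatenate([del_sites, ben_sites])
    order = np.argsort(all_sites)
    sorted_sites = all_sites[order]
    is_del_site = np.concatenate(
        [np.ones(len(del_sites), bool), np.zeros(len(ben_sites), bool)]
    )[order]
    pos_arr = np.arange(1, length + 1)
    right = np.searchsorted(sorted_sites, pos_arr)
    left = np.clip(right - 1, 0, len(sorted_sites) - 1)
    right = np.clip(right, 0, len(sorted_sites) - 1)
    d_left = np.abs(pos_arr - sorted_sites[left])
    d_right = np.abs(sorted_sites[right] - pos_arr)
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    near_del = (dist <= half) & is_del_site[nearest]
    near_ben = (dist <= half) & ~is_del_site[nearest]
    noise = rng.uniform(-1.0, 1.0, length)
    rsa[near_del] = cfg.rsa_buried_mean + 0.03 * noise[near_del]
    rsa[near_ben] = cfg.rsa_exposed_mean + 0.12 * noise[near_ben]
    rsa = np.clip(rsa, 0.0, 1.0)
    profile = ProteinProfile(
        protein_id="synthetic",
        sequence="".join(seq),
        positions=records,
        rsa=rsa.tolist(),
    )
    return profile, del_sites, ben_sites


def simulate_profile(cfg: SimConfig) -> ProteinProfile:
    """Generate one protein profile under the configured conditions."""
    return _build_profile(cfg, np.random.default_rng(cfg.seed))[0]


def _mutations_for(profile: ProteinProfile, sites: Sequence[int], label: str,
                   rng: np.random.Generator) -> list[MutationRecord]:
    muts = []
    for pos in sites:
        rec = profile.positions[pos - 1]
        wt = rec.residue
        others = [a for a in AMINO_ACIDS if a != wt]
        if label == DELETERIOUS:
            # hardest substitution: most-penalized residue at a conserved site
            mut = min(others, key=lambda a: (rec.log_odds[a], a))
        else:
            mut = max(others, key=lambda a: (rec.log_odds[a], a))
        muts.append(
            MutationRecord(protein_id=profile.protein_id, position=int(pos),
                           wt=wt, mut=mut, label=label)
        )
    return muts


def _direct_dataset(cfg: SimConfig, rng: np.random.Generator) -> SimulatedData:
    n_b, n_d = cfg.n_benign, cfg.n_deleterious
    cols = {}
    for j, name in enumerate(FEATURE_NAMES):
        mu_b, sd = _BASE_MOMENTS[j]
        shift = FEATURE_SIGNS[j] * 2.0 * cfg.f_targets[j] * cfg.separation_scale * sd
        ben = rng.normal(mu_b, sd, n_b)
        dele = rng.normal(mu_b + shift, sd, n_d)
        cols[name] = np.concatenate([dele, ben])
    labels = [DELETERIOUS] * n_d + [BENIGN] * n_b
    return SimulatedData(features=pd.DataFrame(cols), labels=labels)


def simulate_dataset(cfg: SimConfig, mode: str = "direct") -> SimulatedData:
    """Generate a labeled feature table.

    ``direct`` draws feature vectors with the configured class separations;
    ``profiles`` builds a full synthetic profile, places mutations on the
    designated sites, and extracts features through the real pipeline.
    """
    rng = np.random.default_rng(cfg.seed)
    if mode == "direct":
        return _direct_dataset(cfg, rng)
    if mode != "profiles":
        raise ValueError(f"unknown mode {mode!r}")
    profile, del_sites, ben_sites = _build_profile(cfg, rng)
    muts = _mutations_for(profile, del_sites, DELETERIOUS, rng) + _mutations_for(
        profile, ben_sites, BENIGN, rng
    )
    table = feature_table({profile.protein_id: profile}, muts)
    return SimulatedData(
        features=table[list(FEATURE_NAMES)],
        labels=[m.label for m in muts],
        profile=profile,
        mutations=muts,
    )


def write_fixture_dir(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Emit PSSM, RSA TSV, mutation TSV and a manifest for a simulated protein.

    Byte-identical across runs with the same configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg, mode="profiles")
    assert data.profile is not None and data.mutations is not None
    (out / "synthetic.pssm").write_text(write_ascii_pssm(data.profile))
    rsa_lines = [
        f"{i}\t{v:.6f}" for i, v in enumerate(data.profile.rsa or [], start=1)
    ]
    (out / "synthetic.rsa.tsv").write_text("\n".join(rsa_lines) + "\n")
    mut_lines = ["protein_id\tmutation\tlabel"] + [
        f"{m.protein_id}\t{m.token}\t{m.label}" for m in data.mutations
    ]
    (out / "synthetic.mutations.tsv").write_text("\n".join(mut_lines) + "\n")
    manifest = {
        "protein_id": data.profile.protein_id,
        "length": len(data.profile),
        "n_mutations": len(data.mutations),
        "n_deleterious": sum(m.label == DELETERIOUS for m in data.mutations),
        "n_benign": sum(m.label == BENIGN for m in data.mutations),
        "seed": cfg.seed,
        "files": ["synthetic.pssm", "synthetic.rsa.tsv", "synthetic.mutations.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
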