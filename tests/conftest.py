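import numpy as np
import pytest

from mutacyp.profile_io import AMINO_ACIDS, PositionRecord, ProteinProfile


def make_pssm_text(rows):
    """Build an NCBI-layout ASCII PSSM from (residue, log_odds[20], pct[20])
    triples, columns in canonical ARND... order."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    for i, (res, lo, pct) in enumerate(rows, start=1):
        lo_s = " ".join(f"{v:3g}" for v in lo)
        pct_s = " ".join(f"{v:4g}" for v in pct)
        lines.append(f"{i:5d} {res}  {lo_s}  {pct_s}  0.36 0.12")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1338     0.3114",
    ]
    return "\n".join(lines)


def make_profile(protein_id, residues, log_odds_rows, pct_rows, rsa=None):
    positions = [
        PositionRecord(
            index=i + 1,
            residue=res,
            log_odds=dict(zip(AMINO_ACIDS, lo)),
            observed_pct=dict(zip(AMINO_ACIDS, pct)),
        )
        for i, (res, lo, pct) in enumerate(zip(residues, log_odds_rows, pct_rows))
    ]
    return ProteinProfile(
        protein_id=protein_id, sequence="".join(residues),
        positions=positions, rsa=rsa,
    )


def random_profile(rng, length=60, with_rsa=True):
    """A structureless random profile for oracle comparisons."""
    residues, lo_rows, pct_rows = [], [], []
    for _ in range(length):
        p = rng.dirichlet(np.full(20, 0.7))
        lo = np.clip(np.round(2 * np.log2(np.maximum(p, 1e-12) / 0.05)), -10, 13)
        residues.append(AMINO_ACIDS[int(np.argmax(p))])
        lo_rows.append(lo.tolist())
        pct_rows.append(np.round(p * 100).tolist())
    rsa = rng.uniform(0, 1, length).tolist() if with_rsa else None
    return make_profile("rand", residues, lo_rows, pct_rows, rsa)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_pssm_text():
    """Three-position hand fixture: query M-K-V with simple integer blocks."""
    lo_m = [0, -1, -2, -3, -1, 0, -2, -3, -2, 1, 2, -1, 6, 0, -2, -1, -1, -1, -1, 1]
    pct_m = [0, 0, 0, 0, 0, 0, 0, 0, 0, 8, 12, 0, 75, 0, 0, 0, 0, 0, 0, 5]
    lo_k = [-1, 2, 0, -1, -3, 1, 1, -2, -1, -3, -2, 5, -1, -3, -1, 0, -1, -3, -2, -2]
    pct_k = [0, 15, 0, 0, 0, 5, 10, 0, 0, 0, 0, 65, 0, 0, 0, 5, 0, 0, 0, 0]
    lo_v = [0, -3, -3, -3, -1, -2, -2, -3, -3, 3, 1, -2, 1, -1, -2, -2, 0, -3, -1, 4]
    pct_v = [5, 0, 0, 0, 0, 0, 0, 0, 0, 20, 5, 0, 0, 0, 0, 0, 0, 0, 0, 70]
    return make_pssm_text([("M", lo_m, pct_m), ("K", lo_k, pct_k), ("V", lo_v, pct_v)])
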