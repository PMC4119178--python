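"""Readers and validators for the external inputs of the pipeline.

Four kinds of input are consumed:

* ASCII position-specific scoring matrices (PSSMs) in the NCBI PSI-BLAST
  layout — per-position log-odds similarity scores and weighted observed
  residue percentages;
* per-residue predicted relative solvent accessibility (RSA) profiles as
  plain two-column tables with values in [0, 1] (or a declared 0-100 scale);
* protein sequences in FASTA;
* mutation tables whose rows carry a protein id, a substitution token in
  one-letter ``WT<pos>MUT`` notation (e.g. ``I462V``) and an optional
  benign/deleterious label.

Coordinates are 1-based everywhere (matching mutation nomenclature); the
single 0-based conversion happens inside :func:`validate_against_profile`
and the feature extractors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
"""The 20 standard residues, in NCBI PSSM column order."""

_AA_SET = frozenset(AMINO_ACIDS)

BENIGN = "benign"
DELETERIOUS = "deleterious"

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class ProfileError(ValueError):
    """Base class for malformed or inconsistent profile inputs."""


class PSSMParseError(ProfileError):
    """Raised when an ASCII PSSM does not follow the expected layout."""


class RSAError(ProfileError):
    """Raised for malformed or out-of-range RSA profiles."""


class MutationFormatError(ProfileError):
    """Raised for malformed mutation tokens."""


class SynonymousMutationError(MutationFormatError):
    """Raised when wild-type and mutant residues are identical."""


class MutationMismatchError(ProfileError):
    """Raised when a mutation does not fit the protein profile."""


@dataclass(frozen=True)
class PositionRecord:
    """PSSM content for one residue position.

    ``log_odds`` holds the similarity scores (log-odds block of the PSSM);
    ``observed_pct`` the sequence-weighted observed residue percentages.
    Both map each of the 20 standard amino acids to a value.
    """

    index: int
    residue: str
    log_odds: Mapping[str, float]
    observed_pct: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.log_odds) != _AA_SET or set(self.observed_pct) != _AA_SET:
            raise ProfileError(
                f"position {self.index}: need exactly one log-odds and one "
                "percentage entry per standard amino acid"
            )
        if any(v < 0 for v in self.observed_pct.values()):
            raise ProfileError(f"position {self.index}: negative percentage")
        if self.residue not in _AA_SET and self.residue != "X":
            raise ProfileError(
                f"position {self.index}: residue {self.residue!r} is not a "
                "standard amino acid or X"
            )


@dataclass(frozen=True)
class ProteinProfile:
    """PSSM-derived per-position data for one protein, plus optional RSA."""

    protein_id: str
    sequence: str
    positions: Sequence[PositionRecord]
    rsa: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.sequence):
            raise ProfileError(
                f"{self.protein_id}: {len(self.positions)} PSSM rows for a "
                f"sequence of length {len(self.sequence)}"
            )
        for i, (rec, aa) in enumerate(zip(self.positions, self.sequence)):
            if rec.residue != aa:
                raise ProfileError(
                    f"{self.protein_id}: PSSM residue {rec.residue} at "
                    f"position {i + 1} disagrees with sequence residue {aa}"
                )
        if self.rsa is not None:
            if len(self.rsa) != len(self.sequence):
                raise ProfileError(
                    f"{self.protein_id}: RSA track length {len(self.rsa)} != "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_rsa(self, rsa: Sequence[float]) -> "ProteinProfile":
        return replace(self, rsa=list(rsa))


@dataclass(frozen=True)
class MutationRecord:
    """One missense substitution: ``wt`` at 1-based ``position`` → ``mut``."""

    protein_id: str
    position: int
    wt: str
    mut: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise SynonymousMutationError(
                f"{self.wt}{self.position}{self.mut}: synonymous substitution"
            )
        for aa in (self.wt, self.mut):
            if aa not in _AA_SET:
                raise MutationFormatError(
                    f"{aa!r} is not a standard one-letter amino acid"
                )
        if self.position < 1:
            raise MutationFormatError(
                f"position {self.position} is not a 1-based coordinate"
            )

    @property
    def token(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


def parse_ascii_pssm(text: str) -> tuple[str, list[PositionRecord]]:
    """Parse an NCBI PSI-BLAST ASCII PSSM into (sequence, position records).

    The amino-acid order of the 40 data columns is taken from the file's own
    header row, never assumed fixed. Data rows must carry 44 whitespace
    fields: index, residue, 20 log-odds, 20 percentages, and two trailing
    per-position statistics (information content, relative weight).
    """
    lines = text.splitlines()
    header_cols: Optional[list[str]] = None
    header_line_no = -1
    for ln_no, line in enumerate(lines, start=1):
        fields = line.split()
        if len(fields) == 40 and all(f in _AA_SET and len(f) == 1 for f in fields):
            header_cols = fields
            header_line_no = ln_no
            break
    if header_cols is None:
        raise PSSMParseError("no 40-letter amino-acid header row found")
    lo_order = header_cols[:20]
    pct_order = header_cols[20:]
    if set(lo_order) != _AA_SET or set(pct_order) != _AA_SET:
        raise PSSMParseError(
            f"line {header_line_no}: header does not list each standard "
            "amino acid once per block"
        )

    records: list[PositionRecord] = []
    seq_chars: list[str] = []
    prev_index = 0
    for ln_no, line in enumerate(
        lines[header_line_no:], start=header_line_no + 1
    ):
        fields = line.split()
        if not fields:
            continue
        if not fields[0].isdigit():
            break  # trailing K/lambda statistics block
        if len(fields) != 44:
            raise PSSMParseError(
                f"line {ln_no}: expected 44 columns "
                f"(index, residue, 20 scores, 20 percentages, 2 statistics), "
                f"got {len(fields)}"
            )
        index = int(fields[0])
        if index != prev_index + 1:
            raise PSSMParseError(
                f"line {ln_no}: position index {index} follows {prev_index}; "
                "indices must be 1-based and strictly consecutive"
            )
        prev_index = index
        residue = fields[1]
        try:
            lo_vals = [float(v) for v in fields[2:22]]
            pct_vals = [float(v) for v in fields[22:42]]
        except ValueError as exc:
            raise PSSMParseError(f"line {ln_no}: non-numeric field: {exc}") from exc
        records.append(
            PositionRecord(
                index=index,
                residue=residue,
                log_odds=dict(zip(lo_order, lo_vals)),
                observed_pct=dict(zip(pct_order, pct_vals)),
            )
        )
        seq_chars.append(residue)
    if not records:
        raise PSSMParseError("no data rows found after the header")
    return "".join(seq_chars), records


def write_ascii_pssm(profile: ProteinProfile) -> str:
    """Serialize a profile back to the NCBI ASCII PSSM layout.

    Round-trips through :func:`parse_ascii_pssm` with identical log-odds,
    percentages, and sequence.
    """
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    for rec in profile.positions:
        lo = " ".join(f"{rec.log_odds[a]:3g}" for a in AMINO_ACIDS)
        pct = " ".join(f"{rec.observed_pct[a]:4g}" for a in AMINO_ACIDS)
        out.append(f"{rec.index:5d} {rec.residue}  {lo}  {pct}  0.00 0.00")
    out.append("")
    return "\n".join(out)


def read_rsa_profile(text: str, *, percent_scale: bool = False) -> list[float]:
    """Read a per-residue RSA track from a two-column (position, value) table.

    One bare value per line is also accepted. Values must lie in [0, 1]
    unless ``percent_scale`` declares the 0-100 scale, in which case they are
    divided by 100.
    """
    entries: dict[int, float] = {}
    bare: list[float] = []
    for ln_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            if len(fields) == 1:
                bare.append(float(fields[0]))
                continue
            if len(fields) == 2:
                entries[int(fields[0])] = float(fields[1])
                continue
        except ValueError as exc:
            raise RSAError(f"line {ln_no}: {exc}") from exc
        raise RSAError(f"line {ln_no}: expected 1 or 2 columns, got {len(fields)}")
    if entries and bare:
        raise RSAError("mixed positional and bare-value lines")
    if entries:
        expected = range(1, max(entries) + 1)
        missing = [i for i in expected if i not in entries]
        if missing:
            raise RSAError(f"missing positions: {missing}")
        values = [entries[i] for i in expected]
    else:
        values = bare
    hi = 100.0 if percent_scale else 1.0
    for i, v in enumerate(values, start=1):
        if not 0.0 <= v <= hi:
            raise RSAError(
                f"position {i}: RSA value {v} outside [0, {hi:g}] "
                f"({'0-100' if percent_scale else '0-1'} scale)"
            )
    if percent_scale:
        values = [v / 100.0 for v in values]
    return values


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (id, sequence) pairs."""
    entries: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            entries.append((line[1:].split()[0], []))
        else:
            if not entries:
                raise ProfileError("FASTA sequence data before any header")
            entries[-1][1].append(line)
    return [(name, "".join(chunks)) for name, chunks in entries]


def parse_mutation(
    token: str, *, protein_id: str = "", label: Optional[str] = None
) -> MutationRecord:
    """Parse a ``WT<pos>MUT`` token such as ``I462V`` into a MutationRecord."""
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise MutationFormatError(
            f"{token!r} does not match the WT<position>MUT one-letter pattern"
        )
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MutationRecord(
        protein_id=protein_id, position=pos, wt=wt, mut=mut, label=label
    )


def read_mutation_table(text: str) -> list[MutationRecord]:
    """Read a mutation TSV: ``protein_id<TAB>token[<TAB>label]`` per row.

    Labels, when present, must be ``benign`` or ``deleterious``. A header
    row starting with ``protein_id`` is skipped.
    """
    records: list[MutationRecord] = []
    for ln_no, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "protein_id":
            continue
        if len(fields) not in (2, 3):
            raise MutationFormatError(
                f"line {ln_no}: expected 2 or 3 tab-separated columns, "
                f"got {len(fields)}"
            )
        label = None
        if len(fields) == 3 and fields[2].strip():
            label = fields[2].strip().lower()
            if label not in (BENIGN, DELETERIOUS):
                raise MutationFormatError(
                    f"line {ln_no}: label {fields[2]!r} is neither "
                    f"'{BENIGN}' nor '{DELETERIOUS}'"
                )
        try:
            records.append(
                parse_mutation(fields[1], protein_id=fields[0].strip(), label=label)
            )
        except MutationFormatError as exc:
            raise MutationFormatError(f"line {ln_no}: {exc}") from exc
    return records


def validate_against_profile(
    m: MutationRecord, p: ProteinProfile
) -> MutationRecord:
    """Check that a mutation's coordinate and wild-type residue fit a profile."""
    if not 1 <= m.position <= len(p):
        raise MutationMismatchError(
            f"{m.token}: position {m.position} outside 1..{len(p)} "
            f"of {p.protein_id}"
        )
    observed = p.sequence[m.position - 1]
    if observed == "X":
        raise MutationMismatchError(
            f"{m.token}: position {m.position} of {p.protein_id} is an "
            "undetermined residue (X); mutations there cannot be scored"
        )
    if observed != m.wt:
        raise MutationMismatchError(
            f"{m.token}: expected wild-type {m.wt} at position {m.position} "
            f"of {p.protein_id}, profile has {observed}"
        )
    return m


def load_cs30() -> list[MutationRecord]:
    """Load the packaged 30-variant literature control set (CS30).

    29 deleterious and 1 benign variant across four human CYPs (CYP7B1,
    CYP21A2, CYP11B1, CYP27B1), collected from clinical reports absent
    from the training catalogue.
    """
    from importlib import resources

    text = (
        resources.files("mutacyp").joinpath("data/cs30.tsv").read_text("utf-8")
    )
    return read_mutation_table(text)
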