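"""Sequence-derived quantities for promoter spacers.

Everything here operates on the spacer of a bacterial sigma70 promoter:
the segment between the -35 and -10 hexamers, written 5'->3' on the sense
strand with position 1 adjacent to the -35 element and position L adjacent
to the -10 element.  Under that convention the extended -10 motif (the
5'-TG-3' dinucleotide of TGn-TATAAT geometry) occupies positions (L-2, L-1),
leaving exactly one base between the motif and the -10 hexamer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpacerSeq",
    "MotifReport",
    "MeltingProfile",
    "LogoMatrix",
    "NN_DG37",
    "MINUS10_CONSENSUS",
    "MINUS35_CONSENSUS",
    "gc_content",
    "count_tg",
    "extended_minus10",
    "consensus_mismatches",
    "melting_profile",
    "logo",
    "complement",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MINUS10_CONSENSUS = "TATAAT"
MINUS35_CONSENSUS = "TTGACA"

# Unified nearest-neighbor free energies, Watson-Crick dimer duplexes,
# Delta-G(37 C) in kcal/mol (SantaLucia 1998 unified parameter set).  Stored
# in the stability-to-melt convention used throughout this package: the sign
# is flipped so that a LARGER value means the step is HARDER to melt.
# Only the 10 unique dimers are listed; the rest follow by reverse complement.
NN_DG37: dict[str, float] = {
    "AA": 1.00,  # == TT
    "AT": 0.88,
    "TA": 0.58,
    "CA": 1.45,  # == TG
    "GT": 1.44,  # == AC
    "CT": 1.28,  # == AG
    "GA": 1.30,  # == TC
    "CG": 2.17,
    "GC": 2.24,
    "GG": 1.84,  # == CC
}


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, *, what: str = "sequence") -> str:
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError(f"{what} must be a non-empty string")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT characters {sorted(bad)}; "
            "degenerate IUPAC bases are rejected"
        )
    return seq


@dataclass(frozen=True)
class SpacerSeq:
    """A promoter spacer sequence over the strict {A,C,G,T} alphabet.

    Positions are 1-based, 5'->3', with position 1 adjacent to the -35
    hexamer and position ``length`` adjacent to the -10 hexamer.
    """

    seq: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        seq = _validate_dna(self.seq, what="spacer")
        if not 1 <= len(seq) <= 50:
            raise ValueError(f"spacer length {len(seq)} outside 1..50")
        object.__setattr__(self, "seq", seq)
        object.__setattr__(self, "length", len(seq))

    def __str__(self) -> str:
        return self.seq


def _as_seq(s: "SpacerSeq | str") -> str:
    return s.seq if isinstance(s, SpacerSeq) else SpacerSeq(s).seq


@dataclass(frozen=True)
class MotifReport:
    """TG-motif content of a spacer.

    tg_count counts every TG dinucleotide window in the spacer;
    tandem_len is the number of consecutive TG units ending at the
    extended -10 window (0 when the motif is absent).
    """

    tg_count: int
    has_extended_minus10: bool
    tandem_len: int


@dataclass(frozen=True)
class MeltingProfile:
    """Per-dinucleotide-step melting energies along a spacer, kcal/mol.

    Larger values mean the step is harder to melt (stability-to-melt
    convention; the negative of the duplex formation free energy).
    """

    step_energies: np.ndarray
    mean_energy: float


@dataclass(frozen=True)
class LogoMatrix:
    """Column base frequencies and per-position information content.

    ``freq`` is 4 x L with rows in A, C, G, T order and columns summing
    to 1; ``ic`` is the per-position information content in bits,
    ic = 2 - H where H is the Shannon entropy of the column.
    """

    freq: np.ndarray
    ic: np.ndarray

    ROWS = ("A", "C", "G", "T")


def gc_content(s: "SpacerSeq | str") -> float:
    """Fraction of G+C bases, in [0, 1]."""
    seq = _as_seq(s)
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_tg(s: "SpacerSeq | str") -> int:
    """Number of positions i with s[i..i+1] == 'TG' (every window counted)."""
    seq = _as_seq(s)
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "TG")


def extended_minus10(s: "SpacerSeq | str") -> MotifReport:
    """Detect the extended -10 TG motif and any tandem TG run ending there.

    The extended -10 window is positions (L-2, L-1): one base is left
    between the motif and the -10 hexamer (TGn-TATAAT geometry).
    ``tandem_len`` is the largest k such that positions L-2k .. L-1 read
    'TG' repeated k times.
    """
    seq = _as_seq(s)
    L = len(seq)
    if L < 4:
        raise ValueError(f"spacer of length {L} too short for extended -10 analysis (need >= 4)")
    k = 0
    while 2 * (k + 1) <= L - 1 and seq[L - 1 - 2 * (k + 1) : L - 1] == "TG" * (k + 1):
        k += 1
    return MotifReport(
        tg_count=count_tg(seq), has_extended_minus10=k >= 1, tandem_len=k
    )


def consensus_mismatches(minus10: str, minus35: str) -> int:
    """Total Hamming distance of the two hexamers to TATAAT and TTGACA."""
    m10 = _validate_dna(minus10, what="-10 hexamer")
    m35 = _validate_dna(minus35, what="-35 hexamer")
    if len(m10) != 6 or len(m35) != 6:
        raise ValueError("hexamers must be exactly 6 bases long")
    d10 = sum(a != b for a, b in zip(m10, MINUS10_CONSENSUS))
    d35 = sum(a != b for a, b in zip(m35, MINUS35_CONSENSUS))
    return d10 + d35


def step_energy(dimer: str) -> float:
    """Melting energy of a single dinucleotide step, kcal/mol."""
    dimer = _validate_dna(dimer, what="dinucleotide")
    if len(dimer) != 2:
        raise ValueError("a step is exactly 2 bases")
    if dimer in NN_DG37:
        return NN_DG37[dimer]
    return NN_DG37[reverse_complement(dimer)]


def melting_profile(s: "SpacerSeq | str") -> MeltingProfile:
    """Nearest-neighbor melting-energy profile along a spacer.

    Returns one value per dinucleotide step (L-1 values) plus their mean.
    Duplex symmetry makes the profile of a reverse complement the reverse
    of the original, so the mean is strand-invariant.
    """
    seq = _as_seq(s)
    if len(seq) < 2:
        raise ValueError("melting profile needs at least 2 bases")
    steps = np.array(
        [step_energy(seq[i : i + 2]) for i in range(len(seq) - 1)], dtype=float
    )
    return MeltingProfile(step_energies=steps, mean_energy=float(steps.mean()))


def logo(seqs, *, small_sample_correction: bool = False) -> LogoMatrix:
    """Base-frequency matrix and per-position information content (bits).

    All sequences must be the same length and strictly ACGT.  Information
    content is the uncorrected 2 - H form by default; the small-sample
    correction subtracts the Miller-Madow bias term 3 / (2 ln 2 N).
    """
    seqs = [_as_seq(s) for s in seqs]
    if len(seqs) == 0:
        raise ValueError("logo requires at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("logo requires equal-length sequences (ragged input)")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    freq = np.empty((4, L))
    for r, base in enumerate(LogoMatrix.ROWS):
        freq[r] = (arr == base.encode()).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2) * len(seqs))
    ic = np.clip(ic, 0.0, 2.0)
    return LogoMatrix(freq=freq, ic=ic)
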