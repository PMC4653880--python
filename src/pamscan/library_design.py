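"""Randomized-PAM library design and combinatorial accounting.

Models the two randomized-library layouts used for in vitro PAM read-out:
a 5-bp fully randomized window (1,024 PAM combinations) and a 7-bp window
assembled from four sublibraries of six random residues plus one fixed
residue (G/C/A/T), giving 16,384 combinations.  Operations cover library
diversity, the sequencing depth rule (at least five reads per possible PAM),
the molar concentration of a degenerate PAM pattern inside a digest, and the
expected genomic spacing of target sites licensed by a PAM pattern.

Coordinate convention: PAM positions are 1-based; position 1 is the first
base 3' of the protospacer, read on the protospacer-containing strand.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from .counts import PamCountTable

#: the 15 standard IUPAC nucleotide codes -> set of concrete bases
IUPAC_CODES: dict[str, frozenset[str]] = {
    code: frozenset(ambiguous_dna_values[code])
    for code in "ACGTRYSWKMBDHVN"
}

#: reverse lookup: frozenset of bases -> tightest IUPAC code
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_DNA = frozenset("ACGT")


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate nucleotide pattern such as ``NGG`` or ``NNAGAAW``.

    U is normalized to T on input; any character outside the 15-code IUPAC
    nucleotide alphabet raises ``ValueError`` naming the offending position.
    """

    pattern: str

    def __post_init__(self) -> None:
        pat = _normalize_seq(self.pattern)
        if not pat:
            raise ValueError("empty IUPAC pattern")
        for i, ch in enumerate(pat):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"illegal IUPAC code {ch!r} at position {i + 1} of {pat!r}"
                )
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        """Allowed bases at each position."""
        return tuple(IUPAC_CODES[c] for c in self.pattern)

    def matches(self, seq: str) -> bool:
        """True if ``seq`` (concrete DNA, same length) fits the pattern."""
        seq = _normalize_seq(seq)
        if len(seq) != len(self.pattern):
            return False
        return all(b in s for b, s in zip(seq, self.position_sets))

    def size(self) -> int:
        """Number of concrete sequences matched (product of code cardinalities)."""
        return math.prod(len(s) for s in self.position_sets)

    def match_probability(self) -> float:
        """Probability a random i.i.d. equal-composition window matches."""
        return math.prod(len(s) / 4.0 for s in self.position_sets)


def _as_pattern(pattern: "IupacPattern | str") -> IupacPattern:
    return pattern if isinstance(pattern, IupacPattern) else IupacPattern(pattern)


@dataclass(frozen=True)
class LibraryScheme:
    """Declarative description of one randomized-PAM plasmid construct.

    ``left_flank`` ends at the protospacer/PAM junction (its 3' terminal 12 nt
    are the left extraction anchor); ``right_flank`` starts immediately 3' of
    the randomized window.  ``sublibraries`` records the 6-random+1-fixed
    partitioning of the 7-bp library as (1-based fixed position, fixed base)
    pairs whose bases must partition {A, C, G, T} exactly.
    ``total_conc`` is the library DNA concentration in a digest (nM).
    """

    name: str
    spacer: str
    left_flank: str
    right_flank: str
    pam_len: int
    sublibraries: tuple[tuple[int, str], ...] | None = None
    total_conc: float = 5.6

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", _normalize_seq(self.spacer))
        object.__setattr__(self, "left_flank", _normalize_seq(self.left_flank))
        object.__setattr__(self, "right_flank", _normalize_seq(self.right_flank))
        for label, seq in (("spacer", self.spacer),
                           ("left_flank", self.left_flank),
                           ("right_flank", self.right_flank)):
            if set(seq) - _DNA:
                raise ValueError(f"{label} contains non-ACGT characters: {seq!r}")
        if len(self.left_flank) < 12 or len(self.right_flank) < 12:
            raise ValueError("flanks must be at least 12 nt (extraction anchors)")
        if self.pam_len < 1:
            raise ValueError("pam_len must be >= 1")
        if self.total_conc < 0:
            raise ValueError("total_conc must be >= 0")
        if self.sublibraries is not None:
            subs = tuple((int(p), _normalize_seq(b)) for p, b in self.sublibraries)
            bases = [b for _, b in subs]
            if sorted(bases) != sorted(_DNA):
                raise ValueError(
                    "sublibrary fixed bases must partition A/C/G/T exactly once each"
                )
            for p, _ in subs:
                if not 1 <= p <= self.pam_len:
                    raise ValueError(f"sublibrary fixed position {p} outside PAM window")
            object.__setattr__(self, "sublibraries", subs)

    # -- anchors and sequences ------------------------------------------------

    @property
    def left12(self) -> str:
        """12-nt left extraction anchor (3' end of the left flank)."""
        return self.left_flank[-12:]

    @property
    def right12(self) -> str:
        """12-nt right extraction anchor (5' end of the right flank)."""
        return self.right_flank[:12]

    def construct(self, pam: str) -> str:
        """Full construct sequence around one concrete PAM."""
        pam = _normalize_seq(pam)
        if len(pam) != self.pam_len or set(pam) - _DNA:
            raise ValueError(f"PAM {pam!r} must be {self.pam_len} nt of ACGT")
        return self.left_flank + pam + self.right_flank

    def all_pams(self) -> Iterator[str]:
        """Every concrete PAM of the randomized window, lexicographic order."""
        for tup in itertools.product("ACGT", repeat=self.pam_len):
            yield "".join(tup)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "spacer": self.spacer,
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "pam_len": self.pam_len,
            "total_conc": self.total_conc,
        }
        if self.sublibraries is not None:
            d["sublibraries"] = [list(s) for s in self.sublibraries]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LibraryScheme":
        subs = d.get("sublibraries")
        return cls(
            name=d["name"],
            spacer=d["spacer"],
            left_flank=d["left_flank"],
            right_flank=d["right_flank"],
            pam_len=int(d["pam_len"]),
            sublibraries=tuple((int(p), b) for p, b in subs) if subs else None,
            total_conc=float(d.get("total_conc", 5.6)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "LibraryScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_fasta(self, path, pams: Sequence[str] | None = None) -> None:
        """Export construct sequences (one record per PAM) as FASTA."""
        pams = list(pams) if pams is not None else ["N" * self.pam_len]
        with open(path, "w") as fh:
            for pam in pams:
                seq = (self.left_flank + _normalize_seq(pam) + self.right_flank
                       if set(_normalize_seq(pam)) - _DNA else self.construct(pam))
                fh.write(f">{self.name}|{pam}\n{seq}\n")


# -- reference schemes --------------------------------------------------------

#: T1 protospacer (DNA strand matching the T1 guide spacer)
T1_SPACER = "CGCTAAAGAGGAAGAGGACA"
#: T1 shifted 3 nt 5' (used to extend PAM read-out from 7 to 10 bp)
T1_SHIFTED_SPACER = "AAACGCTAAAGAGGAAGAGG"
#: synthetic vector-side flank 3' of the randomized window
_VECTOR_RIGHT_FLANK = "GGATCCTCTAGAGTCGACCT"


def t1_scheme(pam_len: int = 5, total_conc: float = 5.6) -> LibraryScheme:
    """Reference scheme: T1 protospacer with a fully randomized PAM window.

    The protospacer itself serves as left flank (its last 12 nt anchor PAM
    extraction); the right flank is vector polylinker sequence.  The 7-bp
    variant records the four 6-random+1-fixed sublibraries at position 7.
    """
    subs = None
    if pam_len == 7:
        subs = tuple((7, b) for b in "GCAT")
    return LibraryScheme(
        name=f"T1-{pam_len}bp",
        spacer=T1_SPACER,
        left_flank=T1_SPACER,
        right_flank=_VECTOR_RIGHT_FLANK,
        pam_len=pam_len,
        sublibraries=subs,
        total_conc=total_conc,
    )


def t1_shifted_scheme(pam_len: int = 7, total_conc: float = 5.6) -> LibraryScheme:
    """Spacer-shifted twin of :func:`t1_scheme` (3 nt 5' shift).

    The physical construct is unchanged, so the extraction flanks are the
    same; only the guide (spacer) differs.  Used to extend PAM identification
    beyond the randomized window length.
    """
    base = t1_scheme(pam_len=pam_len, total_conc=total_conc)
    return LibraryScheme(
        name=f"T1-shift3-{pam_len}bp",
        spacer=T1_SHIFTED_SPACER,
        left_flank=base.left_flank,
        right_flank=base.right_flank,
        pam_len=pam_len,
        sublibraries=base.sublibraries,
        total_conc=total_conc,
    )


# -- operations ---------------------------------------------------------------

def expand_iupac(pattern: "IupacPattern | str") -> set[str]:
    """Every concrete DNA sequence matched by a degenerate pattern."""
    pat = _as_pattern(pattern)
    return {"".join(t) for t in itertools.product(*pat.position_sets)}


def scheme_diversity(scheme: LibraryScheme) -> int:
    """Number of distinct PAM sequences in the randomized window (4^pam_len)."""
    return 4 ** scheme.pam_len


def required_read_depth(scheme: LibraryScheme, multiplier: float = 5.0) -> int:
    """Sequencing depth needed to cover the library ``multiplier``-fold.

    The assay convention is to sequence to at least five times the library
    diversity (5,120 reads for the 5-bp and 81,920 for the 7-bp library).
    """
    if not multiplier > 0:
        raise ValueError(f"multiplier must be > 0, got {multiplier}")
    return math.ceil(multiplier * scheme_diversity(scheme))


def pam_concentration(
    pattern: "IupacPattern | str",
    scheme: LibraryScheme,
    composition: PamCountTable | None = None,
) -> float:
    """Molar concentration (nM) of library members matching ``pattern``.

    With no ``composition``, the ideal uniform library is assumed (matching
    fraction = pattern size / 4^pam_len).  With a sequenced composition, the
    observed frequencies of matching PAMs are summed.  No rounding is applied
    here; round only at presentation.
    """
    pat = _as_pattern(pattern)
    if len(pat) != scheme.pam_len:
        raise ValueError(
            f"pattern length {len(pat)} != scheme pam_len {scheme.pam_len}"
        )
    if composition is None:
        fraction = pat.size() / scheme_diversity(scheme)
    else:
        if composition.pam_len != scheme.pam_len:
            raise ValueError("composition pam_len does not match scheme")
        freqs = composition.frequencies()
        if freqs and abs(sum(freqs.values()) - 1.0) > 1e-6:
            raise ValueError("composition frequencies must sum to 1")
        fraction = sum(f for p, f in freqs.items() if pat.matches(p))
    return scheme.total_conc * fraction


def expected_target_spacing(
    pattern: "IupacPattern | str", both_strands: bool = True
) -> float:
    """Mean distance (bp) between target sites licensed by ``pattern``.

    On an i.i.d. equal-composition genome a site occurs per position with
    probability ``match_probability``; searching both strands doubles the
    rate.  NGG on both strands gives one site every 8 bp on average.
    """
    pat = _as_pattern(pattern)
    rate = pat.match_probability() * (2.0 if both_strands else 1.0)
    return 1.0 / rate
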