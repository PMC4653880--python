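"""From PAM count tables to PFMs, logos, consensuses and dose comparisons.

Cleaved-sample PAM frequencies are first normalized to their frequency in
the starting library (correcting synthesis/cloning bias), then summarized
as a position frequency matrix: the probability of each nucleotide at each
PAM position is the summed normalized weight of all PAMs carrying that
nucleotide there, each position evaluated independently.  The PFM feeds
Schneider-style information content, WebLogo-ready letter heights, IUPAC
consensus calls, dose-to-dose specificity comparisons, and the 3-nt
spacer-shift extension of the PAM window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import PamCountTable
from .library_design import CODE_FOR_SET, IupacPattern

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PFMatrix:
    """Per-position nucleotide probability matrix over the PAM window.

    ``probs`` has shape (L, 4) with columns in A, C, G, T order; each row
    sums to 1.  ``positions`` are 1-based PAM coordinates (position 1 is the
    first base 3' of the protospacer).  Provenance travels along as the
    source sample label, total read count and RNP concentration.
    """

    probs: np.ndarray
    positions: tuple[int, ...] = ()
    total_reads: float | None = None
    sample_label: str = ""
    rnp_conc: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be an (L, 4) matrix (columns A,C,G,T)")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        object.__setattr__(self, "probs", p)
        pos = tuple(self.positions) or tuple(range(1, p.shape[0] + 1))
        if len(pos) != p.shape[0]:
            raise ValueError("positions/probs length mismatch")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def column(self, position: int) -> dict[str, float]:
        """{A,C,G,T} -> probability at a 1-based PAM position."""
        i = self.positions.index(position)
        return {b: float(self.probs[i, j]) for j, b in enumerate(BASES)}

    def to_dataframe(self) -> pd.DataFrame:
        """Rows A, C, G, T x PAM positions."""
        return pd.DataFrame(self.probs.T, index=list(BASES),
                            columns=list(self.positions))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="base")

    @classmethod
    def read_tsv(cls, path) -> "PFMatrix":
        df = pd.read_csv(path, sep="\t", index_col="base")
        probs = df.loc[list(BASES)].to_numpy(float).T
        return cls(probs=probs, positions=tuple(int(c) for c in df.columns))


# -- core transforms ----------------------------------------------------------

def normalize_counts(
    cleaved: PamCountTable,
    library: PamCountTable,
    pseudocount: float | None = None,
) -> PamCountTable:
    """Cleaved-sample frequencies normalized to the starting library.

    Each PAM's weight is cleaved frequency / (library frequency +
    pseudocount); weights are rescaled to sum to 1.  The default pseudocount
    is 0.5 / library total, guarding PAMs that were cleaved but never
    sequenced in the library control; with pseudocount 0 such a PAM is an
    error.  PAMs absent from the cleaved sample simply keep weight 0.
    """
    if cleaved.pam_len != library.pam_len:
        raise ValueError("cleaved and library tables have different pam_len")
    if len(library) == 0:
        raise ValueError("library table is empty")
    if pseudocount is None:
        pseudocount = 0.5 / library.total
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    weights: dict[str, float] = {}
    for pam, f in cleaved.frequencies().items():
        lib_f = library.freq(pam) + pseudocount
        if lib_f == 0.0:
            raise ValueError(
                f"PAM {pam} absent from the library control; use a pseudocount"
            )
        weights[pam] = f / lib_f
    return PamCountTable.from_frequencies(
        {p: w for p, w in weights.items()},
        pam_len=cleaved.pam_len,
        sample_label=f"{cleaved.sample_label} (library-normalized)",
        rnp_conc=cleaved.rnp_conc,
    ) if weights else PamCountTable({}, pam_len=cleaved.pam_len,
                                    sample_label=cleaved.sample_label,
                                    rnp_conc=cleaved.rnp_conc)


def compute_pfm(table: PamCountTable) -> PFMatrix:
    """Position frequency matrix of a (normalized) PAM table.

    probs[j][b] is the summed frequency weight of every PAM carrying base b
    at position j; columns sum to 1 by construction.
    """
    if len(table) == 0:
        raise ValueError("cannot build a PFM from an empty table")
    probs = np.zeros((table.pam_len, 4))
    for pam, f in table.frequencies().items():
        for j, base in enumerate(pam):
            probs[j, _BASE_INDEX[base]] += f
    probs /= probs.sum(axis=1, keepdims=True)
    return PFMatrix(probs=probs, total_reads=table.total,
                    sample_label=table.sample_label, rnp_conc=table.rnp_conc)


def information_content(
    pfm: PFMatrix, background: Mapping[str, float] | None = None
) -> np.ndarray:
    """Bits per PAM position (WebLogo convention).

    Uniform background: IC_j = 2 + sum_b p log2 p, with 0 log 0 = 0, in
    [0, 2].  A non-uniform background switches to relative entropy
    sum_b p log2(p / q).
    """
    p = pfm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        if background is None:
            ic = 2.0 + plogp.sum(axis=1)
        else:
            q = np.array([background[b] for b in BASES], dtype=float)
            if abs(q.sum() - 1.0) > 1e-9 or np.any(q <= 0):
                raise ValueError("background must be positive and sum to 1")
            ic = (plogp - np.where(p > 0, p * np.log2(q), 0.0)).sum(axis=1)
    return np.maximum(ic, 0.0)


def total_information(pfm: PFMatrix) -> float:
    return float(information_content(pfm).sum())


@dataclass(frozen=True)
class ConsensusCall:
    """IUPAC consensus with the frequency mass supporting each position."""

    iupac: IupacPattern
    per_position_support: tuple[float, ...]
    support_threshold: float
    n_floor: float

    def __str__(self) -> str:
        return str(self.iupac)


def call_consensus(
    pfm: PFMatrix, support_threshold: float = 0.9, n_floor: float = 0.30
) -> ConsensusCall:
    """IUPAC consensus: smallest base set capturing the support threshold.

    Per position, bases are retained in descending probability until their
    cumulative mass reaches ``support_threshold`` (ties retain all tied
    bases).  A position whose retained set is all four bases, or where no
    single base exceeds ``n_floor``, is called N.
    """
    if not 0 < support_threshold <= 1 or not 0 < n_floor <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    codes: list[str] = []
    supports: list[float] = []
    for row in pfm.probs:
        order = sorted(range(4), key=lambda j: (-row[j], BASES[j]))
        retained: list[int] = []
        cum = 0.0
        for rank, j in enumerate(order):
            retained.append(j)
            cum += row[j]
            if cum >= support_threshold - 1e-12:
                # include any base tied with the last one retained
                for j2 in order[rank + 1:]:
                    if abs(row[j2] - row[j]) <= 1e-12:
                        retained.append(j2)
                        cum += row[j2]
                    else:
                        break
                break
        if len(retained) == 4 or row.max() <= n_floor:
            codes.append("N")
            supports.append(1.0)
        else:
            codes.append(CODE_FOR_SET[frozenset(BASES[j] for j in retained)])
            supports.append(float(cum))
    return ConsensusCall(
        iupac=IupacPattern("".join(codes)),
        per_position_support=tuple(supports),
        support_threshold=support_threshold,
        n_floor=n_floor,
    )


# -- dose comparison and shift extension --------------------------------------

@dataclass(frozen=True)
class DoseComparison:
    """Low-dose minus high-dose information content, per position and total."""

    positions: tuple[int, ...]
    delta_bits: np.ndarray
    total_delta_bits: float
    flagged_positions: tuple[int, ...]
    noise_floor: float


def compare_doses(
    pfm_low: PFMatrix, pfm_high: PFMatrix, noise_floor: float = 0.1
) -> DoseComparison:
    """Specificity change between a low- and a high-dose digest.

    delta_j = IC_low,j - IC_high,j; positive deltas mean the high-dose PAM
    read-out is more relaxed at that position.  Positions whose |delta|
    exceeds ``noise_floor`` bits are flagged.
    """
    if pfm_low.positions != pfm_high.positions:
        raise ValueError("PFMs cover different position sets")
    delta = information_content(pfm_low) - information_content(pfm_high)
    flagged = tuple(
        pos for pos, d in zip(pfm_low.positions, delta) if abs(d) > noise_floor
    )
    return DoseComparison(
        positions=pfm_low.positions,
        delta_bits=delta,
        total_delta_bits=float(delta.sum()),
        flagged_positions=flagged,
        noise_floor=noise_floor,
    )


@dataclass(frozen=True)
class ShiftDiagnostics:
    """Concordance of the overlap between unshifted and shifted experiments."""

    overlap_tv: dict[int, float]
    discordant_positions: tuple[int, ...]
    tv_threshold: float


def extend_pfm_with_shift(
    pfm_base: PFMatrix,
    pfm_shifted: PFMatrix,
    shift: int = 3,
    tv_threshold: float = 0.1,
) -> tuple[PFMatrix, ShiftDiagnostics]:
    """Extend a PAM PFM beyond the randomized window using a shifted spacer.

    Shifting the spacer ``shift`` nt in the 5' direction moves the PAM frame
    so that randomized base r reports on PAM position r + shift.  Extended
    positions 1..L come from the unshifted experiment; positions L+1..L+shift
    come from shifted-experiment positions L+1-shift..L.  Overlapping
    positions (shift+1..L) are reported from the unshifted PFM, with the
    shifted values retained as a concordance diagnostic (total-variation
    distance per position; > ``tv_threshold`` is flagged).
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    L = len(pfm_base)
    if len(pfm_shifted) != L:
        raise ValueError("base and shifted PFMs must cover windows of equal length")
    if shift > L:
        raise ValueError("shift larger than the randomized window")
    if shift == 0:
        return pfm_base, ShiftDiagnostics(
            overlap_tv={}, discordant_positions=(), tv_threshold=tv_threshold
        )
    probs = np.vstack([pfm_base.probs, pfm_shifted.probs[L - shift:]])
    overlap_tv: dict[int, float] = {}
    for p in range(shift + 1, L + 1):
        tv = 0.5 * float(
            np.abs(pfm_base.probs[p - 1] - pfm_shifted.probs[p - shift - 1]).sum()
        )
        overlap_tv[p] = tv
    discordant = tuple(p for p, tv in overlap_tv.items() if tv > tv_threshold)
    extended = PFMatrix(
        probs=probs,
        positions=tuple(range(1, L + shift + 1)),
        total_reads=pfm_base.total_reads,
        sample_label=f"{pfm_base.sample_label} (+{shift} nt shift extension)",
        rnp_conc=pfm_base.rnp_conc,
    )
    return extended, ShiftDiagnostics(
        overlap_tv=overlap_tv, discordant_positions=discordant,
        tv_threshold=tv_threshold,
    )


# -- logo export --------------------------------------------------------------

def logo_heights(pfm: PFMatrix, mode: str = "probability") -> pd.DataFrame:
    """Letter heights for a sequence logo, rows A,C,G,T x positions.

    ``probability`` mode: height = per-position probability (stacks sum to
    1).  ``bits`` mode: height = probability x information content (stacks
    sum to the position's IC, WebLogo style).
    """
    if mode == "probability":
        heights = pfm.probs
    elif mode == "bits":
        heights = pfm.probs * information_content(pfm)[:, None]
    else:
        raise ValueError(f"mode must be 'probability' or 'bits', got {mode!r}")
    return pd.DataFrame(heights.T, index=list(BASES), columns=list(pfm.positions))
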