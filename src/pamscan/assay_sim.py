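"""End-to-end simulator of the randomized-PAM cleavage assay.

Emulates the wet workflow read by the rest of the package: a plasmid library
with a randomized PAM window (optionally composition-biased), dose-dependent
Cas9 cleavage under a ground-truth per-PAM rate model, capture of cleaved
molecules, and single-end read emission with substitution errors and Phred
qualities.  Companion generators produce mutagenized amplicon reads (for the
indel caller) and supercoiled-fraction time courses (for the kinetics
fitter).

Modeling choices
----------------
* Cleavage of PAM ``p`` over a digest of duration ``t`` minutes is a
  first-order process: P(cleaved) = 1 - exp(-k(p) * g(c) * t), where
  g(c) = c / (c + K_half) is a saturating occupancy factor in the Cas9-guide
  RNA complex concentration ``c`` (nM).  K_half defaults to 5 nM so that
  0.5 nM and 50 nM digests land in the sub-saturating and saturating
  regimes, reproducing the dose-dependent broadening of permissive PAMs.
* dA-tailing, adapter ligation, and PCR are collapsed into one weighted
  Bernoulli capture per molecule; read counts are proportional to cleaved
  molecules.  PCR bias and chimeras are not modeled.
* The blunt cut sits 3 nt 5' of the PAM inside the protospacer; emitted
  reads span barcode + left flank + PAM window + right flank + adapter.
* Sequencing noise is substitution-only (no indel errors); qualities are
  Gaussian around a mean Phred score, clipped to [2, 41].
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import PamCountTable
from .kinetics import KineticsSeries
from .library_design import IupacPattern, LibraryScheme, _as_pattern
from .readproc import SeqRead, quality_string
from .variants import Edit

_BASES = "ACGT"
#: replacement lookup for substitution errors: 3 alternatives per base
_ALT = {b: _BASES.replace(b, "") for b in _BASES}


# -- ground-truth activity model ----------------------------------------------

@dataclass
class CleavageActivityModel:
    """Ground-truth per-PAM first-order cleavage rate k(PAM), 1/min.

    Parameterized either by an explicit rate table or by a per-position
    multiplicative penalty form k(PAM) = k_max * prod_j w_j(base_j) with
    weights in [0, 1].  ``k_half`` (nM) is the half-saturation constant of
    the occupancy factor used by :func:`cleavage_probability`.
    """

    pam_len: int
    k_max: float = 0.2
    position_weights: tuple[Mapping[str, float], ...] | None = None
    rate_table: Mapping[str, float] | None = None
    k_half: float = 5.0

    def __post_init__(self) -> None:
        if self.pam_len < 1:
            raise ValueError("pam_len must be >= 1")
        if not self.k_max > 0:
            raise ValueError("k_max must be > 0")
        if self.k_half < 0:
            raise ValueError("k_half must be >= 0")
        if (self.position_weights is None) == (self.rate_table is None):
            raise ValueError(
                "exactly one of position_weights / rate_table must be given"
            )
        if self.position_weights is not None:
            if len(self.position_weights) != self.pam_len:
                raise ValueError("need one weight map per PAM position")
            for j, w in enumerate(self.position_weights, start=1):
                for b in _BASES:
                    if not 0.0 <= w.get(b, 0.0) <= 1.0:
                        raise ValueError(
                            f"weight w_{j}({b}) outside [0, 1]: {w.get(b)}"
                        )
        else:
            for p, k in self.rate_table.items():
                if len(p) != self.pam_len:
                    raise ValueError(f"rate table key {p!r} has wrong length")
                if k < 0:
                    raise ValueError(f"negative rate for {p!r}")

    def rate(self, pam: str) -> float:
        """k(pam) in 1/min."""
        pam = pam.upper()
        if len(pam) != self.pam_len:
            raise ValueError(f"PAM {pam!r} length != model pam_len {self.pam_len}")
        if self.rate_table is not None:
            return float(self.rate_table.get(pam, 0.0))
        k = self.k_max
        for base, w in zip(pam, self.position_weights):
            k *= w.get(base, 0.0)
        return k

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_table(cls, rates: Mapping[str, float],
                   k_half: float = 5.0) -> "CleavageActivityModel":
        pam_len = len(next(iter(rates)))
        k_max = max(rates.values())
        return cls(pam_len=pam_len, k_max=max(k_max, 1e-300),
                   rate_table=dict(rates), k_half=k_half)

    @classmethod
    def from_position_weights(
        cls, k_max: float, weights: Sequence[Mapping[str, float]],
        k_half: float = 5.0,
    ) -> "CleavageActivityModel":
        return cls(pam_len=len(weights), k_max=k_max,
                   position_weights=tuple(dict(w) for w in weights),
                   k_half=k_half)

    @classmethod
    def from_iupac(
        cls, pattern: IupacPattern | str, k_max: float = 0.2,
        mismatch_weight: float = 0.01, k_half: float = 5.0,
    ) -> "CleavageActivityModel":
        """Penalty model from a consensus: allowed bases weight 1, others
        ``mismatch_weight`` (partial activity of near-cognate PAMs)."""
        pat = _as_pattern(pattern)
        weights = tuple(
            {b: (1.0 if b in allowed else mismatch_weight) for b in _BASES}
            for allowed in pat.position_sets
        )
        return cls.from_position_weights(k_max, weights, k_half=k_half)


@dataclass(frozen=True)
class DigestCondition:
    """One digest: RNP complex concentration (nM), duration (min), library (nM)."""

    rnp_conc: float
    time: float = 60.0
    library_conc: float = 5.6

    def __post_init__(self) -> None:
        if self.rnp_conc < 0 or self.time < 0 or self.library_conc < 0:
            raise ValueError("digest condition values must be nonnegative")


def occupancy(rnp_conc: float, k_half: float) -> float:
    """Saturating occupancy factor g(c) = c / (c + K_half) in [0, 1)."""
    if rnp_conc <= 0:
        return 0.0
    return rnp_conc / (rnp_conc + k_half)


def cleavage_probability(
    pam: str, model: CleavageActivityModel, cond: DigestCondition
) -> float:
    """P(a molecule carrying ``pam`` is cleaved) = 1 - exp(-k g t)."""
    k = model.rate(pam)
    return -math.expm1(-k * occupancy(cond.rnp_conc, model.k_half) * cond.time)


# -- read emission ------------------------------------------------------------

@dataclass(frozen=True)
class ReadEmissionProfile:
    """Sequencer/run description for emitted reads.

    ``mean_quality``/``quality_sd`` parameterize the per-base Phred score
    distribution (Gaussian, rounded, clipped to [2, 41]); substitution
    errors are drawn independently of the printed qualities.
    """

    barcode: str = "ACGT"
    adapter: str = "AGATCGGAAGAGC"
    read_len: int = 100
    substitution_error_rate: float = 0.002
    mean_quality: float = 33.0
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        bc = self.barcode.upper()
        if not 4 <= len(bc) <= 6 or set(bc) - set(_BASES):
            raise ValueError("barcode must be 4-6 nt of ACGT")
        object.__setattr__(self, "barcode", bc)
        object.__setattr__(self, "adapter", self.adapter.upper())
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.read_len < 1:
            raise ValueError("read_len must be positive")


def _quality_matrix(rng: np.random.Generator, n: int, length: int,
                    profile: ReadEmissionProfile) -> np.ndarray:
    q = rng.normal(profile.mean_quality, profile.quality_sd, size=(n, length))
    return np.clip(np.rint(q), 2, 41).astype(np.uint8)


def _error_positions(rng: np.random.Generator, n: int, length: int,
                     rate: float) -> dict[int, np.ndarray]:
    """read index -> array of error columns (sparse; most reads error-free)."""
    if rate <= 0 or n == 0:
        return {}
    mask = rng.random(size=(n, length)) < rate
    rows, cols = np.nonzero(mask)
    grouped: dict[int, list[int]] = defaultdict(list)
    for r, c in zip(rows, cols):
        grouped[int(r)].append(int(c))
    return {r: np.asarray(c) for r, c in grouped.items()}


def _apply_errors(seq: str, cols: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for c in cols:
        if c < len(chars):
            chars[c] = _ALT[chars[c]][rng.integers(3)]
    return "".join(chars)


def _qual_row_string(row: np.ndarray) -> str:
    return (row + 33).tobytes().decode("ascii")


# -- simulators ---------------------------------------------------------------

def simulate_library(
    scheme: LibraryScheme, bias_strength: float = 0.1, seed: int = 0
) -> PamCountTable:
    """Library composition over all 4^pam_len PAMs.

    ``bias_strength`` 0 gives the ideal uniform library; otherwise
    frequencies are a symmetric Dirichlet draw with concentration
    1 / bias_strength per category (larger bias, stronger departure from
    uniformity), emulating synthesis/cloning bias that the downstream
    library normalization must correct.
    """
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    pams = list(scheme.all_pams())
    if bias_strength == 0:
        freqs = np.full(len(pams), 1.0 / len(pams))
    else:
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.full(len(pams), 1.0 / bias_strength))
    return PamCountTable.from_frequencies(
        dict(zip(pams, freqs)), sample_label=f"{scheme.name} library (control)"
    )


def simulate_digest_reads(
    scheme: LibraryScheme,
    library: PamCountTable,
    model: CleavageActivityModel,
    cond: DigestCondition,
    profile: ReadEmissionProfile,
    n_reads: int,
    seed: int = 0,
) -> tuple[list[SeqRead], pd.DataFrame]:
    """Reads captured from a Cas9 digest of the library, plus a truth table.

    Each captured molecule's PAM is drawn with weight
    library frequency x cleavage probability; without any cleavage (e.g.
    RNP concentration 0) no fragments are captured and the read stream is
    empty.  Reads are barcode + left flank + PAM + right flank + adapter,
    truncated (or adapter-padded) to ``read_len``.  The truth table records
    the error-free PAM of every read.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if library.pam_len != scheme.pam_len or model.pam_len != scheme.pam_len:
        raise ValueError("scheme, library and model pam_len must agree")
    min_len = len(profile.barcode) + len(scheme.left_flank) + scheme.pam_len + 12
    if profile.read_len < min_len:
        raise ValueError(
            f"read_len {profile.read_len} cannot span barcode + left flank + "
            f"PAM + 12 nt right anchor ({min_len} nt)"
        )

    truth_cols = {"read_id": [], "pam": []}
    empty_truth = pd.DataFrame(truth_cols)
    pams = sorted(library.counts())
    freqs = np.array([library.freq(p) for p in pams])
    probs = np.array([cleavage_probability(p, model, cond) for p in pams])
    weights = freqs * probs
    wsum = weights.sum()
    if wsum == 0.0 or n_reads == 0:
        return [], empty_truth

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pams), size=n_reads, p=weights / wsum)
    quals = _quality_matrix(rng, n_reads, profile.read_len, profile)
    errors = _error_positions(rng, n_reads, profile.read_len,
                              profile.substitution_error_rate)

    template_cache: dict[str, str] = {}

    def template(pam: str) -> str:
        t = template_cache.get(pam)
        if t is None:
            t = (profile.barcode + scheme.left_flank + pam
                 + scheme.right_flank + profile.adapter)
            while len(t) < profile.read_len:
                t += profile.adapter
            t = t[: profile.read_len]
            template_cache[pam] = t
        return t

    reads: list[SeqRead] = []
    for i in range(n_reads):
        pam = pams[idx[i]]
        seq = template(pam)
        if i in errors:
            seq = _apply_errors(seq, errors[i], rng)
        read_id = f"digest_{i:07d}"
        reads.append(SeqRead(read_id, seq, _qual_row_string(quals[i])))
        truth_cols["read_id"].append(read_id)
        truth_cols["pam"].append(pam)
    return reads, pd.DataFrame(truth_cols)


def simulate_amplicon_reads(
    reference: str,
    cut_site: int,
    indel_spectrum: Sequence[tuple[Edit, float]],
    mutant_fraction: float,
    profile: ReadEmissionProfile,
    n_reads: int,
    seed: int = 0,
) -> tuple[list[SeqRead], pd.DataFrame]:
    """Mutation-detection amplicon reads with a planted indel spectrum.

    A ``mutant_fraction`` of reads carries one edit sampled from the
    spectrum (relative weights); the rest are wild type.  Every edit must be
    an indel anchored within 5 nt of ``cut_site``.  Substitution errors and
    qualities follow the profile; reads longer than ``read_len`` are
    truncated.  The truth table records each read's planted edit.
    """
    reference = reference.upper()
    if not 0 < cut_site < len(reference):
        raise ValueError("cut_site must lie inside the reference")
    if not 0.0 <= mutant_fraction <= 1.0:
        raise ValueError("mutant_fraction must be a probability")
    if mutant_fraction > 0 and not indel_spectrum:
        raise ValueError("mutant_fraction > 0 requires a nonempty spectrum")
    edits = [e for e, _ in indel_spectrum]
    weights = np.array([w for _, w in indel_spectrum], dtype=float)
    for e in edits:
        if abs(e.pos - cut_site) > 5:
            raise ValueError(
                f"edit {e} anchored {abs(e.pos - cut_site)} nt from the cut "
                "(must be within 5 nt)"
            )
        e.apply(reference)  # bounds check
    if edits and (np.any(weights < 0) or weights.sum() == 0):
        raise ValueError("spectrum weights must be nonnegative and not all zero")

    rng = np.random.default_rng(seed)
    is_mutant = rng.random(n_reads) < mutant_fraction if n_reads else np.array([], bool)
    if edits:
        choice = rng.choice(len(edits), size=n_reads, p=weights / weights.sum())
    else:
        choice = np.zeros(n_reads, dtype=int)

    variant_cache = {None: reference[: profile.read_len]}
    for e in edits:
        variant_cache[e] = e.apply(reference)[: profile.read_len]

    max_len = max(len(s) for s in variant_cache.values())
    quals = _quality_matrix(rng, n_reads, max_len, profile)
    errors = _error_positions(rng, n_reads, max_len,
                              profile.substitution_error_rate)

    reads: list[SeqRead] = []
    truth_cols: dict[str, list] = {"read_id": [], "is_mutant": [], "edit": []}
    for i in range(n_reads):
        edit = edits[choice[i]] if is_mutant[i] else None
        seq = variant_cache[edit]
        if i in errors:
            seq = _apply_errors(seq, errors[i], rng)
        read_id = f"amplicon_{i:07d}"
        reads.append(SeqRead(read_id, seq, _qual_row_string(quals[i][: len(seq)])))
        truth_cols["read_id"].append(read_id)
        truth_cols["is_mutant"].append(edit is not None)
        truth_cols["edit"].append("" if edit is None else str(edit))
    return reads, pd.DataFrame(truth_cols)


def simulate_kinetics(
    k: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    substrate_label: str = "",
    replicate_id: int = 0,
) -> KineticsSeries:
    """Supercoiled-fraction time course: exp(-k t) plus clipped Gaussian noise."""
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    t = np.asarray(list(timepoints), dtype=float)
    sc = np.exp(-k * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sc = sc + rng.normal(0.0, noise_sd, size=t.shape)
    sc = np.clip(sc, 0.0, 1.0)
    return KineticsSeries(substrate_label=substrate_label, timepoints=t,
                          sc_fraction=sc, replicate_id=replicate_id)


# -- reference amplicon fixture ----------------------------------------------

#: Blat-style confirmed PAM used for the reference amplicon
EXAMPLE_PAM = "GTCCCGAA"


def example_amplicon() -> tuple[str, int, str]:
    """(reference, cut_site, prefix) for a mutation-detection amplicon.

    Layout: barcode+primer prefix, filler, 20-nt protospacer, 8-nt PAM,
    trailing filler.  The blunt cut sits 3 nt 5' of the PAM inside the
    protospacer.
    """
    from .library_design import T1_SPACER

    prefix = "ACGTGGTCTCATGCAGG"
    filler5 = "TCAAGCTTGCATGCCTGCAG"
    filler3 = "CTGACTCTCTTAAGGTAGCCAAGCTAGCTT"
    reference = prefix + filler5 + T1_SPACER + EXAMPLE_PAM + filler3
    pam_start = len(prefix) + len(filler5) + len(T1_SPACER)
    cut_site = pam_start - 3
    return reference, cut_site, prefix


def example_indel_spectrum(cut_site: int, reference: str) -> list[tuple[Edit, float]]:
    """Eleven distinct 1-3 nt indels around the cut, weights descending.

    All edits are left-normalized against the reference and produce
    pairwise-distinct mutant sequences, so ranks recovered downstream are
    comparable by edit identity.
    """
    c = cut_site
    raw = [
        (Edit("ins", c, 1, "T"), 0.30),
        (Edit("del", c, 1), 0.20),
        (Edit("ins", c + 1, 2, "AG"), 0.13),
        (Edit("del", c - 2, 2), 0.10),
        (Edit("ins", c - 1, 1, "G"), 0.08),
        (Edit("del", c + 1, 3), 0.06),
        (Edit("ins", c + 2, 3, "CAT"), 0.045),
        (Edit("del", c + 2, 1), 0.035),
        (Edit("ins", c - 3, 1, "C"), 0.025),
        (Edit("del", c - 4, 2), 0.015),
        (Edit("ins", c + 3, 2, "TT"), 0.01),
    ]
    spectrum = [(e.left_aligned(reference), w) for e, w in raw]
    seqs = [e.apply(reference) for e, _ in spectrum]
    assert len(set(seqs)) == len(seqs), "planted edits must be distinguishable"
    assert len({e for e, _ in spectrum}) == len(spectrum)
    return spectrum
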