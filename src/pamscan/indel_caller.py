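"""Amplicon INDEL calling for mutation detection at a Cas9 target.

Reads are gated on a perfect barcode+forward-primer prefix and an accepted
length range, globally aligned to the amplicon reference, and classified as
mutant when they carry at least one >= 1 nt insertion or deletion anchored
inside the 10-nt window centered on the expected cut site (3 nt 5' of the
PAM) that is not also present in the no-guide negative control.
Substitutions never count.  Identical mutations are collapsed, ranked, and
the mutant-read percentage is computed over the gated read total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .readproc import SeqRead, quality_trim
from .variants import DEL, INS, Edit

# Alignment scoring: match +2, mismatch -2, gap of length L costs 6 + L
# (affine: 7 for the first gapped base, 1 per extension).
_MATCH = 2.0
_MISMATCH = -2.0
_GAP_OPEN = -7.0
_GAP_EXTEND = -1.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _MATCH
    aligner.mismatch_score = _MISMATCH
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon under mutation surveillance.

    ``protospacer`` and ``pam`` are 0-based half-open intervals on
    ``reference``; the PAM must sit immediately 3' of the protospacer and
    the expected blunt cut is 3 nt 5' of the PAM (between bases, 0-based).
    ``prefix`` is the barcode + forward-primer sequence a valid read must
    start with; ``min_len``/``max_len`` bound accepted read lengths.
    """

    reference: str
    protospacer: tuple[int, int]
    pam: tuple[int, int]
    prefix: str
    min_len: int
    max_len: int
    name: str = ""

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "prefix", self.prefix.upper())
        ps, pe = self.protospacer
        ms, me = self.pam
        if not (0 <= ps < pe <= len(ref) and 0 <= ms < me <= len(ref)):
            raise ValueError("intervals must lie inside the reference")
        if ms != pe:
            raise ValueError("PAM must be immediately 3' of the protospacer")
        if not ref.startswith(self.prefix):
            raise ValueError("reference must begin with the barcode+primer prefix")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")

    @property
    def expected_cut(self) -> int:
        """Blunt-cut coordinate (between bases), 3 nt 5' of the PAM."""
        return self.pam[0] - 3

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "reference": self.reference,
                "protospacer": list(self.protospacer),
                "pam": list(self.pam),
                "prefix": self.prefix,
                "min_len": self.min_len,
                "max_len": self.max_len,
                "name": self.name,
            }, fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "AmpliconTarget":
        with open(path) as fh:
            d = json.load(fh)
        return cls(reference=d["reference"],
                   protospacer=tuple(d["protospacer"]),
                   pam=tuple(d["pam"]), prefix=d["prefix"],
                   min_len=int(d["min_len"]), max_len=int(d["max_len"]),
                   name=d.get("name", ""))


@dataclass(frozen=True)
class ReadAlignment:
    """Global alignment of one read: score and left-normalized indels."""

    read_id: str
    score: float
    edits: tuple[Edit, ...]


@dataclass(frozen=True)
class MutationRecord:
    """One collapsed mutation: its in-window edits, support, audit alignment."""

    edits: tuple[Edit, ...]
    read_count: int = 1
    example_alignment: str = ""

    @property
    def edit(self) -> Edit:
        """Primary (leftmost) edit of this mutation."""
        return self.edits[0]

    def key(self) -> tuple:
        return tuple(str(e) for e in self.edits)


def _edits_from_alignment(aln, reference: str, read: str) -> tuple[Edit, ...]:
    """Indels from a Biopython alignment, left-normalized on the reference."""
    tgt_blocks, qry_blocks = aln.aligned
    edits: list[Edit] = []
    # virtual zero-length blocks at both ends catch leading/trailing gaps
    t_prev, q_prev = 0, 0
    boundaries = list(zip(tgt_blocks, qry_blocks)) + [
        ((len(reference), len(reference)), (len(read), len(read)))
    ]
    for (t_start, t_end), (q_start, q_end) in boundaries:
        t_gap = t_start - t_prev
        q_gap = q_start - q_prev
        if t_gap > 0:
            edits.append(Edit(DEL, t_prev, t_gap))
        if q_gap > 0:
            edits.append(Edit(INS, t_start, q_gap, read[q_prev:q_start]))
        t_prev, q_prev = t_end, q_end
    return tuple(e.left_aligned(reference) for e in edits)


def align_to_reference(
    read: SeqRead | str,
    target: AmpliconTarget,
    min_score_fraction: float = 0.4,
) -> ReadAlignment | None:
    """Deterministic global alignment of a gated read to the reference.

    Scoring: match +2, mismatch -2, gap open -6, gap extend -1 per base;
    indels are subsequently shifted to their leftmost equivalent placement.
    Returns None (read rejected) when the score falls below
    ``min_score_fraction`` of the perfect-match score.
    """
    read_id, seq = (read.id, read.sequence) if isinstance(read, SeqRead) else ("", read)
    if seq == target.reference:
        return ReadAlignment(read_id, _MATCH * len(seq), ())
    aln = _ALIGNER.align(target.reference, seq)[0]
    floor = min_score_fraction * _MATCH * len(target.reference)
    if aln.score < floor:
        return None
    return ReadAlignment(read_id, float(aln.score),
                         _edits_from_alignment(aln, target.reference, seq))


def in_window(edit: Edit, target: AmpliconTarget, window: int = 10) -> bool:
    """Anchor position inside [cut - window/2, cut + window/2)."""
    if window % 2 or window <= 0:
        raise ValueError("window must be a positive even number of nt")
    half = window // 2
    return target.expected_cut - half <= edit.pos < target.expected_cut + half


def _matches_control(edit: Edit, controls, slack: int) -> bool:
    if slack <= 0:
        return edit in controls
    return any(
        c.kind == edit.kind and c.length == edit.length and c.bases == edit.bases
        and abs(c.pos - edit.pos) <= slack
        for c in controls
    )


def call_indel_mutations(
    alignments: Iterable[ReadAlignment],
    target: AmpliconTarget,
    controls: Iterable[Edit] = (),
    window: int = 10,
    control_slack: int = 0,
) -> list[MutationRecord]:
    """One MutationRecord per mutant read.

    A read is mutant iff it carries >= 1 indel anchored inside the detection
    window whose identity (operation, position, length, inserted bases) is
    not present in the negative-control variant set.  ``control_slack``
    optionally also excludes control edits displaced by up to that many nt.
    """
    control_set = set(controls)
    records: list[MutationRecord] = []
    for aln in alignments:
        hits = tuple(
            e for e in aln.edits
            if in_window(e, target, window)
            and not _matches_control(e, control_set, control_slack)
        )
        if hits:
            records.append(MutationRecord(
                edits=hits, read_count=1,
                example_alignment=render_mutation(target, hits),
            ))
    return records


def rank_mutations(
    records: Iterable[MutationRecord], n: int = 10
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Collapse identical mutations and rank them.

    Identity is the full in-window edit tuple (operation, position, length,
    inserted bases).  Order: descending read count, ties by anchor position
    then lexicographic edit description.  Returns (top-n, full table).
    """
    merged: dict[tuple, MutationRecord] = {}
    for rec in records:
        key = rec.key()
        if key in merged:
            old = merged[key]
            merged[key] = MutationRecord(
                edits=old.edits,
                read_count=old.read_count + rec.read_count,
                example_alignment=old.example_alignment,
            )
        else:
            merged[key] = rec
    full = sorted(
        merged.values(),
        key=lambda r: (-r.read_count, r.edit.pos, [str(e) for e in r.edits]),
    )
    return full[:n], full


def mutation_frequency(confirmed_mutant_reads: int, valid_reads: int) -> float | None:
    """Percent mutant reads over gated (valid) reads; None when undefined."""
    if confirmed_mutant_reads < 0 or valid_reads < confirmed_mutant_reads:
        raise ValueError("need valid_reads >= confirmed_mutant_reads >= 0")
    if valid_reads == 0:
        return None
    return 100.0 * confirmed_mutant_reads / valid_reads


def render_mutation(target: AmpliconTarget, edits: Sequence[Edit],
                    flank: int = 15) -> str:
    """Display the edited sequence around the cut: '-' deletions, lowercase
    insertions (amplicon-report style)."""
    ref = target.reference
    chars: list[str] = []
    inserts: dict[int, str] = {}
    deleted = set()
    for e in edits:
        if e.kind == DEL:
            deleted.update(range(e.pos, e.pos + e.length))
        else:
            inserts[e.pos] = inserts.get(e.pos, "") + e.bases.lower()
    lo = max(0, target.expected_cut - flank)
    hi = min(len(ref), target.expected_cut + flank)
    for i in range(lo, hi):
        if i in inserts:
            chars.append(inserts[i])
        chars.append("-" if i in deleted else ref[i])
    if hi in inserts:
        chars.append(inserts[hi])
    return "".join(chars)


# -- pipeline -----------------------------------------------------------------

@dataclass
class AmpliconReport:
    """Mutation-detection summary for one amplicon target."""

    target: AmpliconTarget
    total_reads: int
    valid_reads: int
    mutant_reads: int
    percent_mutant: float | None
    top_mutations: list[MutationRecord]
    all_mutations: list[MutationRecord]
    control_variants: set[Edit]
    rejected_alignments: int
    read_calls: "object" = None  # pandas DataFrame when requested

    def summary_row(self) -> dict:
        return {
            "target": self.target.name,
            "total_reads": self.total_reads,
            "valid_reads": self.valid_reads,
            "mutant_reads": self.mutant_reads,
            "percent_mutant": self.percent_mutant,
        }


def _gate(reads: Iterable[SeqRead], target: AmpliconTarget,
          q_min: int) -> tuple[list[SeqRead], int]:
    """(gated reads, total seen): perfect prefix + accepted length, post-trim."""
    total = 0
    kept: list[SeqRead] = []
    for read in reads:
        total += 1
        trimmed = quality_trim(read, q_min=q_min)
        if (trimmed.sequence.startswith(target.prefix)
                and target.min_len <= len(trimmed.sequence) <= target.max_len):
            kept.append(trimmed)
    return kept, total


def collect_control_variants(
    control_reads: Iterable[SeqRead],
    target: AmpliconTarget,
    window: int = 10,
    q_min: int = 13,
) -> set[Edit]:
    """In-window indels observed in a no-guide control run."""
    gated, _ = _gate(control_reads, target, q_min)
    variants: set[Edit] = set()
    for read in gated:
        aln = align_to_reference(read, target)
        if aln is None:
            continue
        variants.update(e for e in aln.edits if in_window(e, target, window))
    return variants


def analyze_amplicon(
    reads: Iterable[SeqRead],
    target: AmpliconTarget,
    control_reads: Iterable[SeqRead] = (),
    window: int = 10,
    control_slack: int = 0,
    q_min: int = 13,
    top_n: int = 10,
    keep_read_calls: bool = False,
) -> AmpliconReport:
    """Full mutation-detection pass: gate, align, call, subtract, rank."""
    import pandas as pd

    controls = collect_control_variants(control_reads, target, window=window,
                                        q_min=q_min)
    gated, total = _gate(reads, target, q_min)
    alignments: list[ReadAlignment] = []
    rejected = 0
    for read in gated:
        aln = align_to_reference(read, target)
        if aln is None:
            rejected += 1
        else:
            alignments.append(aln)
    records = call_indel_mutations(alignments, target, controls=controls,
                                   window=window, control_slack=control_slack)
    top, full = rank_mutations(records, n=top_n)
    valid = len(gated)
    mutant = sum(r.read_count for r in records)
    calls = None
    if keep_read_calls:
        control_set = set(controls)
        rows = []
        for aln in alignments:
            hits = tuple(
                e for e in aln.edits
                if in_window(e, target, window)
                and not _matches_control(e, control_set, control_slack)
            )
            rows.append({
                "read_id": aln.read_id,
                "is_mutant": bool(hits),
                "mutation": ";".join(str(e) for e in hits),
            })
        calls = pd.DataFrame(rows)
    return AmpliconReport(
        target=target,
        total_reads=total,
        valid_reads=valid,
        mutant_reads=mutant,
        percent_mutant=mutation_frequency(mutant, valid),
        top_mutations=top,
        all_mutations=full,
        control_variants=controls,
        rejected_alignments=rejected,
        read_calls=calls,
    )
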