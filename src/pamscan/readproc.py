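"""FASTQ processing for PAM capture sequencing.

The read-out chain mirrors the sequencing post-processing of the cleavage
assay: reads are 3'-trimmed at the first base below Phred Q13, demultiplexed
by a perfectly matching 4-6 nt barcode at the 5' end, and the PAM is
extracted only from reads carrying a perfect 12-nt sequence match on either
side of the randomized window.  Extracted PAMs are collapsed into like
sequences and counted.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, Mapping, NamedTuple

from Bio.Seq import Seq

from .counts import PamCountTable

PHRED_OFFSET = 33


class SeqRead(NamedTuple):
    """One sequencing read: identifier, bases, Sanger Phred+33 qualities."""

    id: str
    sequence: str
    qualities: str

    def to_fastq(self) -> str:
        return f"@{self.id}\n{self.sequence}\n+\n{self.qualities}\n"


def phred_values(qualities: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qualities]


def quality_string(values) -> str:
    return "".join(chr(int(q) + PHRED_OFFSET) for q in values)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# -- FASTQ I/O ----------------------------------------------------------------

def read_fastq(path) -> Iterator[SeqRead]:
    """Iterate reads from a FASTQ file (gzip accepted by .gz suffix)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and seq:
                raise ValueError(f"truncated FASTQ record at {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at {header.strip()!r}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"sequence/quality length mismatch in {header.strip()!r}"
                )
            yield SeqRead(header[1:].strip().split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[SeqRead], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(r.to_fastq())


# -- per-read operations ------------------------------------------------------

def quality_trim(read: SeqRead, q_min: int = 13) -> SeqRead:
    """Longest prefix in which every base has Phred quality >= ``q_min``.

    3' truncation at the first sub-threshold base; may return an empty read.
    """
    if len(read.sequence) != len(read.qualities):
        raise ValueError("sequence and quality strings differ in length")
    cut = len(read.sequence)
    threshold = q_min + PHRED_OFFSET
    for i, ch in enumerate(read.qualities):
        if ord(ch) < threshold:
            cut = i
            break
    return SeqRead(read.id, read.sequence[:cut], read.qualities[:cut])


def _check_barcodes(barcodes: Mapping[str, str]) -> dict[str, str]:
    clean = {label: bc.upper() for label, bc in barcodes.items()}
    seqs = list(clean.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("barcodes must be unique")
    for bc in seqs:
        if not 4 <= len(bc) <= 6:
            raise ValueError(f"barcode {bc!r} must be 4-6 nt")
    for a in seqs:
        for b in seqs:
            if a != b and b.startswith(a):
                raise ValueError(f"barcode set is not prefix-free: {a!r} prefixes {b!r}")
    return clean


def demux(
    reads: Iterable[SeqRead], barcodes: Mapping[str, str]
) -> tuple[dict[str, list[SeqRead]], list[SeqRead]]:
    """Assign reads by perfect 5' barcode match; strip the barcode.

    The barcode set must be unique and prefix-free, so each read matches at
    most one barcode.  Unmatched reads land in the unassigned bin.
    """
    clean = _check_barcodes(barcodes)
    assigned: dict[str, list[SeqRead]] = {label: [] for label in clean}
    unassigned: list[SeqRead] = []
    for read in reads:
        for label, bc in clean.items():
            if read.sequence.startswith(bc):
                n = len(bc)
                assigned[label].append(
                    SeqRead(read.id, read.sequence[n:], read.qualities[n:])
                )
                break
        else:
            unassigned.append(read)
    return assigned, unassigned


def _find_pams(seq: str, left12: str, right12: str, pam_len: int) -> list[str]:
    hits: list[str] = []
    start = 0
    while True:
        i = seq.find(left12, start)
        if i < 0:
            break
        j = i + 12 + pam_len
        if len(seq) >= j + 12 and seq[j:j + 12] == right12:
            hits.append(seq[i + 12:j])
        start = i + 1
    return hits


def classify_read(
    seq: str, left12: str, right12: str, pam_len: int, search_rc: bool = True
) -> tuple[str, str | None]:
    """(status, pam) where status is 'extracted', 'ambiguous' or 'no_match'.

    Forward orientation is searched first, then the reverse complement.
    Within one orientation the leftmost valid flank pair wins; a read with
    valid matches in both orientations is dropped as ambiguous.
    """
    if len(left12) != 12 or len(right12) != 12:
        raise ValueError("flank anchors must be exactly 12 nt")
    fwd = _find_pams(seq, left12, right12, pam_len)
    rev = _find_pams(reverse_complement(seq), left12, right12, pam_len) if search_rc else []
    if fwd and rev:
        return "ambiguous", None
    hits = fwd or rev
    if not hits:
        return "no_match", None
    return "extracted", hits[0]


def extract_pam(
    seq: str, left12: str, right12: str, pam_len: int, search_rc: bool = True
) -> str | None:
    """PAM between perfect 12-nt flank matches, or None.

    Returns the ``pam_len`` bases found at exactly ``pam_len`` separation
    between ``left12`` and ``right12``, searching the read as given and,
    failing that, its reverse complement.
    """
    status, pam = classify_read(seq, left12, right12, pam_len, search_rc=search_rc)
    return pam if status == "extracted" else None


def count_pams(
    pams: Iterable[str],
    pam_len: int | None = None,
    sample_label: str = "",
    rnp_conc: float | None = None,
) -> PamCountTable:
    """Collapse a stream of equal-length PAM sequences into a count table."""
    counts: dict[str, int] = {}
    length: int | None = None
    for pam in pams:
        pam = pam.upper()
        if length is None:
            length = len(pam)
        elif len(pam) != length:
            raise ValueError(f"mixed PAM lengths in stream: {length} vs {len(pam)}")
        counts[pam] = counts.get(pam, 0) + 1
    if length is not None and pam_len is not None and length != pam_len:
        raise ValueError(f"stream PAM length {length} != declared pam_len {pam_len}")
    return PamCountTable(counts, pam_len=pam_len if length is None else length,
                         sample_label=sample_label, rnp_conc=rnp_conc)


# -- pipeline -----------------------------------------------------------------

def process_reads(
    reads: Iterable[SeqRead],
    barcodes: Mapping[str, str],
    left12: str,
    right12: str,
    pam_len: int,
    q_min: int = 13,
    search_rc: bool = True,
    rnp_conc: Mapping[str, float] | None = None,
) -> tuple[dict[str, PamCountTable], dict]:
    """Trim, demultiplex, extract and count in one pass.

    Returns one :class:`PamCountTable` per barcode label plus a QC summary
    (reads in, unassigned, per-sample no-match/ambiguous/extracted tallies).
    Conservation: assigned + unassigned = reads in.
    """
    trimmed = []
    n_in = 0
    for read in reads:
        n_in += 1
        trimmed.append(quality_trim(read, q_min=q_min))
    assigned, unassigned = demux(trimmed, barcodes)
    tables: dict[str, PamCountTable] = {}
    qc: dict = {
        "reads_in": n_in,
        "assigned": sum(len(v) for v in assigned.values()),
        "unassigned": len(unassigned),
        "samples": {},
    }
    for label, sample_reads in assigned.items():
        pams: list[str] = []
        tally = {"reads": len(sample_reads), "no_match": 0,
                 "ambiguous": 0, "extracted": 0}
        for read in sample_reads:
            status, pam = classify_read(
                read.sequence, left12, right12, pam_len, search_rc=search_rc
            )
            if status == "extracted":
                tally["extracted"] += 1
                pams.append(pam)  # type: ignore[arg-type]
            else:
                tally[status] += 1
        conc = None if rnp_conc is None else rnp_conc.get(label)
        tables[label] = count_pams(pams, pam_len=pam_len,
                                   sample_label=label, rnp_conc=conc)
        qc["samples"][label] = tally
    return tables, qc


def read_barcode_tsv(path) -> dict[str, str]:
    """Two-column TSV (label, barcode) -> mapping."""
    barcodes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, bc = line.split("\t")[:2]
            if label.lower() in {"label", "sample"}:
                continue
            barcodes[label] = bc.upper()
    return _check_barcodes(barcodes)
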