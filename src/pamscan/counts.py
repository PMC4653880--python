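"""Collapsed PAM count tables.

A :class:`PamCountTable` is the central exchange object of the pipeline: one
table per sample (starting-library control or Cas9 digest), mapping each
distinct PAM sequence to its read count and frequency.  Counts are positive
floats so the same container can hold integer read tallies, simulated library
compositions, and library-normalized weights.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

_DNA = frozenset("ACGT")


class PamCountTable:
    """PAM sequence -> (count, frequency) for one sample.

    Parameters
    ----------
    counts
        Mapping of PAM sequence (uppercase ACGT) to a positive count or
        weight.  All keys must share one length.
    pam_len
        Required only when ``counts`` is empty; otherwise inferred and, if
        given, cross-checked.
    sample_label
        Free-text provenance (e.g. "Sth1 0.5 nM digest").
    rnp_conc
        Cas9-guide RNA complex concentration of the digest in nM, if any.
    """

    __slots__ = ("_counts", "_total", "pam_len", "sample_label", "rnp_conc")

    def __init__(
        self,
        counts: Mapping[str, float],
        pam_len: int | None = None,
        sample_label: str = "",
        rnp_conc: float | None = None,
    ) -> None:
        clean: dict[str, float] = {}
        inferred: int | None = None
        for pam, count in counts.items():
            pam = pam.upper()
            if not pam or set(pam) - _DNA:
                raise ValueError(f"PAM {pam!r} is not an unambiguous DNA string")
            if inferred is None:
                inferred = len(pam)
            elif len(pam) != inferred:
                raise ValueError(
                    f"mixed PAM lengths: {inferred} and {len(pam)} ({pam!r})"
                )
            c = float(count)
            if not c > 0:
                raise ValueError(f"count for {pam} must be > 0, got {count}")
            clean[pam] = clean.get(pam, 0.0) + c
        if inferred is None:
            if pam_len is None:
                raise ValueError("pam_len is required for an empty table")
            inferred = int(pam_len)
        elif pam_len is not None and int(pam_len) != inferred:
            raise ValueError(f"pam_len={pam_len} but keys have length {inferred}")
        if inferred < 1:
            raise ValueError("pam_len must be >= 1")
        self._counts = clean
        self._total = sum(clean.values())
        self.pam_len = inferred
        self.sample_label = sample_label
        self.rnp_conc = rnp_conc

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_frequencies(
        cls,
        frequencies: Mapping[str, float],
        sample_label: str = "",
        rnp_conc: float | None = None,
        pam_len: int | None = None,
    ) -> "PamCountTable":
        """Build a table whose counts *are* the given frequencies."""
        return cls(frequencies, pam_len=pam_len, sample_label=sample_label,
                   rnp_conc=rnp_conc)

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, pam: str) -> bool:
        return pam.upper() in self._counts

    def __iter__(self):
        return iter(self._counts)

    @property
    def total(self) -> float:
        """Sum of counts (total reads for read-derived tables)."""
        return self._total

    def count(self, pam: str) -> float:
        return self._counts.get(pam.upper(), 0.0)

    def freq(self, pam: str) -> float:
        """Frequency of ``pam`` (0 for unseen sequences)."""
        if self._total == 0:
            return 0.0
        return self._counts.get(pam.upper(), 0.0) / self._total

    def counts(self) -> dict[str, float]:
        return dict(self._counts)

    def frequencies(self) -> dict[str, float]:
        """PAM -> frequency; sums to 1 when the table is nonempty."""
        if self._total == 0:
            return {}
        t = self._total
        return {p: c / t for p, c in self._counts.items()}

    def sorted_items(self) -> list[tuple[str, float]]:
        """(pam, count) in deterministic order: descending count, ties lexicographic."""
        return sorted(self._counts.items(), key=lambda kv: (-kv[1], kv[0]))

    # -- I/O ------------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(p, c, c / self._total) for p, c in self.sorted_items()]
        return pd.DataFrame(rows, columns=["pam", "count", "frequency"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, sample_label: str = "",
                 rnp_conc: float | None = None) -> "PamCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"pam": str})
        return cls(dict(zip(df["pam"], df["count"])),
                   sample_label=sample_label, rnp_conc=rnp_conc)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PamCountTable(pam_len={self.pam_len}, n_distinct={len(self)}, "
                f"total={self._total:g}, sample={self.sample_label!r})")


def merge_counts(tables: Iterable[PamCountTable],
                 sample_label: str = "") -> PamCountTable:
    """Sum several tables of equal ``pam_len`` (e.g. sequencing lanes)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    pam_len = tables[0].pam_len
    merged: dict[str, float] = {}
    for t in tables:
        if t.pam_len != pam_len:
            raise ValueError("cannot merge tables with different pam_len")
        for p, c in t.counts().items():
            merged[p] = merged.get(p, 0.0) + c
    return PamCountTable(merged, pam_len=pam_len, sample_label=sample_label)
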