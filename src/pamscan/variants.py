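"""Small insertion/deletion edits on a reference sequence.

Shared between the amplicon simulator (which plants edits) and the indel
caller (which recovers them).  Coordinates are 0-based on the reference:
an insertion of ``bases`` at ``pos`` inserts before ``reference[pos]``;
a deletion at ``pos`` removes ``reference[pos:pos+length]``.
"""

from __future__ import annotations

from dataclasses import dataclass

INS = "ins"
DEL = "del"


@dataclass(frozen=True)
class Edit:
    """One indel: kind ('ins'/'del'), anchor position, length, inserted bases."""

    kind: str
    pos: int
    length: int
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (INS, DEL):
            raise ValueError(f"kind must be 'ins' or 'del', got {self.kind!r}")
        if self.length < 1:
            raise ValueError("edit length must be >= 1")
        if self.pos < 0:
            raise ValueError("edit position must be >= 0")
        if self.kind == INS:
            bases = self.bases.upper()
            if len(bases) != self.length or set(bases) - set("ACGT"):
                raise ValueError("insertion bases must be ACGT of the stated length")
            object.__setattr__(self, "bases", bases)
        elif self.bases:
            raise ValueError("deletions carry no bases")

    def __str__(self) -> str:
        if self.kind == INS:
            return f"ins@{self.pos}+{self.bases}"
        return f"del@{self.pos}x{self.length}"

    @classmethod
    def parse(cls, text: str) -> "Edit":
        kind, _, rest = text.partition("@")
        if kind == INS:
            pos, _, bases = rest.partition("+")
            return cls(INS, int(pos), len(bases), bases)
        if kind == DEL:
            pos, _, length = rest.partition("x")
            return cls(DEL, int(pos), int(length))
        raise ValueError(f"cannot parse edit {text!r}")

    # -- semantics ------------------------------------------------------------

    def apply(self, reference: str) -> str:
        """Reference sequence with this edit applied."""
        if self.kind == INS:
            if self.pos > len(reference):
                raise ValueError("insertion beyond reference end")
            return reference[: self.pos] + self.bases + reference[self.pos:]
        if self.pos + self.length > len(reference):
            raise ValueError("deletion runs off the reference end")
        return reference[: self.pos] + reference[self.pos + self.length:]

    def left_aligned(self, reference: str) -> "Edit":
        """Equivalent edit shifted to its leftmost reference position.

        Standard indel normalization: a gap adjacent to a repeat can be
        placed at several positions that yield the same edited sequence; the
        canonical representative anchors it leftmost.
        """
        pos = self.pos
        if self.kind == DEL:
            while pos > 0 and reference[pos - 1] == reference[pos + self.length - 1]:
                pos -= 1
            return Edit(DEL, pos, self.length)
        bases = self.bases
        while pos > 0 and bases and reference[pos - 1] == bases[-1]:
            bases = reference[pos - 1] + bases[:-1]
            pos -= 1
        return Edit(INS, pos, self.length, bases)

    def sort_key(self) -> tuple:
        return (self.pos, str(self))
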