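"""Tiny sequence helpers shared across modules."""

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Standard-code translation (stops rendered as '*')."""
    return str(Seq(cds).translate())
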