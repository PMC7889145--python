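"""Small shared sequence helpers."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]
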