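"""Dialect table of common small RNA library-prep 3' adapters.

Used only to *annotate* an inferred adapter pattern with a likely kit name;
adapter inference itself never consults this table, so the reference-free
contract is preserved.
"""

from __future__ import annotations

# adapter sequence -> (kit name, typical 5' random bases, typical 3' random bases)
KNOWN_ADAPTERS: dict[str, tuple[str, int, int]] = {
    "TGGAATTCTCGGGTGCCAAGG": ("Illumina TruSeq Small RNA", 0, 0),
    "AGATCGGAAGAGCACACGTC": ("Illumina universal / NEXTflex (4N)", 4, 4),
    "AACTGTAGGCACCATCAAT": ("QIAseq miRNA", 0, 0),
    "CTGTCTCTTATACACATCT": ("Nextera-style", 0, 0),
}


def annotate_adapter(adapter3: str, min_prefix: int = 10) -> str | None:
    """Return the kit name whose adapter shares the longest prefix with
    ``adapter3`` (at least ``min_prefix`` bases), or None if no kit matches."""
    best_name = None
    best_len = min_prefix - 1
    for seq, (name, _, _) in KNOWN_ADAPTERS.items():
        n = 0
        for a, b in zip(adapter3, seq):
            if a != b:
                break
            n += 1
        if n > best_len:
            best_len = n
            best_name = name
    return best_name
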