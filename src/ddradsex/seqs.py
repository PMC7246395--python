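"""Small nucleotide-string utilities shared across the pipeline.

Sequences are plain uppercase Python strings; coordinates are 0-based
half-open throughout the package.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide ambiguity codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_sequence(seq: str) -> bool:
    """True if *seq* contains only uppercase A/C/G/T/N."""
    return bool(_VALID_SEQ.match(seq))


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern (e.g. ``GGWCC``) into a regex.

    N in a *pattern* matches any base; N in a *sequence* matches nothing,
    which is enforced by expanding codes to explicit ACGT classes only.
    """
    parts = []
    for code in pattern.upper():
        try:
            bases = IUPAC[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def matches_iupac_prefix(seq: str, pattern: str) -> bool:
    """IUPAC-aware test that *seq* begins with *pattern*."""
    if len(seq) < len(pattern):
        return False
    for base, code in zip(seq, pattern.upper()):
        if base not in IUPAC.get(code, ""):
            return False
    return True


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings.

    With *limit*, stops early and returns ``limit + 1`` as soon as the
    distance exceeds it (the exact value above the limit is not needed by
    any caller).
    """
    if len(a) != len(b):
        raise ValueError(f"hamming() requires equal lengths ({len(a)} vs {len(b)})")
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d
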