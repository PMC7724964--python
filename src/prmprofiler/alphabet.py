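"""Amino-acid alphabets used throughout the package.

Phage-derived peptides come from a library built with trinucleotide codons for
19 amino acids: cysteine was left out to avoid disulfide artifacts. Profiles
for such data therefore use the 19-letter alphabet; natural-sequence analyses
(SLiMs, disordered regions, proteome scans) use all 20 residues.
"""

from __future__ import annotations

#: The 20 standard residues, alphabetical by one-letter code.
ALPHABET_20: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: The phage-library alphabet: 19 residues, no cysteine.
ALPHABET_NO_CYS: tuple[str, ...] = tuple(a for a in ALPHABET_20 if a != "C")

#: Pad character marking positions outside a peptide in an offset alignment.
PAD = "-"

STANDARD_RESIDUES = frozenset(ALPHABET_20)


def resolve_alphabet(name_or_letters) -> tuple[str, ...]:
    """Resolve ``"no-cys"``/``"full"`` or an explicit residue iterable."""
    if isinstance(name_or_letters, str):
        key = name_or_letters.lower().replace("_", "-")
        if key in ("no-cys", "nocys", "phage", "19"):
            return ALPHABET_NO_CYS
        if key in ("full", "20", "standard"):
            return ALPHABET_20
        letters = tuple(name_or_letters)
    else:
        letters = tuple(name_or_letters)
    bad = set(letters) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residues in alphabet: {sorted(bad)}")
    if len(set(letters)) != len(letters):
        raise ValueError("duplicate residues in alphabet")
    return letters
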